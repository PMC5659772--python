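"""Unit tests for binning, filtering, normalization and the MACC slope."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from macc.core import (
    MACCError,
    MACCTrack,
    TitrationCounts,
    bin_genome,
    compute_macc,
    count_fragments,
    double_x_reads,
    filter_hotspots,
    gc_correct,
    median_shift,
    normalize_library,
)

CONCENTRATIONS = [100.0, 25.0, 6.25, 1.5]


def ols_slope(conc, freqs):
    """Independent least-squares oracle: normal equations long-hand."""
    x = [-np.log(c) for c in conc]
    n = len(x)
    sx, sy = sum(x), sum(freqs)
    sxx = sum(v * v for v in x)
    sxy = sum(v * w for v, w in zip(x, freqs))
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)


def titration(bins, counts, **kw):
    return TitrationCounts(
        bins=bins, concentrations=list(CONCENTRATIONS), counts=counts, **kw
    )


class TestBinGenome:
    def test_tiling_with_short_last_bin(self):
        bins = bin_genome({"chr2": 250}, bin_size=100)
        assert list(bins.start) == [0, 100, 200]
        assert list(bins.end) == [100, 200, 250]

    def test_rejects_nonpositive_size(self):
        with pytest.raises(MACCError):
            bin_genome({"chr2": 0})

    def test_gc_pure_gc_sequence(self):
        bins = bin_genome({"chr2": 100}, bin_size=100, fasta={"chr2": "GGCC" * 25})
        assert bins.gc[0] == 1.0

    def test_gc_over_non_n_bases_and_all_n(self):
        seq = "GGCCAATT" + "N" * 92 + "N" * 100
        bins = bin_genome({"chr2": 200}, bin_size=100, fasta={"chr2": seq})
        # 4 GC of 8 real bases in bin 0; bin 1 is all N
        assert bins.gc[0] == pytest.approx(0.5)
        assert np.isnan(bins.gc[1])

    def test_fasta_name_mismatch_lists_offenders(self):
        with pytest.raises(MACCError, match="chr3"):
            bin_genome({"chr3": 100}, fasta={"chr2": "A" * 100})


class TestHotspots:
    def test_single_towering_position_masked(self):
        frags = pd.DataFrame(
            {
                "chrom": "chr2",
                "start": np.concatenate([np.arange(200), np.full(1000, 5_000)]),
            }
        )
        frags["end"] = frags["start"] + 150
        mask = filter_hotspots(frags, z_threshold=7.0)
        assert mask.n_masked == 1
        assert mask.is_masked("chr2", [5_000, 4_999]).tolist() == [True, False]

    def test_uniform_coverage_warns_and_masks_nothing(self):
        frags = pd.DataFrame({"chrom": "chr2", "start": np.arange(100)})
        frags["end"] = frags["start"] + 150
        with pytest.warns(UserWarning, match="uniform"):
            mask = filter_hotspots(frags)
        assert mask.n_masked == 0

    def test_infinite_threshold_masks_nothing(self):
        frags = pd.DataFrame({"chrom": "chr2", "start": [1, 1, 1, 2]})
        frags["end"] = frags["start"] + 150
        assert filter_hotspots(frags, z_threshold=np.inf).n_masked == 0


class TestCountFragments:
    def test_midpoint_rule(self, toy_bins):
        frags = pd.DataFrame({"chrom": ["chr2"], "start": [150], "end": [250]})
        counts = count_fragments(frags, toy_bins)
        assert counts[2] == 1 and counts.sum() == 1  # midpoint 200 -> bin [200,300)

    def test_size_filter_drops_short_fragment(self, toy_bins):
        frags = pd.DataFrame({"chrom": ["chr2"], "start": [100], "end": [190]})
        assert count_fragments(frags, toy_bins, size_range=(100, 200)).sum() == 0

    def test_conservation_of_retained_fragments(self, toy_bins):
        frags = pd.DataFrame({"chrom": ["chr2"] * 10, "start": [300] * 10, "end": [450] * 10})
        counts = count_fragments(frags, toy_bins)
        assert counts.sum() == 10
        assert counts[3] == 10  # midpoint 375

    def test_fragment_beyond_chromosome_end(self, toy_bins):
        frags = pd.DataFrame({"chrom": ["chr2"], "start": [900], "end": [1_050]})
        with pytest.raises(MACCError, match="chr2:900-1050"):
            count_fragments(frags, toy_bins)

    def test_masked_start_positions_excluded(self, toy_bins):
        frags = pd.DataFrame({"chrom": ["chr2"] * 3, "start": [100, 100, 300]})
        frags["end"] = frags["start"] + 150
        mask = filter_hotspots(
            pd.DataFrame(
                {"chrom": "chr2", "start": np.r_[np.arange(200), np.full(500, 100)]}
            ).assign(end=lambda d: d["start"] + 150),
            z_threshold=7.0,
        )
        counts = count_fragments(frags, toy_bins, mask=mask)
        assert counts.sum() == 1


class TestNormalizeLibrary:
    def test_cpm_arithmetic(self, toy_bins):
        counts = np.zeros((10, 4))
        counts[:, 0] = [4] + [0] * 9
        counts[0, 0] = 4
        counts[1:, 0] = (2_000_000 - 4) / 9
        counts[:, 1:] = 1
        tc = normalize_library(titration(toy_bins, counts))
        assert tc.column(100.0)[0] == pytest.approx(2.0)
        assert tc.normalized

    def test_double_normalization_refused(self, toy_bins):
        tc = normalize_library(titration(toy_bins, np.ones((10, 4))))
        with pytest.raises(MACCError, match="already"):
            normalize_library(tc)

    def test_columns_sum_to_per_million(self, toy_bins):
        rng = np.random.default_rng(0)
        tc = normalize_library(titration(toy_bins, rng.poisson(50, (10, 4)).astype(float)))
        np.testing.assert_allclose(tc.counts.sum(axis=0), 1e6)

    def test_zero_total_column_rejected(self, toy_bins):
        counts = np.ones((10, 4))
        counts[:, 2] = 0
        with pytest.raises(MACCError, match="6.25"):
            normalize_library(titration(toy_bins, counts))


class TestComputeMacc:
    def _track_for(self, freqs):
        bins = bin_genome({"chr2": 100}, bin_size=100)
        tc = titration(bins, np.asarray(freqs, dtype=float)[None, :], normalized=True)
        return compute_macc(tc)

    def test_open_chromatin_slope_positive(self):
        track = self._track_for([2, 4, 8, 10])
        assert track.score[0] == pytest.approx(ols_slope(CONCENTRATIONS, [2, 4, 8, 10]))
        assert track.score[0] == pytest.approx(2.00, abs=0.01)

    def test_constant_frequencies_give_zero(self):
        assert self._track_for([5, 5, 5, 5]).score[0] == 0.0

    def test_sign_symmetry(self):
        up = self._track_for([2, 4, 8, 10]).score[0]
        down = self._track_for([10, 8, 4, 2]).score[0]
        assert down == pytest.approx(-up)

    def test_requires_two_concentrations(self, toy_bins):
        tc = TitrationCounts(
            bins=toy_bins, concentrations=[25.0], counts=np.ones((10, 1)), normalized=True
        )
        with pytest.raises(MACCError):
            compute_macc(tc)

    def test_matches_bruteforce_on_random_bins(self, toy_bins):
        rng = np.random.default_rng(42)
        counts = rng.uniform(0.1, 100, size=(10, 4))
        track = compute_macc(titration(toy_bins, counts, normalized=True))
        expected = [ols_slope(CONCENTRATIONS, row) for row in counts]
        np.testing.assert_allclose(track.score, expected, atol=1e-9)

    def test_log_base_rescales_by_constant(self, toy_bins):
        rng = np.random.default_rng(1)
        tc = titration(toy_bins, rng.uniform(1, 10, (10, 4)), normalized=True)
        natural = compute_macc(tc).score
        base2 = compute_macc(tc, log_base=2.0).score
        np.testing.assert_allclose(base2, natural * np.log(2.0))


class TestGCCorrect:
    def _scored_bins(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        bins = bin_genome({"chr2": n * 100}, bin_size=100)
        bins.gc = rng.uniform(0.3, 0.7, n)
        return bins, rng

    def test_null_correction_is_nearly_identity(self):
        bins, rng = self._scored_bins()
        track = MACCTrack(bins=bins, score=rng.normal(0, 1, len(bins)))
        corrected = gc_correct(track)
        # scores independent of gc: correction only removes smoother wiggle
        assert np.abs(corrected.score - track.score).max() < 0.5
        assert np.corrcoef(corrected.score, track.score)[0, 1] > 0.95

    def test_removes_injected_gc_trend(self):
        bins, rng = self._scored_bins(seed=1)
        trend = 3.0 * np.sin(2 * np.pi * bins.gc)
        track = MACCTrack(bins=bins, score=rng.normal(0, 0.5, len(bins)) + trend)
        corrected = gc_correct(track)
        assert abs(np.corrcoef(track.score, bins.gc)[0, 1]) > 0.5
        assert abs(np.corrcoef(corrected.score, bins.gc)[0, 1]) < 0.05

    def test_idempotent_up_to_smoother_tolerance(self):
        bins, rng = self._scored_bins(seed=2)
        track = MACCTrack(
            bins=bins, score=rng.normal(0, 0.5, len(bins)) + 2 * bins.gc
        )
        once = gc_correct(track)
        twice = gc_correct(once)
        assert np.abs(twice.score - once.score).max() < 0.1

    def test_refuses_with_too_few_gc_bins(self, toy_bins):
        toy_bins.gc = np.full(10, 0.5)
        track = MACCTrack(bins=toy_bins, score=np.arange(10.0))
        with pytest.warns(UserWarning, match="refused"):
            out = gc_correct(track)
        np.testing.assert_array_equal(out.score, track.score)

    def test_bins_without_gc_pass_through(self):
        bins, rng = self._scored_bins(seed=3)
        bins.gc[::5] = np.nan
        track = MACCTrack(bins=bins, score=rng.normal(0, 1, len(bins)))
        corrected = gc_correct(track)
        np.testing.assert_array_equal(corrected.score[::5], track.score[::5])
        assert corrected.meta["n_gc_missing"] == 100


class TestMedianShiftAndDoubleX:
    def test_median_shift_properties(self, toy_bins):
        rng = np.random.default_rng(0)
        a = MACCTrack(bins=toy_bins, score=rng.normal(2, 1, 10))
        b = MACCTrack(bins=toy_bins, score=rng.normal(-1, 1, 10))
        assert np.median(median_shift(a).score) == 0.0
        np.testing.assert_array_equal(
            median_shift(MACCTrack(bins=toy_bins, score=np.full(10, 3.0))).score,
            np.zeros(10),
        )
        raw_diff = a.score - b.score
        shifted_diff = median_shift(a).score - median_shift(b).score
        np.testing.assert_allclose(np.diff(raw_diff), np.diff(shifted_diff), atol=1e-12)

    def _two_chrom_counts(self):
        bins = bin_genome({"chrX": 500, "chr2": 500}, bin_size=100)
        rng = np.random.default_rng(0)
        return bins, rng.poisson(50, (10, 4)).astype(float)

    def test_x_counts_doubled_before_renormalization(self):
        bins, counts = self._two_chrom_counts()
        tc = titration(bins, counts)
        doubled = double_x_reads(tc, "chrX", renormalize=False)
        np.testing.assert_array_equal(doubled.counts[:5], counts[:5] * 2)
        np.testing.assert_array_equal(doubled.counts[5:], counts[5:])

    def test_unknown_chromosome_rejected(self):
        bins, counts = self._two_chrom_counts()
        with pytest.raises(MACCError, match="chr9"):
            double_x_reads(titration(bins, counts), "chr9")

    def test_requires_raw_counts(self):
        bins, counts = self._two_chrom_counts()
        with pytest.raises(MACCError):
            double_x_reads(normalize_library(titration(bins, counts)), "chrX")

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_slope_invariant_under_uniform_column_scaling(self, scale):
        # CPM normalization cancels any per-column count scaling, so the
        # fitted slope is unchanged — the basis of the X-doubling control.
        bins = bin_genome({"chr2": 1_000}, bin_size=100)
        rng = np.random.default_rng(7)
        counts = rng.poisson(80, (10, 4)).astype(float)
        base = compute_macc(normalize_library(titration(bins, counts))).score
        scaled = compute_macc(normalize_library(titration(bins, counts * scale))).score
        np.testing.assert_allclose(scaled, base, atol=1e-9)
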