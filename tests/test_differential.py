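"""Tests for Δ MACC, the moderated test, classification and summaries."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from macc import intervals
from macc.core import MACCError, MACCTrack, bin_genome
from macc.differential import (
    category_counts,
    chromosome_distribution,
    classify_regions,
    delta_macc,
    direction_fractions,
    moderated_ttest,
    randomized_sites,
)
from macc.differential import test_bins as run_test_bins

from .conftest import make_track


class TestDeltaMacc:
    def test_identical_tracks_give_zero(self, toy_bins):
        t = make_track(toy_bins, np.arange(10.0))
        np.testing.assert_array_equal(delta_macc(t, t), np.zeros(10))

    def test_control_shift_moves_delta(self, toy_bins):
        rnai = make_track(toy_bins, np.arange(10.0))
        control = make_track(toy_bins, np.arange(10.0) + 1.0)
        np.testing.assert_allclose(delta_macc(rnai, control), -1.0)

    def test_antisymmetry(self, toy_bins):
        rng = np.random.default_rng(0)
        a = make_track(toy_bins, rng.normal(size=10))
        b = make_track(toy_bins, rng.normal(size=10))
        np.testing.assert_allclose(delta_macc(a, b), -delta_macc(b, a))

    def test_grid_mismatch_rejected(self, toy_bins):
        other = bin_genome({"chr2": 1_000}, bin_size=200)
        with pytest.raises(MACCError):
            delta_macc(make_track(toy_bins, np.zeros(10)), make_track(other, np.zeros(5)))


class TestModeratedTTest:
    def test_identical_constants_give_p_one(self):
        a = np.full((50, 2), 3.0)
        res = moderated_ttest(a, a)
        np.testing.assert_array_equal(res.p_value, 1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(MACCError):
            moderated_ttest(np.zeros((10, 1)), np.zeros((10, 2)))

    def test_matches_limma_exactly(self):
        """Independent oracle: limma's eBayes moderated t on the same matrix."""
        rng = np.random.default_rng(0)
        n = 300
        sd = np.exp(rng.normal(-1, 0.3, n))
        mu = rng.normal(0, 1, n)
        b = mu[:, None] + rng.normal(0, sd[:, None], (n, 2))
        a = mu[:, None] + rng.normal(0, sd[:, None], (n, 2))
        ours = moderated_ttest(a, b)
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "m.csv"
            out = Path(td) / "out.csv"
            pd.DataFrame(np.hstack([b, a])).to_csv(csv, index=False)
            script = f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{csv}"))
            design <- cbind(Intercept = 1, diff = c(0, 0, 1, 1))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(coef = fit$coefficients[, "diff"],
                                 p = fit$p.value[, "diff"],
                                 d0 = fit$df.prior, s0 = fit$s2.prior),
                      "{out}", row.names = FALSE)
            """
            subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
            limma = pd.read_csv(out)
        np.testing.assert_allclose(ours.delta, limma["coef"], atol=1e-10)
        assert ours.df_prior == pytest.approx(limma["d0"][0], rel=1e-9)
        assert ours.var_prior == pytest.approx(limma["s0"][0], rel=1e-9)
        np.testing.assert_allclose(ours.p_value, limma["p"], atol=1e-10)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        res = moderated_ttest(rng.normal(size=(5_000, 2)), rng.normal(size=(5_000, 2)))
        from scipy.stats import kstest

        assert kstest(res.p_value, "uniform").pvalue > 0.01

    def test_test_bins_requires_shared_grid(self, toy_bins):
        other = bin_genome({"chr2": 1_000}, bin_size=200)
        tracks_a = [make_track(toy_bins, np.zeros(10)) for _ in range(2)]
        tracks_b = [make_track(other, np.zeros(5)) for _ in range(2)]
        with pytest.raises(MACCError):
            run_test_bins(tracks_a, tracks_b)


TOY_GENES = pd.DataFrame(
    [
        {"chrom": "chr2", "start": 1_000, "end": 3_000, "strand": "+", "gene_id": "g1"},
    ]
)
TOY_ENH = pd.DataFrame([{"chrom": "chr2", "pos": 5_050}])


class TestClassifyRegions:
    def _bins(self):
        return bin_genome({"chr2": 10_000}, bin_size=100)

    def classify(self):
        return classify_regions(
            self._bins(), {"genes": TOY_GENES, "enhancer_centers": TOY_ENH}
        )

    def test_upstream_window_is_tss(self):
        cats = self.classify()
        assert cats[6] == "tss_tts"  # bin [600,700), upstream window [500,1000)

    def test_gene_interior_is_body(self):
        assert self.classify()[15] == "gene_body"  # bin [1500,1600)

    def test_enhancer_window(self):
        assert self.classify()[50] == "enhancer"  # bin [5000,5100), center 5050

    def test_remainder_unannotated(self):
        assert self.classify()[90] == "unannotated"

    def test_invalid_gene_rejected(self):
        genes = pd.DataFrame(
            [{"chrom": "chr2", "start": 500, "end": 400, "strand": "+", "gene_id": "bad"}]
        )
        with pytest.raises(MACCError, match="bad"):
            classify_regions(self._bins(), {"genes": genes})

    def test_agrees_with_bruteforce_scan(self):
        """Random toy annotations versus a literal per-midpoint scan."""
        rng = np.random.default_rng(0)
        bins = self._bins()
        for _ in range(10):
            n_genes = rng.integers(1, 5)
            starts = np.sort(rng.choice(np.arange(500, 8_000, 100), n_genes, replace=False))
            genes = pd.DataFrame(
                {
                    "chrom": "chr2",
                    "start": starts,
                    "end": starts + rng.integers(3, 12, n_genes) * 100,
                    "strand": rng.choice(["+", "-"], n_genes),
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                }
            )
            enh = pd.DataFrame({"chrom": "chr2", "pos": rng.choice(9_000, 2)})
            got = classify_regions(bins, {"genes": genes, "enhancer_centers": enh})
            for i, (s, e) in enumerate(zip(bins.start, bins.end)):
                mid = (s + e) // 2
                expected = "unannotated"
                in_tss = any(
                    (g["strand"] == "+" and g["start"] - 500 <= mid < g["start"])
                    or (g["strand"] == "+" and g["end"] <= mid < g["end"] + 500)
                    or (g["strand"] == "-" and g["end"] <= mid < g["end"] + 500)
                    or (g["strand"] == "-" and g["start"] - 500 <= mid < g["start"])
                    for _, g in genes.iterrows()
                )
                if in_tss:
                    expected = "tss_tts"
                elif any(abs(mid - p) <= 500 and mid != p + 500 for p in enh["pos"]):
                    expected = "enhancer" if any(
                        p - 500 <= mid < p + 500 for p in enh["pos"]
                    ) else expected
                    expected = "enhancer"
                elif any(g["start"] <= mid < g["end"] for _, g in genes.iterrows()):
                    expected = "gene_body"
                assert got[i] == expected, f"bin {i} mid {mid}"


class TestCategoryCounts:
    def _diff(self, p_values):
        return pd.DataFrame({"p_value": p_values})

    def test_raw_counts(self):
        cats = np.array(["gene_body"] * 10 + ["enhancer"] * 5, dtype=object)
        p = np.array([0.001] * 10 + [0.5] * 5)
        table = category_counts(self._diff(p), cats).set_index("category")
        assert table.loc["gene_body", "n_significant"] == 10
        assert table["n_significant"].sum() == 10

    def test_zero_threshold_empties_table(self):
        cats = np.array(["gene_body"] * 5, dtype=object)
        table = category_counts(self._diff(np.zeros(5) + 1e-9), cats, p_threshold=0)
        assert table["n_significant"].sum() == 0

    def test_genome_fraction_normalization(self):
        # category covering 10% of the genome with 5 hits scores 50;
        # one covering 50% with 5 hits scores 10
        genes = pd.DataFrame(
            [{"chrom": "chr2", "start": 2_000, "end": 7_000, "strand": "+", "gene_id": "g"}]
        )
        annotation = {"genes": genes}
        sizes = {"chr2": 10_000}
        from macc.differential import category_coverage

        cov = category_coverage(annotation, sizes)
        assert cov["tss_tts"] == 1_000  # 500 bp flanking each gene end
        assert cov["gene_body"] == 5_000  # flanks fall outside the body
        cats = np.array(["gene_body"] * 5 + ["tss_tts"] * 5, dtype=object)
        p = np.full(10, 1e-6)
        table = category_counts(
            self._diff(p), cats, normalize_by_genome_fraction=True,
            annotation=annotation, chrom_sizes=sizes,
        ).set_index("category")
        assert table.loc["tss_tts", "normalized"] == pytest.approx(5 / 0.1)
        assert np.isnan(table.loc["enhancer", "normalized"])


class TestChromosomeDistribution:
    def _tracks(self, x_vals, a_vals):
        bins = bin_genome({"chrX": len(x_vals) * 100, "chr2": len(a_vals) * 100})
        return {"control": make_track(bins, np.concatenate([x_vals, a_vals]))}

    def test_identical_samples_give_p_near_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=500)
        tracks = self._tracks(v, v)
        _, tests = chromosome_distribution(tracks, "chrX")
        assert tests["p_value"].iloc[0] > 0.9

    def test_shifted_x_detected(self):
        rng = np.random.default_rng(1)
        auto = rng.normal(size=1_000)
        tracks = self._tracks(auto + 0.5, auto)
        summary, tests = chromosome_distribution(tracks, "chrX")
        s = summary.set_index("group")
        assert s.loc["X", "median"] - s.loc["autosomes", "median"] == pytest.approx(0.5, abs=1e-9)
        assert tests["p_value"].iloc[0] < 1e-6

    def test_notch_formula_on_1_to_100(self):
        vals = np.arange(1.0, 101.0)
        tracks = self._tracks(vals, vals)
        summary, _ = chromosome_distribution(tracks, "chrX")
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # type-7: 25.75, 75.25
        expected = 1.58 * (q3 - q1) / 10.0
        assert summary.set_index("group").loc["X", "notch_halfwidth"] == pytest.approx(expected)

    def test_empty_group_rejected(self):
        bins = bin_genome({"chr2": 1_000})
        with pytest.raises(MACCError):
            chromosome_distribution({"c": make_track(bins, np.zeros(10))}, "chrX")


class TestDirectionFractions:
    @pytest.mark.parametrize(
        "deltas, expected",
        [
            ([-1, -1, -1, 1], (75.0, 25.0)),
            ([-1, -2, -3], (100.0, 0.0)),
            ([2, 0.5], (0.0, 100.0)),
        ],
    )
    def test_fractions(self, deltas, expected):
        down, up, n_zero = direction_fractions(np.array(deltas, dtype=float))
        assert (down, up) == expected
        assert down + up == 100.0
        assert n_zero == 0

    def test_zeros_reported_separately(self):
        down, up, n_zero = direction_fractions(np.array([0.0, 0.0, -1.0]))
        assert (down, up, n_zero) == (100.0, 0.0, 2)

    def test_empty_rejected(self):
        with pytest.raises(MACCError):
            direction_fractions(np.array([]))


class TestRandomizedSites:
    def _mask(self):
        return pd.DataFrame([{"chrom": "chr2", "start": 200, "end": 800}])

    def test_sites_avoid_mask_and_are_reproducible(self, toy_bins):
        sites = randomized_sites(50, toy_bins, self._mask(), seed=3)
        assert len(sites) == 50
        assert ~(
            (sites["pos"] >= 200) & (sites["pos"] < 800)
        ).any()
        again = randomized_sites(50, toy_bins, self._mask(), seed=3)
        pd.testing.assert_frame_equal(sites, again)

    def test_full_mask_rejected(self, toy_bins):
        mask = pd.DataFrame([{"chrom": "chr2", "start": 0, "end": 1_000}])
        with pytest.raises(MACCError):
            randomized_sites(5, toy_bins, mask, seed=0)


class TestIntervalHelpers:
    def test_merge_subtract_contains(self):
        s, e = intervals.merge([10, 5, 20], [15, 12, 30])
        assert list(s) == [5, 20] and list(e) == [15, 30]
        a = {"c": (np.array([0]), np.array([100]))}
        b = {"c": (np.array([20, 60]), np.array([30, 70]))}
        s2, e2 = intervals.subtract(a, b)["c"]
        assert list(s2) == [0, 30, 70] and list(e2) == [20, 60, 100]
        hits = intervals.contains(b, "c", [19, 20, 29, 30, 65])
        assert hits.tolist() == [False, True, True, False, True]
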