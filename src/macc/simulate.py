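"""Synthetic genome and titration data with known accessibility truth.

The generator emulates the study design end to end: a small genome
(one X chromosome plus autosomes) carrying genes, enhancer centers,
CLAMP-like peaks with occupancy scores, chromatin entry sites (CES,
X-only, subgrouped A/B/C), and a repeat mask; a four-point MNase
titration (1.5U, 6.25U, 25U, 100U) with two replicates per condition;
and three RNAi conditions (control, clamp_rnai, msl2_rnai).

Per bin *b* the expected normalized read frequency at concentration
*c* is linear in ``x = -log c`` (centered over the series)::

    mu_b(c) = beta_b + (a_b + g(GC_b)) * (x_c - mean x)

so the true accessibility slope ``a_b`` is exactly the estimand of the
MACC regression, while ``g(GC)`` injects a smooth technical GC artifact
into the fitted slope that the GC correction should remove.  Under
clamp RNAi the control slope loses an exponentially decaying elevation
around peak anchors (truncated at 3 decay lengths); under msl2 RNAi
the slope is depressed only within a short window of CES centers.

Fragment counts are Poisson around the expected frequencies scaled to
the configured depth; fragment lengths follow a truncated normal
around the 150-bp mononucleosome size.  All randomness flows from one
recorded seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from macc.core import (
    GenomeBins,
    TitrationCounts,
    MACCError,
    bin_genome,
)

CONDITIONS = ("control", "clamp_rnai", "msl2_rnai")

#: CES subgroup sizes on the X at full scale (A: MSL-dependent CLAMP
#: occupancy, B: partially dependent, C: independent)
CES_GROUP_SIZES = {"A": 176, "B": 43, "C": 45}


@dataclass
class SimulationConfig:
    """Tunable parameters of the synthetic study.

    Defaults are the desk-scale study conditions: a 3 x 1 Mb genome,
    four MNase concentrations, two replicates, three conditions, and
    2e6 fragments per sample.
    """

    concentrations: tuple = (1.5, 6.25, 25.0, 100.0)
    n_replicates: int = 2
    bin_size: int = 100
    depth: int = 2_000_000
    chrom_sizes: dict = field(
        default_factory=lambda: {"chrX": 1_000_000, "chr2L": 1_000_000, "chr2R": 1_000_000}
    )
    x_name: str = "chrX"
    n_genes: int = 300
    gene_length_range: tuple = (2_000, 6_000)
    n_enhancers: int = 60
    n_peaks_x: int = 30
    n_peaks_autosome: int = 15  # per autosome
    ces_scale: float = 0.25
    repeat_fraction: float = 0.05
    # accessibility field
    baseline_log_sd: float = 0.2
    slope_sd: float = 0.10
    slope_smooth_bins: int = 5
    peak_bump: float = 0.25
    perturbation_decay_scale: float = 1_000.0  # bp
    decay_truncate: float = 3.0  # kernel zeroed beyond this many decay lengths
    clamp_attenuation: float = 1.0
    msl2_window: float = 200.0  # bp around CES centers
    msl2_effect: float = 0.20
    gc_effect_amplitude: float = 0.08
    noise: str = "poisson"  # "poisson" | "nb" | "none"
    nb_dispersion: float = 0.05
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 15.0
    fragment_length_bounds: tuple = (100, 250)
    # Start-seq
    startseq_baseline_log_mean: float = np.log(100.0)
    startseq_baseline_log_sd: float = 1.0
    startseq_dispersion: float = 0.05
    startseq_frac_perturbed: float = 0.10
    startseq_log2_effect: float = 2.0
    startseq_x_positive_fraction: float = 0.62
    startseq_autosome_positive_fraction: float = 0.50
    # qPCR
    qpcr_input_fraction: float = 0.01
    qpcr_efficiency: float = 2.0
    qpcr_ct_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        conc = list(self.concentrations)
        if len(set(conc)) != len(conc) or any(c <= 0 for c in conc):
            raise MACCError("concentrations must be strictly positive and distinct")
        if self.depth <= 0:
            raise MACCError("depth must be positive")
        if self.qpcr_efficiency <= 1:
            raise MACCError("qPCR amplification efficiency must exceed 1")
        if self.noise not in ("poisson", "nb", "none"):
            raise MACCError(f"unknown noise model {self.noise!r}")


@dataclass
class SyntheticGenome:
    """A toy genome with annotation, anchors and per-bin truth."""

    config: SimulationConfig
    chrom_sizes: dict
    sequences: dict  # chrom -> A/C/G/T string
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id
    enhancer_centers: pd.DataFrame  # chrom, pos
    peaks: pd.DataFrame  # chrom, pos, occupancy
    ces: pd.DataFrame  # chrom, pos, group
    repeat_mask: pd.DataFrame  # chrom, start, end
    bins: GenomeBins
    baseline: np.ndarray  # beta_b per bin
    gc_effect: np.ndarray  # g(GC_b) per bin
    truth: pd.DataFrame  # chrom, start, end, control, clamp_rnai, msl2_rnai
    startseq_truth: pd.DataFrame  # gene_id, baseline_mean, label, log2fc

    @property
    def x_name(self) -> str:
        return self.config.x_name

    def true_slopes(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise MACCError(f"unknown condition {condition!r}")
        return self.truth[condition].to_numpy()


def _rng(config: SimulationConfig, *key) -> np.random.Generator:
    """Independent stream keyed on (seed, purpose...).

    Keys are digested with CRC32, which is stable across processes
    (unlike builtin ``hash`` on strings), so outputs are byte-identical
    for a fixed seed no matter where the generator runs.
    """
    digest = [config.seed] + [zlib.crc32(repr(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(digest))


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def _make_sequences(config, bins, rng) -> tuple[dict, np.ndarray]:
    """Per-chromosome sequences whose GC drifts smoothly along the genome."""
    sequences = {}
    for name, size in config.chrom_sizes.items():
        n_bins = int(np.ceil(size / config.bin_size))
        drift = 0.45 + 0.12 * np.sin(2 * np.pi * np.arange(n_bins) / 200.0)
        drift += _smooth(rng.normal(0, 0.1, n_bins), 25)
        gc_target = np.clip(drift, 0.25, 0.65)
        per_base = np.repeat(gc_target, config.bin_size)[:size]
        u = rng.random(size)
        v = rng.random(size)
        bases = np.where(
            u < per_base,
            np.where(v < 0.5, ord("G"), ord("C")),
            np.where(v < 0.5, ord("A"), ord("T")),
        ).astype(np.uint8)
        sequences[name] = bases.tobytes().decode("ascii")
    gc = np.empty(len(bins))
    for name in config.chrom_sizes:
        sl = bins.chrom_slice(name)
        seq = np.frombuffer(sequences[name].encode(), dtype=np.uint8)
        edges = np.append(bins.start[sl], config.chrom_sizes[name])
        is_gc = (seq == ord("G")) | (seq == ord("C"))
        cum = np.concatenate([[0], np.cumsum(is_gc)])
        gc[sl] = (cum[edges[1:]] - cum[edges[:-1]]) / (edges[1:] - edges[:-1])
    return sequences, gc


def _place_genes(config, rng) -> pd.DataFrame:
    chroms = list(config.chrom_sizes)
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[: config.n_genes % len(chroms)] += 1
    rows = []
    gi = 0
    lo, hi = config.gene_length_range
    for name, n in zip(chroms, per_chrom):
        size = config.chrom_sizes[name]
        slot = size // max(n, 1)
        if slot <= lo:
            raise MACCError(
                f"cannot place {n} genes of >= {lo} bp on {name} ({size} bp)"
            )
        for k in range(n):
            length = int(rng.integers(lo, min(hi, slot - 1) + 1))
            start = int(k * slot + rng.integers(0, slot - length))
            rows.append(
                {
                    "chrom": name,
                    "start": start,
                    "end": start + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "gene_id": f"gene{gi:04d}",
                }
            )
            gi += 1
    return pd.DataFrame(rows)


def _random_positions(rng, size, n, margin=1_000) -> np.ndarray:
    return np.sort(rng.choice(np.arange(margin, size - margin), size=n, replace=False))


def make_genome(config: SimulationConfig | None = None) -> SyntheticGenome:
    """Build a deterministic synthetic genome for a given config/seed."""
    config = config or SimulationConfig()
    config.validate()
    if config.x_name not in config.chrom_sizes:
        raise MACCError(f"X chromosome {config.x_name!r} missing from chrom_sizes")
    if len(config.chrom_sizes) < 3:
        raise MACCError("need one X and at least two autosomes")

    bins = bin_genome(config.chrom_sizes, config.bin_size)
    seq_rng = _rng(config, "sequence")
    sequences, gc = _make_sequences(config, bins, seq_rng)
    bins.gc = gc

    genes = _place_genes(config, _rng(config, "genes"))

    anchor_rng = _rng(config, "anchors")
    peak_rows = []
    for name, size in config.chrom_sizes.items():
        n = config.n_peaks_x if name == config.x_name else config.n_peaks_autosome
        for pos in _random_positions(anchor_rng, size, n):
            peak_rows.append(
                {"chrom": name, "pos": int(pos), "occupancy": float(anchor_rng.lognormal(1.0, 0.6))}
            )
    peaks = pd.DataFrame(peak_rows)

    ces_counts = {g: max(1, round(n * config.ces_scale)) for g, n in CES_GROUP_SIZES.items()}
    n_ces = sum(ces_counts.values())
    x_size = config.chrom_sizes[config.x_name]
    if n_ces > max(0, x_size - 2_000) // 500:
        raise MACCError(f"X chromosome too short for {n_ces} CES")
    ces_pos = _random_positions(anchor_rng, x_size, n_ces)
    groups = np.repeat(list(ces_counts), list(ces_counts.values()))
    anchor_rng.shuffle(groups)
    ces = pd.DataFrame({"chrom": config.x_name, "pos": ces_pos, "group": groups})

    enh_rows = []
    for name, size in config.chrom_sizes.items():
        n = config.n_enhancers // len(config.chrom_sizes)
        enh_rows += [{"chrom": name, "pos": int(p)} for p in _random_positions(anchor_rng, size, n)]
    enhancers = pd.DataFrame(enh_rows)

    mask_rows = []
    mask_rng = _rng(config, "repeats")
    for name, size in config.chrom_sizes.items():
        n_iv = max(1, int(size * config.repeat_fraction / 2_000))
        starts = np.sort(mask_rng.choice(size - 2_000, size=n_iv, replace=False))
        for s in starts:
            mask_rows.append({"chrom": name, "start": int(s), "end": int(s + 2_000)})
    repeat_mask = pd.DataFrame(mask_rows)

    baseline, gc_effect, truth = _make_truth(config, bins, gc, peaks, ces)
    startseq_truth = _make_startseq_truth(config, genes)

    return SyntheticGenome(
        config=config,
        chrom_sizes=dict(config.chrom_sizes),
        sequences=sequences,
        genes=genes,
        enhancer_centers=enhancers,
        peaks=peaks,
        ces=ces,
        repeat_mask=repeat_mask,
        bins=bins,
        baseline=baseline,
        gc_effect=gc_effect,
        truth=truth,
        startseq_truth=startseq_truth,
    )


def _anchor_kernel(bins, anchors, scale, truncate) -> np.ndarray:
    """Sum over anchors of exp(-distance/scale), zeroed beyond truncate*scale."""
    out = np.zeros(len(bins))
    cutoff = truncate * scale
    for chrom, sub in anchors.groupby("chrom", sort=False):
        sl = bins.chrom_slice(chrom)
        centers = bins.centers[sl]
        for pos in sub["pos"].to_numpy():
            d = np.abs(centers - pos)
            near = d <= cutoff
            out[sl][near] += np.exp(-d[near] / scale)
    return out


def _make_truth(config, bins, gc, peaks, ces):
    rng = _rng(config, "field")
    n = len(bins)
    beta = np.exp(rng.normal(0.0, config.baseline_log_sd, n))
    a = rng.normal(0.0, config.slope_sd, n)
    if config.slope_smooth_bins > 1:
        a = _smooth(a, config.slope_smooth_bins)
        a *= config.slope_sd / a.std()

    bump = config.peak_bump * _anchor_kernel(
        bins, peaks, config.perturbation_decay_scale, config.decay_truncate
    )
    x = -np.log(np.asarray(config.concentrations))
    xmax = np.abs(x - x.mean()).max()
    g = config.gc_effect_amplitude * np.sin(2 * np.pi * gc)

    def clip_slope(slope):
        # keep expected frequencies positive at every titration point
        bound = 0.6 * beta / xmax - np.abs(g)
        return np.clip(slope, -bound, bound)

    control = clip_slope(a + bump)
    clamp = clip_slope(a + (1.0 - config.clamp_attenuation) * bump)

    in_window = np.zeros(n, dtype=bool)
    for chrom, sub in ces.groupby("chrom", sort=False):
        sl = bins.chrom_slice(chrom)
        centers = bins.centers[sl]
        for pos in sub["pos"].to_numpy():
            in_window[sl] |= np.abs(centers - pos) <= config.msl2_window
    msl2 = clip_slope(np.where(in_window, control - config.msl2_effect, control))

    truth = bins.to_frame()[["chrom", "start", "end"]]
    truth["control"] = control
    truth["clamp_rnai"] = clamp
    truth["msl2_rnai"] = msl2
    return beta, g, truth


def _make_startseq_truth(config, genes) -> pd.DataFrame:
    rng = _rng(config, "startseq-truth")
    n = len(genes)
    baseline = np.exp(
        rng.normal(config.startseq_baseline_log_mean, config.startseq_baseline_log_sd, n)
    )
    perturbed = rng.random(n) < config.startseq_frac_perturbed
    on_x = (genes["chrom"] == config.x_name).to_numpy()
    p_pos = np.where(
        on_x, config.startseq_x_positive_fraction, config.startseq_autosome_positive_fraction
    )
    # positive regulation: Start-RNA abundance decreases after clamp RNAi
    positive = rng.random(n) < p_pos
    log2fc = np.where(
        perturbed,
        np.where(positive, -config.startseq_log2_effect, config.startseq_log2_effect),
        0.0,
    )
    label = np.where(
        ~perturbed, "unchanged", np.where(positive, "positive_regulation", "negative_regulation")
    )
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": genes["chrom"],
            "baseline_mean": baseline,
            "label": label,
            "log2fc": log2fc,
        }
    )


# ---------------------------------------------------------------------------
# titration sampling


def expected_frequencies(genome: SyntheticGenome, condition: str) -> np.ndarray:
    """Expected (unnormalized) frequency matrix bins x concentrations."""
    config = genome.config
    a_eff = genome.true_slopes(condition) + genome.gc_effect
    x = -np.log(np.asarray(config.concentrations))
    xc = x - x.mean()
    mu = genome.baseline[:, None] + a_eff[:, None] * xc[None, :]
    return np.maximum(mu, 1e-9)


def simulate_titration_counts(
    genome: SyntheticGenome, condition: str, replicate: int
) -> TitrationCounts:
    """Draw per-bin fragment counts for one sample (all concentrations)."""
    config = genome.config
    mu = expected_frequencies(genome, condition)
    p = mu / mu.sum(axis=0, keepdims=True)
    lam = p * config.depth
    if config.noise == "none":
        counts = lam
    else:
        rng = _rng(config, "titration", condition, replicate)
        if config.noise == "poisson":
            counts = rng.poisson(lam).astype(float)
        else:  # negative binomial: var = mu + phi mu^2
            phi = config.nb_dispersion
            r = 1.0 / phi
            counts = rng.negative_binomial(r, r / (r + lam)).astype(float)
    return TitrationCounts(
        bins=genome.bins,
        concentrations=list(config.concentrations),
        counts=counts,
        normalized=False,
        condition=condition,
        replicate=replicate,
    )


def counts_to_fragments(
    genome: SyntheticGenome, tc: TitrationCounts, concentration
) -> pd.DataFrame:
    """Expand one concentration column into sorted BED-like fragments.

    Midpoints are uniform within each bin; lengths are drawn from a
    truncated Normal(150, 15) on [100, 250] bp, so the default MACC
    size window retains essentially all fragments.
    """
    config = genome.config
    rng = _rng(config, "fragments", tc.condition, tc.replicate, float(concentration))
    col = tc.column(concentration).astype(np.int64)
    frames = []
    lo, hi = config.fragment_length_bounds
    a = (lo - config.fragment_length_mean) / config.fragment_length_sd
    b = (hi - config.fragment_length_mean) / config.fragment_length_sd
    for chrom in genome.chrom_sizes:
        sl = genome.bins.chrom_slice(chrom)
        k = col[sl]
        n = int(k.sum())
        if n == 0:
            continue
        bin_start = np.repeat(genome.bins.start[sl], k)
        bin_len = np.repeat((genome.bins.end - genome.bins.start)[sl], k)
        mid = bin_start + rng.random(n) * bin_len
        length = scipy.stats.truncnorm.rvs(
            a, b, loc=config.fragment_length_mean, scale=config.fragment_length_sd,
            size=n, random_state=rng,
        )
        length = np.round(length).astype(np.int64)
        start = np.round(mid - length / 2).astype(np.int64)
        start = np.clip(start, 0, genome.chrom_sizes[chrom] - length)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
        )
    frags = pd.concat(frames, ignore_index=True)
    return frags.sort_values(["chrom", "start", "end"], kind="stable", ignore_index=True)


def simulate_titration(
    genome: SyntheticGenome, condition: str, replicate: int, include_fragments: bool = True
):
    """Simulate one sample: counts plus (optionally) per-concentration fragments.

    Returns
    -------
    (TitrationCounts, dict | None)
        Raw counts and, when requested, a dict mapping concentration to
        a sorted fragment DataFrame (chrom, start, end).
    """
    tc = simulate_titration_counts(genome, condition, replicate)
    if not include_fragments:
        return tc, None
    frags = {c: counts_to_fragments(genome, tc, c) for c in genome.config.concentrations}
    return tc, frags


# ---------------------------------------------------------------------------
# Start-seq and qPCR


def simulate_startseq(
    genome: SyntheticGenome, condition: str, replicate: int
) -> pd.DataFrame:
    """Per-gene nascent-RNA (Start-seq) counts at the observed TSS.

    Counts are negative binomial around the gene's baseline mean,
    scaled by the condition's true fold change; ``startseq_dispersion``
    of zero falls back to Poisson.
    """
    if condition not in CONDITIONS:
        raise MACCError(f"unknown condition {condition!r}")
    config = genome.config
    truth = genome.startseq_truth
    mean = truth["baseline_mean"].to_numpy().copy()
    if condition == "clamp_rnai":
        mean = mean * 2.0 ** truth["log2fc"].to_numpy()
    rng = _rng(config, "startseq", condition, replicate)
    phi = config.startseq_dispersion
    if phi <= 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mean))
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "chrom": truth["chrom"],
            "condition": condition,
            "replicate": replicate,
            "count": counts,
        }
    )


def simulate_qpcr(
    design: pd.DataFrame,
    true_log2fe: dict,
    config: SimulationConfig | None = None,
    n_replicates: int = 3,
    control_locus: str = "cg15570",
) -> pd.DataFrame:
    """Generate a long-format ChIP-qPCR Ct table from true enrichments.

    ``design`` needs columns (locus, condition); ``true_log2fe`` maps
    (locus, condition) to the true log2 fold enrichment over the
    internal-control locus.  Cts are built by inverting the
    percent-input model (IP percent input of the control locus fixed
    at 1%), with Gaussian cycle noise of ``qpcr_ct_noise_sd``.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = _rng(config, "qpcr")
    f = config.qpcr_input_fraction
    if not (0 < f <= 1):
        raise MACCError("input_fraction must lie in (0, 1]")
    dilution = np.log2(1.0 / f)
    rows = []
    pi_control = 1.0  # percent input at the internal-control locus
    for _, row in design.iterrows():
        locus, condition = row["locus"], row["condition"]
        log2fe = float(true_log2fe[(locus, condition)])
        for rep in range(1, n_replicates + 1):
            for role, pi in (
                ("target", pi_control * 2.0**log2fe),
                ("internal_control", pi_control),
            ):
                ct_input = 25.0 + rng.normal(0, config.qpcr_ct_noise_sd)
                ct_ip = ct_input - dilution - np.log2(pi / 100.0)
                ct_ip += rng.normal(0, config.qpcr_ct_noise_sd)
                locus_id = locus if role == "target" else control_locus
                for template, ct in (("IP", ct_ip), ("input", ct_input)):
                    rows.append(
                        {
                            "locus": locus,
                            "amplicon": locus_id,
                            "role": role,
                            "template": template,
                            "condition": condition,
                            "replicate": rep,
                            "Ct": float(ct),
                            "input_fraction": f,
                        }
                    )
    return pd.DataFrame(rows)
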