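"""Differential accessibility between RNAi conditions.

Per-bin Δ (RNAi − control), an empirical-Bayes moderated two-sample
t-test across replicates, feature classification of changed bins,
chromosome-level distribution summaries (X vs autosomes), direction
fractions, and randomized-site controls.

The moderated test shrinks each bin's pooled variance toward a common
prior variance; the prior degrees of freedom are estimated by method
of moments on the log sample variances, so a handful of replicates
per condition still yields stable per-bin inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from macc import intervals
from macc.core import GenomeBins, MACCTrack, MACCError

CATEGORIES = ("tss_tts", "enhancer", "gene_body", "unannotated")


@dataclass
class ModeratedTestResult:
    """Per-feature moderated two-sample test (RNAi vs control)."""

    delta: np.ndarray  # mean(rnai) - mean(control)
    t: np.ndarray
    p_value: np.ndarray
    df_prior: float
    var_prior: float
    df_total: float


def delta_macc(rnai: MACCTrack, control: MACCTrack) -> np.ndarray:
    """Per-bin accessibility change, RNAi minus control."""
    if not rnai.bins.same_grid(control.bins):
        raise MACCError("tracks are on different bin grids")
    return rnai.score - control.score


def moderated_ttest(group_a: np.ndarray, group_b: np.ndarray) -> ModeratedTestResult:
    """Moderated two-sample t-test per row (a − b), equal-variance design.

    ``group_a``/``group_b`` are features x replicates matrices.  The
    per-row pooled variance ``s2`` (df = n_a + n_b − 2) is shrunk toward
    a prior ``s0^2`` with weight ``d0`` estimated from the spread of
    ``log s2``: under the scaled-F model,
    ``var(log s2) = trigamma(df/2) + trigamma(d0/2)``, solved for d0 by
    inverting the trigamma; the moderated statistic has df + d0 degrees
    of freedom.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise MACCError("need at least two replicates per condition")
    df = na + nb - 2
    delta = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((a.var(axis=1, ddof=1) * (na - 1)) + (b.var(axis=1, ddof=1) * (nb - 1))) / df

    pos = s2 > 0
    if pos.sum() < 2:
        # degenerate: no variance information at all
        t = np.where(delta == 0, 0.0, np.sign(delta) * np.inf)
        p = np.where(delta == 0, 1.0, 0.0)
        return ModeratedTestResult(delta, t, p, np.inf, 0.0, np.inf)

    z = np.log(s2[pos])
    e_z, var_z = z.mean(), z.var(ddof=1)
    excess = var_z - scipy.special.polygamma(1, df / 2.0)
    if excess <= 1e-8:
        d0 = np.inf
        log_s0 = e_z - scipy.special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            e_z
            - scipy.special.polygamma(0, df / 2.0)
            + np.log(df / 2.0)
            + scipy.special.polygamma(0, d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    s0_2 = float(np.exp(log_s0))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    if np.isinf(df_total):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
    return ModeratedTestResult(delta, t, np.clip(p, 0.0, 1.0), float(d0), s0_2, df_total)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations, limma-style)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = scipy.special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / scipy.special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def test_bins(
    control_reps: list, rnai_reps: list, with_fdr: bool = True
) -> pd.DataFrame:
    """Per-bin moderated test of MACC change between replicate sets.

    Returns a frame with chrom/start/end, delta (RNAi − control),
    t, p_value and (optionally) a BH-adjusted q_value column.
    """
    grids = [t.bins for t in control_reps + rnai_reps]
    if not all(g.same_grid(grids[0]) for g in grids):
        raise MACCError("replicate tracks are on different bin grids")
    ctrl = np.column_stack([t.score for t in control_reps])
    rnai = np.column_stack([t.score for t in rnai_reps])
    res = moderated_ttest(rnai, ctrl)
    bins = control_reps[0].bins
    out = bins.to_frame()[["chrom", "start", "end"]]
    out["delta"] = res.delta
    out["t"] = res.t
    out["p_value"] = res.p_value
    if with_fdr:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(res.p_value, method="fdr_bh")[1]
    out.attrs["df_prior"] = res.df_prior
    out.attrs["var_prior"] = res.var_prior
    return out


# ---------------------------------------------------------------------------
# feature classification


def _gene_windows(genes: pd.DataFrame, flank: int = 500):
    """Strand-aware TSS-upstream and TTS-downstream windows."""
    bad = genes["end"] < genes["start"]
    if bad.any():
        raise MACCError(f"gene(s) with end < start: {genes.loc[bad, 'gene_id'].tolist()}")
    recs = []
    for _, g in genes.iterrows():
        if g["strand"] == "-":
            upstream = (g["chrom"], g["end"], g["end"] + flank)
            downstream = (g["chrom"], max(0, g["start"] - flank), g["start"])
        else:
            upstream = (g["chrom"], max(0, g["start"] - flank), g["start"])
            downstream = (g["chrom"], g["end"], g["end"] + flank)
        recs += [upstream, downstream]
    return recs


def _category_interval_sets(annotation, flank: int = 500):
    genes = annotation["genes"]
    enhancers = annotation.get("enhancer_centers")
    tss_tts = intervals.build(_gene_windows(genes, flank))
    enh_recs = []
    if enhancers is not None and len(enhancers):
        enh_recs = [
            (r["chrom"], max(0, r["pos"] - flank), r["pos"] + flank)
            for _, r in enhancers.iterrows()
        ]
    enh = intervals.build(enh_recs)
    body = intervals.build(
        [(r["chrom"], r["start"], r["end"]) for _, r in genes.iterrows()]
    )
    return {"tss_tts": tss_tts, "enhancer": enh, "gene_body": body}


def classify_regions(bins: GenomeBins, annotation: dict, flank: int = 500) -> np.ndarray:
    """Assign each bin (by midpoint) to a feature category.

    Precedence: TSS/TTS-proximal (±``flank`` bp strand-aware of gene
    ends) > enhancer (±``flank`` bp of centers) > gene body >
    unannotated.  ``annotation`` maps "genes" to a strand-aware gene
    frame and optionally "enhancer_centers" to (chrom, pos).
    """
    sets = _category_interval_sets(annotation, flank)
    category = np.full(len(bins), "unannotated", dtype=object)
    mid = (bins.start + bins.end) // 2
    for chrom in bins.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        m = mid[sl]
        assigned = np.zeros(len(m), dtype=bool)
        for name in ("tss_tts", "enhancer", "gene_body"):
            hit = intervals.contains(sets[name], chrom, m) & ~assigned
            category[sl][hit] = name
            assigned |= hit
    return category


def category_coverage(annotation: dict, chrom_sizes: dict, flank: int = 500) -> dict:
    """Bp of genome per category under the classification precedence."""
    sets = _category_interval_sets(annotation, flank)
    genome = intervals.build([(c, 0, s) for c, s in chrom_sizes.items()])
    for name in sets:  # clip to chromosome bounds
        sets[name] = intervals.subtract(genome, intervals.subtract(genome, sets[name]))
    tss = sets["tss_tts"]
    enh = intervals.subtract(sets["enhancer"], tss)
    body = intervals.subtract(intervals.subtract(sets["gene_body"], tss), sets["enhancer"])
    covered = {
        "tss_tts": intervals.total_length(tss),
        "enhancer": intervals.total_length(enh),
        "gene_body": intervals.total_length(body),
    }
    covered["unannotated"] = sum(chrom_sizes.values()) - sum(covered.values())
    return covered


def category_counts(
    diff: pd.DataFrame,
    category: np.ndarray,
    p_threshold: float = 0.01,
    normalize_by_genome_fraction: bool = False,
    annotation: dict | None = None,
    chrom_sizes: dict | None = None,
    flank: int = 500,
) -> pd.DataFrame:
    """Count significant bins per feature category.

    With ``normalize_by_genome_fraction`` each count is divided by the
    fraction of the genome (merged, non-double-counted bp under the
    classification precedence) covered by its category; categories with
    zero coverage report NaN rather than infinity.
    """
    sig = diff["p_value"].to_numpy() < p_threshold
    rows = []
    for name in CATEGORIES:
        rows.append({"category": name, "n_significant": int((sig & (category == name)).sum())})
    table = pd.DataFrame(rows)
    if normalize_by_genome_fraction:
        if annotation is None or chrom_sizes is None:
            raise MACCError("normalization requires annotation and chrom_sizes")
        cov = category_coverage(annotation, chrom_sizes, flank)
        total = sum(chrom_sizes.values())
        frac = np.array([cov[name] / total for name in CATEGORIES])
        with np.errstate(divide="ignore", invalid="ignore"):
            table["genome_fraction"] = frac
            table["normalized"] = np.where(
                frac > 0, table["n_significant"] / frac, np.nan
            )
    return table


# ---------------------------------------------------------------------------
# chromosome-level summaries


def _notch(values: np.ndarray) -> float:
    """Half-width of the 95% notch: 1.58 * IQR / sqrt(n) (type-7 quartiles)."""
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return 1.58 * (q3 - q1) / np.sqrt(len(values))


def chromosome_distribution(
    tracks_by_condition: dict, x_name: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution summaries of MACC by chromosome group and condition.

    Returns (summary, tests): per (condition, group in {X, autosomes,
    all}) the n/median/quartiles/notch half-width, plus two-sided
    Mann-Whitney p-values for X vs autosomes within each condition and
    for every condition pair within each group.
    """
    rows, test_rows = [], []
    groups: dict = {}
    for condition, track in tracks_by_condition.items():
        on_x = track.bins.chrom == x_name
        if on_x.sum() == 0 or (~on_x).sum() == 0:
            raise MACCError("empty chromosome group")
        split = {
            "X": track.score[on_x],
            "autosomes": track.score[~on_x],
            "all": track.score,
        }
        groups[condition] = split
        for name, vals in split.items():
            q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "condition": condition,
                    "group": name,
                    "n": len(vals),
                    "median": q2,
                    "q1": q1,
                    "q3": q3,
                    "notch_halfwidth": _notch(vals),
                }
            )
        mw = scipy.stats.mannwhitneyu(split["X"], split["autosomes"], alternative="two-sided")
        test_rows.append(
            {
                "comparison": f"{condition}: X vs autosomes",
                "p_value": mw.pvalue,
            }
        )
    conditions = list(tracks_by_condition)
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1 :]:
            for name in ("X", "autosomes", "all"):
                mw = scipy.stats.mannwhitneyu(
                    groups[c1][name], groups[c2][name], alternative="two-sided"
                )
                test_rows.append(
                    {"comparison": f"{name}: {c1} vs {c2}", "p_value": mw.pvalue}
                )
    summary = pd.DataFrame(rows)
    summary.attrs["notch_convention"] = "1.58*IQR/sqrt(n), type-7 quartiles"
    return summary, pd.DataFrame(test_rows)


def direction_fractions(gene_deltas: np.ndarray) -> tuple[float, float, int]:
    """Percent of genes decreasing / increasing in accessibility.

    Percentages are over genes with nonzero Δ; the count of exact
    zeros is returned separately.
    """
    deltas = np.asarray(gene_deltas, dtype=float)
    if deltas.size == 0:
        raise MACCError("empty gene set")
    nonzero = deltas[deltas != 0]
    n_zero = int((deltas == 0).sum())
    if nonzero.size == 0:
        return 0.0, 0.0, n_zero
    pct_down = 100.0 * (nonzero < 0).sum() / nonzero.size
    return float(pct_down), float(100.0 - pct_down), n_zero


def randomized_sites(
    n: int, bins: GenomeBins, repeat_mask: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Uniform random positions over the non-repetitive genome."""
    masked = intervals.build(
        [(r["chrom"], r["start"], r["end"]) for _, r in repeat_mask.iterrows()]
    )
    genome = intervals.build([(c, 0, s) for c, s in bins.chrom_sizes.items()])
    free = intervals.subtract(genome, masked)
    lengths = []
    keys = []
    for chrom, (s, e) in free.items():
        for a, b in zip(s, e):
            keys.append((chrom, a))
            lengths.append(b - a)
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.sum() == 0:
        raise MACCError("repeat mask covers the whole genome")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, lengths.sum(), size=n)
    cum = np.cumsum(lengths)
    idx = np.searchsorted(cum, offsets, side="right")
    rows = []
    for o, i in zip(offsets, idx):
        chrom, start = keys[i]
        prev = cum[i - 1] if i > 0 else 0
        rows.append({"chrom": chrom, "pos": int(start + (o - prev))})
    return pd.DataFrame(rows).sort_values(["chrom", "pos"], ignore_index=True)
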