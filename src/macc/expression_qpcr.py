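"""Nascent-transcription (Start-seq) differential analysis and ChIP-qPCR math.

Start-seq counts nascent RNAs at engaged-Pol-II positions; observed
TSS (obsTSS) are re-derived from the 5'-end signal rather than taken
from annotation.  Differential abundance between RNAi conditions uses
the same moderated two-sample statistic as the accessibility module
on CPM-normalized log counts; "positive regulation" means a decrease
in Start-RNA abundance after clamp RNAi.

qPCR enrichment follows the percent-input convention: Ct values are
converted to percent of input (adjusting the input Ct for its
dilution, e.g. log2(100) cycles for a 1% input), internally normalized
to an unbound control locus, and reported as log2 fold enrichment with
replicate SEM and a between-condition t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from macc.core import MACCError
from macc.differential import moderated_ttest
from macc.profiles import split_by_score


def define_obstss(
    start_reads: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 250
) -> pd.DataFrame:
    """Locate the observed TSS of each gene from 5'-end read signal.

    ``start_reads`` holds stranded 5'-end positions with per-position
    counts (chrom, pos, strand, count).  The obsTSS is the position of
    maximum summed signal on the gene's strand within ±``window_bp``
    of the annotated start (strand-aware); ties take the lower
    coordinate; genes with zero signal in the window are excluded.
    """
    if "strand" not in start_reads.columns:
        raise MACCError("start reads must carry a strand column")
    rows = []
    by_key = {
        key: sub.sort_values("pos")
        for key, sub in start_reads.groupby(["chrom", "strand"], sort=False)
    }
    for _, g in genes.iterrows():
        anno_start = g["end"] - 1 if g["strand"] == "-" else g["start"]
        sub = by_key.get((g["chrom"], g["strand"]))
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, anno_start - window_bp, side="left")
        hi = np.searchsorted(pos, anno_start + window_bp, side="right")
        if hi <= lo:
            continue
        window_pos = pos[lo:hi]
        window_counts = sub["count"].to_numpy()[lo:hi]
        if window_counts.sum() == 0:
            continue
        best = window_pos[np.argmax(window_counts)]  # argmax takes first => lower pos
        rows.append(
            {
                "gene_id": g["gene_id"],
                "chrom": g["chrom"],
                "pos": int(best),
                "strand": g["strand"],
            }
        )
    return pd.DataFrame(rows)


def differential_start(
    counts: pd.DataFrame,
    control: str = "control",
    rnai: str = "clamp_rnai",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated differential test of Start-RNA abundance per obsTSS.

    ``counts`` is a frame with obsTSS metadata columns (gene_id, chrom)
    and one count column per (condition, replicate) named
    ``"{condition}_rep{k}"``.  Counts are CPM-normalized per column and
    log(x+1)-transformed before testing.  Direction at ``alpha``:
    positive_regulation = significant decrease after RNAi.
    obsTSS with zero counts in every sample are excluded.
    """
    ctrl_cols = [c for c in counts.columns if c.startswith(f"{control}_rep")]
    rnai_cols = [c for c in counts.columns if c.startswith(f"{rnai}_rep")]
    if len(ctrl_cols) < 2 or len(rnai_cols) < 2:
        raise MACCError("need at least two replicates per condition")
    mat = counts[ctrl_cols + rnai_cols].to_numpy(dtype=float)
    nonzero = mat.sum(axis=1) > 0
    kept = counts.loc[nonzero].reset_index(drop=True)
    mat = mat[nonzero]
    cpm = mat / mat.sum(axis=0, keepdims=True) * 1e6
    logc = np.log(cpm + 1.0)
    nc = len(ctrl_cols)
    res = moderated_ttest(logc[:, nc:], logc[:, :nc])
    out = kept[[c for c in ("gene_id", "chrom", "pos", "strand") if c in kept.columns]].copy()
    out["log_change"] = res.delta
    out["p_value"] = res.p_value
    sig = res.p_value < alpha
    out["direction"] = np.where(
        ~sig,
        "unchanged",
        np.where(res.delta < 0, "positive_regulation", "negative_regulation"),
    )
    out.attrs["alpha"] = alpha
    out.attrs["n_excluded_zero"] = int((~nonzero).sum())
    return out


def regulation_summary(tested: pd.DataFrame, chrom_groups: dict | None = None) -> pd.DataFrame:
    """Per-chromosome percentages of changed / up- / down-regulated obsTSS.

    ``chrom_groups`` optionally maps extra group names (e.g. "X",
    "autosomes") to lists of chromosome names; individual chromosomes
    are always reported.  Percentages are rounded to one decimal;
    direction splits are over the significant set and undefined (NaN)
    when nothing changed.
    """
    groups = {chrom: [chrom] for chrom in tested["chrom"].unique()}
    groups["all"] = list(tested["chrom"].unique())
    if chrom_groups:
        groups.update(chrom_groups)
    rows = []
    for name, chroms in groups.items():
        sub = tested[tested["chrom"].isin(chroms)]
        if len(sub) == 0:
            continue
        changed = sub["direction"] != "unchanged"
        n_sig = int(changed.sum())
        row = {
            "group": name,
            "n_total": len(sub),
            "n_changed": n_sig,
            "pct_changed": round(100.0 * n_sig / len(sub), 1),
        }
        if n_sig:
            pos = int((sub["direction"] == "positive_regulation").sum())
            row["pct_positive"] = round(100.0 * pos / n_sig, 1)
            row["pct_negative"] = round(100.0 * (n_sig - pos) / n_sig, 1)
        else:
            row["pct_positive"] = np.nan
            row["pct_negative"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def expression_quartiles(control_counts: pd.DataFrame, value_cols: list) -> np.ndarray:
    """Q1 (lowest) … Q4 (highest) labels from mean control abundance."""
    means = control_counts[value_cols].mean(axis=1).to_numpy()
    return split_by_score(control_counts.index, means, mode="quartiles")


# ---------------------------------------------------------------------------
# qPCR


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """Percent of input recovered in the IP for one amplicon.

    The input Ct is first adjusted by ``log2(1/input_fraction)`` cycles
    to represent 100% input, assuming perfect per-cycle doubling.
    """
    if not (0 < input_fraction <= 1):
        raise MACCError("input_fraction must lie in (0, 1]")
    adjusted = ct_input - np.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def qpcr_enrichment(records: pd.DataFrame) -> pd.DataFrame:
    """Per-locus log2 fold enrichment over the internal-control locus.

    ``records`` is long-format with columns (locus, role in
    {target, internal_control}, template in {IP, input}, condition,
    replicate, Ct, input_fraction).  Per replicate,
    ``log2FE = log2(percent_input(target) / percent_input(control))``;
    replicate values are averaged with SEM, and a two-sided two-sample
    t-test compares conditions per locus when two are present.
    """
    required = {"locus", "role", "template", "condition", "replicate", "Ct", "input_fraction"}
    missing = required - set(records.columns)
    if missing:
        raise MACCError(f"qPCR table is missing columns: {sorted(missing)}")
    per_rep = []
    for (locus, condition, rep), sub in records.groupby(
        ["locus", "condition", "replicate"], sort=False
    ):
        pis = {}
        for role in ("target", "internal_control"):
            r = sub[sub["role"] == role]
            ip = r[r["template"] == "IP"]
            inp = r[r["template"] == "input"]
            if len(ip) == 0 or len(inp) == 0:
                raise MACCError(
                    f"missing IP or input Ct for {locus}/{condition}/rep{rep}/{role}"
                )
            pis[role] = percent_input(
                ip["Ct"].mean(), inp["Ct"].mean(), float(inp["input_fraction"].iloc[0])
            )
        per_rep.append(
            {
                "locus": locus,
                "condition": condition,
                "replicate": rep,
                "log2_fold_enrichment": np.log2(pis["target"] / pis["internal_control"]),
            }
        )
    per_rep = pd.DataFrame(per_rep)
    rows = []
    for (locus, condition), sub in per_rep.groupby(["locus", "condition"], sort=False):
        vals = sub["log2_fold_enrichment"].to_numpy()
        rows.append(
            {
                "locus": locus,
                "condition": condition,
                "log2_fold_enrichment": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                "n_replicates": len(vals),
            }
        )
    summary = pd.DataFrame(rows)
    tests = []
    for locus, sub in per_rep.groupby("locus", sort=False):
        conds = sub["condition"].unique()
        if len(conds) == 2:
            a = sub.loc[sub["condition"] == conds[0], "log2_fold_enrichment"]
            b = sub.loc[sub["condition"] == conds[1], "log2_fold_enrichment"]
            t = scipy.stats.ttest_ind(a, b)
            tests.append(
                {
                    "locus": locus,
                    "comparison": f"{conds[0]} vs {conds[1]}",
                    "t": t.statistic,
                    "p_value": t.pvalue,
                }
            )
    summary.attrs["condition_tests"] = pd.DataFrame(tests)
    return summary


def relative_abundance(ct_target: np.ndarray, ct_reference: np.ndarray) -> float:
    """ΔCt relative abundance, ``2^(Ct_ref − Ct_target)``.

    Technical-replicate Cts are averaged *before* the power transform.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if ct_target.size == 0 or ct_reference.size == 0 or ct_target.size != ct_reference.size:
        raise MACCError("need equally many paired target and reference Cts")
    return float(2.0 ** (ct_reference.mean() - ct_target.mean()))
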