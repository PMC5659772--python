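"""Readers and writers for the text formats the pipeline speaks.

BED/bedGraph coordinates are 0-based half-open.  All writers accept
``.gz`` paths (compression inferred from the extension by pandas; the
FASTA writer handles gzip itself).
"""

from __future__ import annotations

import gzip
import json

import numpy as np
import pandas as pd

from macc.core import GenomeBins, MACCError, MACCTrack

BED3 = ["chrom", "start", "end"]


def _opener(path, mode="wt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


# ---------------------------------------------------------------------------
# fragments


def read_fragments(path, fmt: str | None = None) -> pd.DataFrame:
    """Read fragments as (chrom, start, end) from BED or SAM/BAM.

    For SAM/BAM a fragment is the outer span of a properly paired
    template (taken from the leftmost mate's TLEN); orphan mates are
    skipped and counted in ``df.attrs["n_orphans"]``.  Output is
    sorted by (chrom, start, end).
    """
    path = str(path)
    if fmt is None:
        fmt = "sam_bam" if path.endswith((".sam", ".bam", ".cram")) else "bed"
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=BED3, dtype={0: str, 1: np.int64, 2: np.int64},
        )
        bad = df["end"] <= df["start"]
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise MACCError(
                f"{path}: line {i + 1}: end <= start "
                f"({df.loc[i, 'chrom']}:{df.loc[i, 'start']}-{df.loc[i, 'end']})"
            )
        df.attrs["n_orphans"] = 0
    elif fmt == "sam_bam":
        import pysam

        rows = []
        n_orphans = 0
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if not rec.is_proper_pair:
                    n_orphans += 1
                    continue
                tlen = rec.template_length
                if tlen <= 0:  # count each pair once, from the leftmost mate
                    continue
                rows.append((rec.reference_name, rec.reference_start, rec.reference_start + tlen))
        df = pd.DataFrame(rows, columns=BED3)
        df.attrs["n_orphans"] = n_orphans
    else:
        raise MACCError(f"unknown fragment format {fmt!r}")
    return df.sort_values(BED3, kind="stable", ignore_index=True)


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    fragments[BED3].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# tracks


def write_bedgraph(track: MACCTrack, path, merge: bool = True, precision: int = 6) -> None:
    """Write a binned track as 4-column bedGraph (sorted input required).

    Adjacent bins with equal rounded values are merged into one line
    when ``merge`` is set.
    """
    bins = track.bins
    order_ok = all(
        np.all(np.diff(bins.start[bins.chrom_slice(c)]) > 0) for c in bins.chrom_sizes
    )
    if not order_ok:
        raise MACCError("track bins are not sorted")
    vals = np.round(track.score, precision)
    with _opener(path) as fh:
        for chrom in bins.chrom_sizes:
            sl = bins.chrom_slice(chrom)
            s, e, v = bins.start[sl], bins.end[sl], vals[sl]
            if merge and len(s):
                breaks = np.flatnonzero(v[1:] != v[:-1]) + 1
                seg_start = np.concatenate([[0], breaks])
                seg_end = np.concatenate([breaks, [len(v)]])
                for a, b in zip(seg_start, seg_end):
                    fh.write(f"{chrom}\t{s[a]}\t{e[b - 1]}\t{v[a]:.{precision}f}\n")
            else:
                for a in range(len(s)):
                    fh.write(f"{chrom}\t{s[a]}\t{e[a]}\t{v[a]:.{precision}f}\n")


def read_bedgraph(path, bins: GenomeBins) -> MACCTrack:
    """Read a bedGraph onto an existing bin grid (inverse of the writer)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    score = np.zeros(len(bins))
    for chrom, sub in df.groupby("chrom", sort=False):
        sl = bins.chrom_slice(chrom)
        starts = bins.start[sl]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            i0 = np.searchsorted(starts, s)
            i1 = np.searchsorted(starts, e, side="left")
            score[sl.start + i0 : sl.start + i1] = v
    return MACCTrack(bins=bins, score=score)


# ---------------------------------------------------------------------------
# genome pieces


def write_chrom_sizes(chrom_sizes: dict, path) -> None:
    with _opener(path) as fh:
        for name, size in chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with _opener(path) as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genes_bed12(genes: pd.DataFrame, path) -> None:
    """Single-block BED12 records, one per gene."""
    with _opener(path) as fh:
        for _, g in genes.iterrows():
            length = g["end"] - g["start"]
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g["chrom"], g["start"], g["end"], g["gene_id"], 0, g["strand"],
                        g["start"], g["end"], "0,0,0", 1, f"{length},", "0,",
                    )
                )
                + "\n"
            )


def read_genes_bed(path) -> pd.DataFrame:
    """Genes from BED6/BED12 (first six columns used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise MACCError(f"{path}: need at least 6 BED columns for stranded genes")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    return df[["chrom", "start", "end", "strand", "gene_id"]].astype(
        {"chrom": str, "start": np.int64, "end": np.int64}
    )


def write_anchors_bed(anchors: pd.DataFrame, path, extra: str | None = None) -> None:
    """Point anchors as 1-bp BED; ``extra`` column lands in the score slot
    (numeric, e.g. occupancy) or the name slot (labels, e.g. CES group)."""
    with _opener(path) as fh:
        for _, a in anchors.iterrows():
            name, score = ".", 0
            if extra is not None:
                value = a[extra]
                if isinstance(value, (int, float, np.floating, np.integer)):
                    score = value
                else:
                    name = value
            strand = a.get("strand", ".")
            fh.write(f"{a['chrom']}\t{a['pos']}\t{a['pos'] + 1}\t{name}\t{score}\t{strand}\n")


def read_anchors_bed(path, extra: str | None = None, extra_slot: str = "score") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({"chrom": df[0].astype(str), "pos": df[1].astype(np.int64)})
    if df.shape[1] >= 6:
        out["strand"] = df[5]
    if extra is not None:
        col = 4 if extra_slot == "score" else 3
        out[extra] = df[col]
    return out


def write_mask_bed(mask: pd.DataFrame, path) -> None:
    mask[BED3].to_csv(path, sep="\t", header=False, index=False)


def read_mask_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED3, usecols=[0, 1, 2])


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(meta: dict, path) -> None:
    with _opener(path) as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
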