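"""Anchor-relative averaging of MACC and read-frequency tracks.

Signals live on 100-bp bins; profiles sample them on a 10-bp offset
grid by linear interpolation between bin centers, average over
anchors (strand-aware), attach a pointwise 95% normal-approximation
confidence band, and lightly smooth the averaged curves with a
running window.  Metagene profiles rescale each gene body to a fixed
number of positions with flanks kept in real bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from macc.core import MACCError, MACCTrack, TitrationCounts, CPM_CONSTANT


@dataclass
class Profile:
    """Averaged anchor-relative signal with a 95% CI band."""

    offsets: np.ndarray  # bp (site profiles) or scaled position (metagene)
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_sites: int
    signal: str = "MACC"
    smoothing_bp: float = 10.0
    meta: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_sites": self.n_sites,
            }
        )


def _interp_track(track: MACCTrack, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Linear interpolation of a binned track at bp positions.

    Bin values are anchored at bin centers; positions beyond the first
    or last center clamp to the edge value.
    """
    sl = track.bins.chrom_slice(chrom)
    return np.interp(positions, track.bins.centers[sl], track.score[sl])


def _site_matrix(track, anchors: pd.DataFrame, offsets: np.ndarray):
    """Rows of interpolated signal per retained anchor (strand-flipped)."""
    rows = []
    n_dropped = 0
    flank = max(abs(offsets[0]), abs(offsets[-1]))
    for chrom, sub in anchors.groupby("chrom", sort=False):
        size = track.bins.chrom_sizes.get(chrom)
        if size is None:
            raise MACCError(f"anchors on unknown chromosome {chrom!r}")
        for _, rec in sub.iterrows():
            pos = rec["pos"]
            if pos - flank < 0 or pos + flank > size:
                n_dropped += 1
                continue
            off = offsets if rec.get("strand", "+") != "-" else -offsets
            rows.append(_interp_track(track, chrom, pos + off))
    return np.asarray(rows), n_dropped


def _running_mean(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    # reflect edges so the window average is defined everywhere
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(values)]
    return out


def _summarize(matrix: np.ndarray, offsets, signal, step, smoothing_bp, meta=None) -> Profile:
    n = matrix.shape[0]
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    half = 1.96 * sd / np.sqrt(n)
    window = max(1, int(round(smoothing_bp / step)))
    mean_s = _running_mean(mean, window)
    lo = _running_mean(mean - half, window)
    hi = _running_mean(mean + half, window)
    return Profile(
        offsets=np.asarray(offsets, dtype=float),
        mean=mean_s,
        ci_low=lo,
        ci_high=hi,
        n_sites=n,
        signal=signal,
        smoothing_bp=smoothing_bp,
        meta=meta,
    )


def site_profile(
    track: MACCTrack,
    anchors: pd.DataFrame,
    flank_bp: int,
    step: int = 10,
    smoothing_bp: float = 10.0,
    signal: str = "MACC",
) -> Profile:
    """Average signal on a symmetric offset grid around point anchors.

    ``anchors`` needs columns (chrom, pos) and may carry a strand
    column; minus-strand anchors contribute mirror-image rows.  Anchors
    whose flank extends past a chromosome end are dropped (count kept
    in ``meta``).  The 95% CI is mean ± 1.96·sd/√n across sites.
    """
    if len(anchors) == 0:
        raise MACCError("empty anchor set")
    offsets = np.arange(-flank_bp, flank_bp + step, step)
    matrix, n_dropped = _site_matrix(track, anchors, offsets)
    if matrix.size == 0:
        raise MACCError("no anchors remain after edge filtering")
    return _summarize(
        matrix, offsets, signal, step, smoothing_bp, meta={"n_edge_dropped": n_dropped}
    )


def metagene_profile(
    track: MACCTrack,
    genes: pd.DataFrame,
    n_body_bins: int = 100,
    flank_bp: int = 500,
    step: int = 10,
    smoothing_bp: float = 10.0,
) -> Profile:
    """Scaled gene-body profile: fixed-bp flanks, body rescaled.

    Offsets run −flank..0 (upstream, bp), 0..n_body_bins (body,
    scaled units plotted as bin index), then n_body_bins..+flank bp
    downstream; minus-strand genes are flipped so transcription always
    runs left to right.
    """
    matrix, offsets = _metagene_matrix(track, genes, n_body_bins, flank_bp, step)
    if matrix.size == 0:
        raise MACCError("no gene long enough for a metagene profile")
    return _summarize(matrix, offsets, "MACC", 1, smoothing_bp / step, meta=None)


def _metagene_matrix(track, genes, n_body_bins, flank_bp, step):
    up = np.arange(-flank_bp, 0, step, dtype=float) / step  # upstream, in steps
    body = np.linspace(0, n_body_bins, n_body_bins + 1)
    down = n_body_bins + np.arange(step, flank_bp + step, step, dtype=float) / step
    offsets = np.concatenate([up, body, down])
    rows = []
    for _, g in genes.iterrows():
        size = track.bins.chrom_sizes.get(g["chrom"])
        if size is None:
            raise MACCError(f"gene on unknown chromosome {g['chrom']!r}")
        start, end = g["start"], g["end"]
        if end - start < n_body_bins or start - flank_bp < 0 or end + flank_bp > size:
            continue
        body_pos = np.linspace(start, end, n_body_bins + 1)
        up_pos = start + np.arange(-flank_bp, 0, step)
        down_pos = end + np.arange(step, flank_bp + step, step)
        pos = np.concatenate([up_pos, body_pos, down_pos])
        vals = _interp_track(track, g["chrom"], pos)
        if g.get("strand", "+") == "-":
            vals = vals[::-1]
        rows.append(vals)
    return np.asarray(rows), offsets


def heatmap_matrix(
    track_or_rows,
    genes: pd.DataFrame,
    order_by: str,
    keys: np.ndarray | None = None,
    n_body_bins: int = 100,
) -> pd.DataFrame:
    """Per-gene scaled-body signal rows in a declared order.

    ``order_by`` is ``"chip_occupancy"`` (descending occupancy; ``keys``
    required) or ``"delta_magnitude"`` (strongest decrease first, keyed
    on the row mean when ``keys`` is not given).  Ties keep input
    order.  Returns a frame indexed by gene id with an ``order_key``
    column followed by the body positions.
    """
    if isinstance(track_or_rows, MACCTrack):
        rows = []
        kept = []
        for _, g in genes.iterrows():
            if g["end"] - g["start"] < n_body_bins:
                continue
            pos = np.linspace(g["start"], g["end"], n_body_bins + 1)
            vals = _interp_track(track_or_rows, g["chrom"], pos)
            if g.get("strand", "+") == "-":
                vals = vals[::-1]
            rows.append(vals)
            kept.append(g["gene_id"])
        matrix = np.asarray(rows)
        ids = kept
    else:
        matrix = np.asarray(track_or_rows, dtype=float)
        ids = list(genes["gene_id"])
        if matrix.shape[0] != len(ids):
            raise MACCError("row count does not match gene count")

    if order_by == "chip_occupancy":
        if keys is None:
            raise MACCError("chip_occupancy ordering requires per-gene keys")
        order = np.argsort(-np.asarray(keys, dtype=float), kind="stable")
    elif order_by == "delta_magnitude":
        key_vals = np.asarray(keys, dtype=float) if keys is not None else matrix.mean(axis=1)
        order = np.argsort(key_vals, kind="stable")  # most negative (decrease) first
        keys = key_vals
    else:
        raise MACCError(f"unknown ordering {order_by!r}")
    keys = np.asarray(keys, dtype=float)
    if np.isnan(keys).any():
        missing = [ids[i] for i in np.flatnonzero(np.isnan(keys))]
        raise MACCError(f"missing ordering key for rows: {missing}")
    out = pd.DataFrame(matrix[order], index=[ids[i] for i in order])
    out.insert(0, "order_key", keys[order])
    out.attrs["order_by"] = order_by
    return out


def split_by_score(items, scores, mode: str = "quartiles") -> np.ndarray:
    """Label items by rank groups of a score (ties stay low).

    ``halves``: bottom ceil(n/2) = "low", rest "high".  ``quartiles``:
    labels Q1 (lowest) … Q4 (highest) with boundaries at positions
    floor(n·k/4) of the stable ascending order; items tied with a
    boundary score remain in the lower group.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        raise MACCError("empty input")
    if len(list(items)) != n:
        raise MACCError("items and scores differ in length")
    if np.all(scores == scores[0]):
        warnings.warn("all scores equal: single degenerate group", stacklevel=2)
        return np.full(n, "low" if mode == "halves" else "Q1", dtype=object)
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    if mode == "halves":
        cut = -(-n // 2)  # ceil(n/2) items in the low group
        labels = np.where(ranks < cut, "low", "high").astype(object)
        boundaries = [cut]
        names = ["low", "high"]
    elif mode == "quartiles":
        edges = [n * k // 4 for k in (1, 2, 3)]
        labels = np.empty(n, dtype=object)
        group_of_rank = np.digitize(ranks, edges, right=False)
        names = ["Q1", "Q2", "Q3", "Q4"]
        labels[:] = [names[g] for g in group_of_rank]
        boundaries = edges
    else:
        raise MACCError(f"unknown mode {mode!r}")
    # ties at a boundary stay with the lower group
    sorted_scores = scores[order]
    for b in boundaries:
        if 0 < b < n and sorted_scores[b] == sorted_scores[b - 1]:
            tied = scores == sorted_scores[b - 1]
            low_label = labels[order[b - 1]]
            labels[tied & (ranks >= b)] = low_label
    return labels


def read_frequency_profile(
    tc: TitrationCounts,
    anchors: pd.DataFrame,
    flank_bp: int,
    step: int = 10,
    smoothing_bp: float = 10.0,
) -> dict:
    """One read-frequency profile per MNase concentration.

    Counts should come from the nucleosome-sized fragment window
    (140–160 bp); columns are CPM-normalized if they are not already.
    The lowest concentration's profile is flagged as the
    accessible-chromatin view in its metadata.
    """
    counts = tc.counts
    if not tc.normalized:
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            raise MACCError("zero-total concentration column")
        counts = counts / totals * CPM_CONSTANT
    lowest = min(tc.concentrations)
    out = {}
    for j, conc in enumerate(tc.concentrations):
        track = MACCTrack(bins=tc.bins, score=counts[:, j], condition=tc.condition)
        prof = site_profile(
            track, anchors, flank_bp, step=step, smoothing_bp=smoothing_bp,
            signal="read frequency",
        )
        prof.meta = dict(prof.meta or {}, concentration=conc,
                         accessible_view=(conc == lowest))
        out[conc] = prof
    return out
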