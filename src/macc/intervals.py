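"""Half-open interval arithmetic on per-chromosome coordinate arrays.

All coordinates are 0-based half-open, matching BED.  Intervals are
kept as parallel ``(start, end)`` numpy arrays per chromosome; the
helpers here merge, subtract and query them without any external
genomic-ranges dependency.
"""

from __future__ import annotations

import numpy as np

# an interval set is dict[chrom] -> (starts, ends), both int64, sorted, merged
IntervalSet = dict


def merge(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent half-open intervals; returns sorted arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_length(iset: IntervalSet) -> int:
    """Summed bp covered by a merged interval set."""
    return int(sum((e - s).sum() for s, e in iset.values()))


def build(records) -> IntervalSet:
    """Build a merged interval set from an iterable of (chrom, start, end)."""
    by_chrom: dict[str, list] = {}
    for chrom, s, e in records:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in by_chrom.items():
        s = np.array([i[0] for i in ivs], dtype=np.int64)
        e = np.array([i[1] for i in ivs], dtype=np.int64)
        out[chrom] = merge(s, e)
    return out


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set difference a \\ b of merged interval sets."""
    out = {}
    for chrom, (sa, ea) in a.items():
        if chrom not in b:
            out[chrom] = (sa.copy(), ea.copy())
            continue
        sb, eb = b[chrom]
        rs, re = [], []
        for s, e in zip(sa, ea):
            cur = s
            # b intervals overlapping [s, e)
            i = np.searchsorted(eb, cur, side="right")
            while i < len(sb) and sb[i] < e:
                if sb[i] > cur:
                    rs.append(cur)
                    re.append(sb[i])
                cur = max(cur, eb[i])
                i += 1
            if cur < e:
                rs.append(cur)
                re.append(e)
        out[chrom] = (np.array(rs, dtype=np.int64), np.array(re, dtype=np.int64))
    return out


def contains(iset: IntervalSet, chrom: str, pos) -> np.ndarray:
    """Vectorized membership test of positions in a merged interval set."""
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    if chrom not in iset or iset[chrom][0].size == 0:
        return np.zeros(pos.shape, dtype=bool)
    s, e = iset[chrom]
    idx = np.searchsorted(s, pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(pos.shape, dtype=bool)
    hit[ok] = pos[ok] < e[idx[ok]]
    return hit
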