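"""Per-bin MACC scoring from MNase titration fragment data.

Pipeline: tile the genome into fixed-size bins, discard fragments that
start at hotspot positions (per-position fragment-start count with
Z >= 7 against the covered-position mean), count retained fragments per
bin by midpoint, normalize each concentration column to counts per
million, fit an ordinary least-squares line of normalized frequency
against ``-log(concentration)`` per bin, and correct the resulting
slope track for GC composition with a local regression.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CPM_CONSTANT = 1_000_000.0

#: fragment length windows (bp, inclusive) used in the analyses
MACC_SIZE_RANGE = (100, 200)
NUCLEOSOME_SIZE_RANGE = (140, 160)


class MACCError(ValueError):
    """Raised on contract violations in the MACC pipeline."""


@dataclass
class GenomeBins:
    """Non-overlapping bins tiling a genome.

    Attributes
    ----------
    chrom_sizes : dict
        Ordered mapping chromosome name -> length (bp).
    chrom, start, end : ndarray
        Per-bin coordinates, sorted, tiling each chromosome; the last
        bin of a chromosome may be shorter than ``bin_size``.
    gc : ndarray or None
        GC fraction in [0, 1] per bin, NaN where undefined (all-N bin);
        None when no sequence was supplied.
    """

    chrom_sizes: dict
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    bin_size: int
    gc: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.start)

    @property
    def centers(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def chrom_slice(self, name: str) -> slice:
        idx = np.flatnonzero(self.chrom == name)
        if idx.size == 0:
            raise MACCError(f"chromosome {name!r} not in bin grid")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bin_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Map positions on one chromosome to global bin indices."""
        sl = self.chrom_slice(chrom)
        local = np.minimum(
            np.asarray(pos, dtype=np.int64) // self.bin_size,
            sl.stop - sl.start - 1,
        )
        return sl.start + local

    def same_grid(self, other: "GenomeBins") -> bool:
        return (
            self.chrom_sizes == other.chrom_sizes
            and self.bin_size == other.bin_size
            and len(self) == len(other)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})
        if self.gc is not None:
            df["gc"] = self.gc
        return df


@dataclass
class HotspotMask:
    """Per-position exclusion mask from the hotspot filter."""

    positions: dict  # chrom -> sorted int64 array of masked positions
    z_threshold: float
    n_masked: int
    n_covered: int

    @property
    def fraction_masked(self) -> float:
        return self.n_masked / self.n_covered if self.n_covered else 0.0

    def is_masked(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        masked = self.positions.get(chrom)
        if masked is None or masked.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(masked, pos)
        ok = idx < masked.size
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = masked[idx[ok]] == pos[ok]
        return out


@dataclass
class TitrationCounts:
    """Fragment counts (or CPM frequencies) per bin and MNase concentration."""

    bins: GenomeBins
    concentrations: list
    counts: np.ndarray  # bins x concentrations
    normalized: bool = False
    condition: str = ""
    replicate: int = 0
    size_range: tuple = MACC_SIZE_RANGE

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.bins), len(self.concentrations)):
            raise MACCError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.bins)} bins x {len(self.concentrations)} concentrations"
            )
        if len(set(self.concentrations)) != len(self.concentrations) or any(
            c <= 0 for c in self.concentrations
        ):
            raise MACCError("concentrations must be positive and distinct")

    def column(self, concentration) -> np.ndarray:
        return self.counts[:, self.concentrations.index(concentration)]


@dataclass
class MACCTrack:
    """Per-bin accessibility score for one sample.

    ``score`` has units of normalized frequency per unit -log
    concentration; positive values mark accessible chromatin.
    """

    bins: GenomeBins
    score: np.ndarray
    gc_corrected: bool = False
    n_concentrations: int = 0
    condition: str = ""
    replicate: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if len(self.score) != len(self.bins):
            raise MACCError("score length does not match bin grid")
        if not np.all(np.isfinite(self.score)):
            raise MACCError("MACC scores must be finite")

    def chrom_values(self, name: str) -> np.ndarray:
        return self.score[self.bins.chrom_slice(name)]


def bin_genome(chrom_sizes: dict, bin_size: int = 100, fasta=None) -> GenomeBins:
    """Tile each chromosome with ``bin_size`` bins; optionally attach GC.

    Parameters
    ----------
    chrom_sizes : dict
        Ordered chromosome name -> length (bp), all positive.
    fasta : str, pyfaidx.Fasta, or dict, optional
        Sequence source used to compute per-bin GC fraction over non-N
        bases (NaN for all-N bins).  A dict of name -> sequence string
        is accepted for in-memory genomes.
    """
    if any(size <= 0 for size in chrom_sizes.values()):
        raise MACCError("chromosome sizes must be positive")
    chroms, starts, ends = [], [], []
    for name, size in chrom_sizes.items():
        s = np.arange(0, size, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, size)
        chroms.append(np.full(len(s), name, dtype=object))
        starts.append(s)
        ends.append(e)
    bins = GenomeBins(
        chrom_sizes=dict(chrom_sizes),
        chrom=np.concatenate(chroms),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        bin_size=bin_size,
    )
    if fasta is not None:
        bins.gc = _gc_per_bin(bins, fasta)
    return bins


def _get_sequences(fasta, names):
    if isinstance(fasta, dict):
        seqs = fasta
    else:
        import pyfaidx

        fa = fasta if isinstance(fasta, pyfaidx.Fasta) else pyfaidx.Fasta(str(fasta))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    missing = [n for n in names if n not in seqs]
    if missing:
        raise MACCError(f"FASTA is missing chromosomes: {missing}")
    return seqs


def _gc_per_bin(bins: GenomeBins, fasta) -> np.ndarray:
    seqs = _get_sequences(fasta, list(bins.chrom_sizes))
    gc = np.full(len(bins), np.nan)
    for name, size in bins.chrom_sizes.items():
        seq = seqs[name].upper()
        if len(seq) != size:
            raise MACCError(
                f"sequence length {len(seq)} for {name!r} does not match "
                f"declared size {size}"
            )
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_base = is_gc | (arr == ord("A")) | (arr == ord("T"))
        sl = bins.chrom_slice(name)
        edges = np.append(bins.start[sl], size)
        gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
        base_cum = np.concatenate([[0], np.cumsum(is_base)])
        gc_counts = gc_cum[edges[1:]] - gc_cum[edges[:-1]]
        base_counts = base_cum[edges[1:]] - base_cum[edges[:-1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            gc[sl] = np.where(base_counts > 0, gc_counts / np.maximum(base_counts, 1), np.nan)
    return gc


def filter_hotspots(fragments: pd.DataFrame, z_threshold: float = 7.0) -> HotspotMask:
    """Identify positions with abnormally many fragment starts.

    The Z-score of each covered position's fragment-start count is taken
    against the mean and SD over all positions with at least one start
    in this sample; positions at or above ``z_threshold`` are masked and
    fragments starting there are discarded downstream.
    """
    positions: dict = {}
    all_counts = []
    per_chrom = []
    for chrom, sub in fragments.groupby("chrom", sort=False):
        pos, counts = np.unique(sub["start"].to_numpy(np.int64), return_counts=True)
        per_chrom.append((chrom, pos, counts))
        all_counts.append(counts)
    if not all_counts:
        return HotspotMask(positions={}, z_threshold=z_threshold, n_masked=0, n_covered=0)
    counts_all = np.concatenate(all_counts)
    mean, sd = counts_all.mean(), counts_all.std()
    n_masked = 0
    if sd == 0:
        warnings.warn("uniform per-position coverage: no hotspots masked", stacklevel=2)
    else:
        for chrom, pos, counts in per_chrom:
            z = (counts - mean) / sd
            hot = pos[z >= z_threshold]
            if hot.size:
                positions[chrom] = hot
                n_masked += hot.size
    return HotspotMask(
        positions=positions,
        z_threshold=z_threshold,
        n_masked=n_masked,
        n_covered=int(counts_all.size),
    )


def count_fragments(
    fragments: pd.DataFrame,
    bins: GenomeBins,
    size_range: tuple = MACC_SIZE_RANGE,
    mask: HotspotMask | None = None,
) -> np.ndarray:
    """Count fragments per bin by midpoint (one column of a titration).

    Fragments outside ``size_range`` (inclusive, bp) or starting at a
    masked hotspot position are dropped.  Each retained fragment lands
    in exactly one bin, so the column total equals the retained count.
    """
    counts = np.zeros(len(bins))
    lo, hi = size_range
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in bins.chrom_sizes:
            raise MACCError(f"fragment on unknown chromosome {chrom!r}")
        start = sub["start"].to_numpy(np.int64)
        end = sub["end"].to_numpy(np.int64)
        beyond = end > bins.chrom_sizes[chrom]
        if beyond.any():
            i = int(np.flatnonzero(beyond)[0])
            raise MACCError(
                f"fragment {chrom}:{start[i]}-{end[i]} extends beyond "
                f"chromosome end {bins.chrom_sizes[chrom]}"
            )
        length = end - start
        keep = (length >= lo) & (length <= hi)
        if mask is not None:
            keep &= ~mask.is_masked(chrom, start)
        if not keep.any():
            continue
        mid = (start[keep] + end[keep]) // 2
        idx = bins.bin_index(chrom, mid)
        counts += np.bincount(idx, minlength=len(bins))
    return counts


def normalize_library(tc: TitrationCounts) -> TitrationCounts:
    """Scale each concentration column to counts per million of its total."""
    if tc.normalized:
        raise MACCError("counts are already library-normalized")
    totals = tc.counts.sum(axis=0)
    if np.any(totals == 0):
        bad = [c for c, t in zip(tc.concentrations, totals) if t == 0]
        raise MACCError(f"zero fragment total for concentration(s) {bad}")
    return replace(tc, counts=tc.counts / totals * CPM_CONSTANT, normalized=True)


def compute_macc(tc: TitrationCounts, log_base: float | None = None) -> MACCTrack:
    """Fit the per-bin accessibility slope across the titration.

    For each bin the score is the OLS slope of normalized frequency
    against ``x = -log(concentration)`` (natural log by default; any
    base rescales all scores by a constant).  High frequency at low
    MNase concentration — open chromatin — gives a positive slope.
    """
    if not tc.normalized:
        raise MACCError("compute_macc requires library-normalized counts")
    if len(tc.concentrations) < 2:
        raise MACCError("need at least two distinct concentrations to fit a slope")
    x = -np.log(np.asarray(tc.concentrations, dtype=float))
    if log_base is not None:
        x = x / np.log(log_base)
    xc = x - x.mean()
    slope = tc.counts @ xc / (xc @ xc)
    return MACCTrack(
        bins=tc.bins,
        score=slope,
        gc_corrected=False,
        n_concentrations=len(tc.concentrations),
        condition=tc.condition,
        replicate=tc.replicate,
    )


def gc_correct(
    track: MACCTrack,
    gc: np.ndarray | None = None,
    span: float = 0.3,
    min_bins: int = 100,
) -> MACCTrack:
    """Remove the GC-composition trend from a score track.

    The expected score as a function of bin GC is estimated by LOWESS
    over all scored bins (span 0.3); the corrected score is
    ``raw - fitted + mean(raw)`` so the genome-wide mean is preserved.
    Bins without a GC value pass through uncorrected.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    gc = track.bins.gc if gc is None else np.asarray(gc, dtype=float)
    if gc is None:
        raise MACCError("no GC fractions available for correction")
    ok = np.isfinite(gc)
    if ok.sum() < min_bins:
        warnings.warn(
            f"only {int(ok.sum())} bins have GC values (<{min_bins}); "
            "GC correction refused",
            stacklevel=2,
        )
        return replace(track)
    x, y = gc[ok], track.score[ok]
    delta = 0.005 * (x.max() - x.min())
    fitted = lowess(y, x, frac=span, delta=delta, return_sorted=False)
    corrected = track.score.copy()
    corrected[ok] = y - fitted + y.mean()
    new = replace(track, score=corrected, gc_corrected=True)
    new.meta = dict(track.meta, gc_span=span, n_gc_missing=int((~ok).sum()))
    return new


def median_shift(track: MACCTrack) -> MACCTrack:
    """Shift scores so the genome-wide median is zero (per-sample)."""
    return replace(track, score=track.score - np.median(track.score))


def double_x_reads(tc: TitrationCounts, x_name: str, renormalize: bool = True) -> TitrationCounts:
    """Double raw counts on the X chromosome, then renormalize.

    Compensates for the single X in male cells versus two copies of
    each autosome; under uniform per-column scaling the fitted slopes
    off the X are unchanged after renormalization.
    """
    if tc.normalized:
        raise MACCError("double_x_reads requires raw (unnormalized) counts")
    if x_name not in tc.bins.chrom_sizes:
        raise MACCError(f"unknown chromosome {x_name!r}")
    counts = tc.counts.copy()
    counts[tc.bins.chrom_slice(x_name)] *= 2.0
    doubled = replace(tc, counts=counts)
    return normalize_library(doubled) if renormalize else doubled
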