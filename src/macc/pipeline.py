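"""End-to-end driver: simulate -> score -> differential -> profiles.

Every run writes its outputs plus a ``metadata.json`` carrying the
seed, the package version and a hash of the resolved configuration,
and is byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import macc.io as mio
from macc import __version__
from macc.core import (
    MACCError,
    MACCTrack,
    TitrationCounts,
    bin_genome,
    compute_macc,
    count_fragments,
    filter_hotspots,
    gc_correct,
    normalize_library,
)
from macc.differential import (
    category_counts,
    chromosome_distribution,
    classify_regions,
    delta_macc,
    direction_fractions,
    test_bins,
)
from macc.profiles import metagene_profile, site_profile
from macc.simulate import CONDITIONS, SimulationConfig, make_genome, simulate_titration


class RunConfig:
    """Validated pipeline configuration (YAML-backed).

    Sections: ``simulate`` (SimulationConfig overrides) or ``inputs``
    (paths to fragments/annotation for real data), plus ``score``,
    ``differential`` and ``profiles`` parameter blocks.
    """

    def __init__(self, data: dict):
        self.data = dict(data)
        self.seed = int(data.get("seed", 0))
        self.simulate = data.get("simulate")
        self.inputs = data.get("inputs")
        score = data.get("score", {})
        self.bin_size = int(score.get("bin_size", 100))
        self.z_threshold = float(score.get("z_threshold", 7.0))
        self.size_range = tuple(score.get("size_range", (100, 200)))
        diff = data.get("differential", {})
        self.p_threshold = float(diff.get("p_threshold", 0.01))
        prof = data.get("profiles", {})
        self.peak_flank = int(prof.get("peak_flank", 10_000))
        self.ces_flank = int(prof.get("ces_flank", 500))
        self.metagene_flank = int(prof.get("metagene_flank", 500))
        self.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise MACCError("config needs exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            for key in ("fragments", "chrom_sizes", "genes"):
                if key not in self.inputs:
                    raise MACCError(f"inputs section is missing required key {key!r}")
        if not (0 < self.p_threshold < 1):
            raise MACCError("p_threshold must lie in (0, 1)")

    def simulation_config(self) -> SimulationConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("bin_size", self.bin_size)
        if "chrom_sizes" in overrides:
            overrides["chrom_sizes"] = dict(overrides["chrom_sizes"])
        return SimulationConfig(**overrides)

    def hash(self) -> str:
        canonical = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _score_sample(frag_frames: dict, bins, concentrations, config: RunConfig,
                  condition: str, replicate: int):
    """Hotspot-filter, bin, normalize and fit one titration sample."""
    columns = []
    mask_fractions = []
    for conc in concentrations:
        frags = frag_frames[conc]
        mask = filter_hotspots(frags, z_threshold=config.z_threshold)
        mask_fractions.append(mask.fraction_masked)
        columns.append(count_fragments(frags, bins, size_range=config.size_range, mask=mask))
    tc = TitrationCounts(
        bins=bins,
        concentrations=list(concentrations),
        counts=np.column_stack(columns),
        condition=condition,
        replicate=replicate,
    )
    track = compute_macc(normalize_library(tc))
    if bins.gc is not None:
        track = gc_correct(track)
    track.meta["hotspot_fraction"] = float(np.mean(mask_fractions))
    return track


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is None:
        raise MACCError(
            "file-based inputs are scored via the CLI stage commands; "
            "run_pipeline drives the simulated study"
        )

    sim = config.simulation_config()
    genome = make_genome(sim)

    gdir = out / "genome"
    gdir.mkdir(exist_ok=True)
    mio.write_fasta(genome.sequences, gdir / "genome.fa")
    mio.write_chrom_sizes(genome.chrom_sizes, gdir / "chrom.sizes")
    mio.write_genes_bed12(genome.genes, gdir / "genes.bed12")
    mio.write_anchors_bed(genome.peaks, gdir / "peaks.bed", extra="occupancy")
    mio.write_anchors_bed(genome.ces, gdir / "ces.bed", extra="group")
    mio.write_anchors_bed(genome.enhancer_centers, gdir / "enhancers.bed")
    mio.write_mask_bed(genome.repeat_mask, gdir / "repeats.bed")
    mio.write_table(genome.truth, gdir / "truth.tsv")

    fdir = out / "fragments"
    tracks: dict = {c: [] for c in CONDITIONS}
    for condition in CONDITIONS:
        for rep in range(1, sim.n_replicates + 1):
            _, frags = simulate_titration(genome, condition, rep)
            sdir = fdir / f"{condition}_rep{rep}"
            sdir.mkdir(parents=True, exist_ok=True)
            for conc, df in frags.items():
                mio.write_fragments_bed(df, sdir / f"{conc:g}U.bed")
            track = _score_sample(
                frags, genome.bins, sim.concentrations, config, condition, rep
            )
            tracks[condition].append(track)

    tdir = out / "tracks"
    tdir.mkdir(exist_ok=True)
    mean_tracks = {}
    for condition, reps in tracks.items():
        for track in reps:
            mio.write_bedgraph(
                track, tdir / f"{condition}_rep{track.replicate}.macc.bedGraph"
            )
        mean_tracks[condition] = MACCTrack(
            bins=genome.bins,
            score=np.mean([t.score for t in reps], axis=0),
            gc_corrected=True,
            condition=condition,
        )
        mio.write_bedgraph(mean_tracks[condition], tdir / f"{condition}.mean.macc.bedGraph")

    ddir = out / "differential"
    ddir.mkdir(exist_ok=True)
    annotation = {"genes": genome.genes, "enhancer_centers": genome.enhancer_centers}
    category = classify_regions(genome.bins, annotation)
    for rnai in ("clamp_rnai", "msl2_rnai"):
        diff = test_bins(tracks["control"], tracks[rnai])
        sig = diff["p_value"] < config.p_threshold
        diff["direction"] = np.where(
            ~sig, "unchanged", np.where(diff["delta"] < 0, "down", "up")
        )
        diff["category"] = category
        mio.write_table(diff, ddir / f"{rnai}_vs_control.tsv")
        cats = category_counts(
            diff, category, p_threshold=config.p_threshold,
            normalize_by_genome_fraction=True,
            annotation=annotation, chrom_sizes=genome.chrom_sizes,
        )
        mio.write_table(cats, ddir / f"{rnai}_categories.tsv")
        gene_delta = _per_gene_delta(mean_tracks[rnai], mean_tracks["control"], genome)
        down, up, n_zero = direction_fractions(gene_delta["delta"].to_numpy())
        mio.write_table(
            pd.DataFrame(
                [{"pct_decrease": down, "pct_increase": up, "n_zero": n_zero}]
            ),
            ddir / f"{rnai}_direction_fractions.tsv",
        )
    summary, tests = chromosome_distribution(mean_tracks, genome.x_name)
    mio.write_table(summary, ddir / "chromosome_summary.tsv")
    mio.write_table(tests, ddir / "chromosome_tests.tsv")

    pdir = out / "profiles"
    pdir.mkdir(exist_ok=True)
    peak_flank = min(config.peak_flank, min(genome.chrom_sizes.values()) // 4)
    for condition, track in mean_tracks.items():
        prof = site_profile(track, genome.peaks, flank_bp=peak_flank)
        mio.write_table(prof.to_frame(), pdir / f"{condition}_peaks.tsv")
        prof = site_profile(track, genome.ces, flank_bp=config.ces_flank)
        mio.write_table(prof.to_frame(), pdir / f"{condition}_ces.tsv")
        meta = metagene_profile(track, genome.genes, flank_bp=config.metagene_flank)
        mio.write_table(meta.to_frame(), pdir / f"{condition}_metagene.tsv")

    mio.write_metadata(
        {
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": config.data,
            "version": __version__,
            "conditions": list(CONDITIONS),
            "n_replicates": sim.n_replicates,
            "concentrations": list(sim.concentrations),
        },
        out / "metadata.json",
    )
    return out


def _per_gene_delta(rnai: MACCTrack, control: MACCTrack, genome) -> pd.DataFrame:
    """Mean Δ over gene-body bins, one row per gene."""
    delta = delta_macc(rnai, control)
    bins = rnai.bins
    mid = (bins.start + bins.end) // 2
    rows = []
    for _, g in genome.genes.iterrows():
        sl = bins.chrom_slice(g["chrom"])
        inside = (mid[sl] >= g["start"]) & (mid[sl] < g["end"])
        if not inside.any():
            continue
        rows.append({"gene_id": g["gene_id"], "delta": float(delta[sl][inside].mean())})
    return pd.DataFrame(rows)


def _as_serializable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return obj
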