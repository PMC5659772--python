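"""Shared study configuration for the analysis drivers.

Desk-scale version of the study: three 200-kb chromosomes (one X),
four MNase concentrations, two replicates of control / clamp_rnai /
msl2_rnai at 2e5 fragments per concentration.
"""

from pathlib import Path

from macc.simulate import SimulationConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def study_config(**overrides) -> SimulationConfig:
    base = dict(
        chrom_sizes={"chrX": 200_000, "chr2L": 200_000, "chr2R": 200_000},
        depth=200_000,
        n_genes=60,
        n_enhancers=15,
        n_peaks_x=8,
        n_peaks_autosome=4,
        seed=SEED,
    )
    base.update(overrides)
    return SimulationConfig(**base)
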