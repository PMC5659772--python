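import numpy as np
import pytest
from hypothesis import settings

from macc.core import GenomeBins, MACCTrack, bin_genome
from macc.simulate import SimulationConfig, make_genome

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

TINY_SIZES = {"chrX": 60_000, "chr2L": 60_000, "chr2R": 60_000}


def tiny_config(**overrides) -> SimulationConfig:
    base = dict(
        chrom_sizes=dict(TINY_SIZES),
        depth=100_000,
        n_genes=15,
        n_enhancers=6,
        n_peaks_x=4,
        n_peaks_autosome=2,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_genome():
    return make_genome(tiny_config())


@pytest.fixture
def toy_bins() -> GenomeBins:
    return bin_genome({"chr2": 1_000}, bin_size=100)


def make_track(bins: GenomeBins, values, **kw) -> MACCTrack:
    return MACCTrack(bins=bins, score=np.asarray(values, dtype=float), **kw)
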