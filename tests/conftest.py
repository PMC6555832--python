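import numpy as np
import pytest

from oncochrom.genome import AUTOSOME, X, Chromosome, GenomeAssembly
from oncochrom.synthetic_data import (
    ChromosomeSpec,
    DapiSpec,
    GeneSpec,
    SyntheticConfig,
    generate_dataset,
)
from oncochrom.track_io import STATE_LOGRATIO, BinnedTrack


@pytest.fixture
def small_assembly():
    return GenomeAssembly(
        (
            Chromosome("chrI", 50_000, AUTOSOME),
            Chromosome("chrII", 42_500, AUTOSOME),
            Chromosome("chrX", 30_000, X),
        )
    )


def make_track(assembly, bin_size, fill=0.0, state=STATE_LOGRATIO, values=None):
    if values is None:
        values = {
            c.name: np.full(assembly.n_bins(c.name, bin_size), fill)
            for c in assembly
        }
    return BinnedTrack(assembly, bin_size, values, state=state)


@pytest.fixture
def track_factory(small_assembly):
    def factory(fill=0.0, bin_size=1000, state=STATE_LOGRATIO, values=None):
        return make_track(small_assembly, bin_size, fill, state, values)

    return factory


def small_config(**overrides):
    defaults = dict(
        seed=7,
        bin_size=1000,
        chromosomes=ChromosomeSpec(n_autosomes=2, autosome_length=60_000, x_length=40_000),
        genes=GeneSpec(n_genes=60, gene_length=400, n_de=20),
        dapi=DapiSpec(n_per_population=20),
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def default_dataset():
    """The default-size H3.3-mode dataset (10,000 bins at 1 kb), seed 1."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def h3like_dataset():
    from oncochrom.synthetic_data import OncohistoneSpec

    cfg = SyntheticConfig(seed=1, oncohistone=OncohistoneSpec(mode="H3-like"))
    return generate_dataset(cfg)
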