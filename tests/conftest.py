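import numpy as np
import pytest

from crossbind import (
    PipelineParams,
    SyntheticConfig,
    analyse,
    build_world,
    inputs_from_world,
)


def small_config(seed: int = 5, **overrides) -> SyntheticConfig:
    """A reduced world (0.8 Mb chromosomes) for fast structural tests."""
    defaults = dict(
        seed=seed,
        chrom_length=800_000,
        genes_per_chrom=34,
        n_conserved_genes=20,
        n_alternative_genes=8,
        n_a_specific_genes=5,
        n_b_specific_genes=5,
        n_indeterminate_sites=5,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def world_nf():
    """Default-size noise-free world (planted classes exactly observable)."""
    return build_world(SyntheticConfig(seed=11).noise_free())


@pytest.fixture(scope="session")
def report_nf(world_nf):
    return analyse(inputs_from_world(world_nf), PipelineParams(n_perm=500, seed=11))


@pytest.fixture(scope="session")
def world_noisy():
    """Default world with the calibrated q-value noise and peak jitter."""
    return build_world(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def report_noisy(world_noisy):
    return analyse(inputs_from_world(world_noisy), PipelineParams(n_perm=500, seed=7))


@pytest.fixture(scope="session")
def small_world():
    return build_world(small_config().noise_free())
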