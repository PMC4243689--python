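import numpy as np
import pytest

from basepop.genome_sim import GenomeSpec, init_random_population


@pytest.fixture
def small_spec() -> GenomeSpec:
    """Two chromosomes, 90 neutral + 10 marker loci each."""
    return GenomeSpec(
        n_chromosomes=2,
        n_nonmarker_per_chrom=90,
        n_marker_per_chrom=10,
        mutation_rate=2.5e-3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_pop(small_spec, rng):
    return init_random_population(small_spec, 10, 10, rng)
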