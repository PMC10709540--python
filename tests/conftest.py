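import numpy as np
import pytest

from breedsim import FixtureSpec, make_founders, make_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return FixtureSpec(
        chromosomes=3,
        markers_per_chromosome=6,
        chromosome_length_cM=50.0,
        founders=8,
        traits=2,
        heritability=(0.4, 0.7),
        seed=7,
    )


@pytest.fixture
def small_map(small_spec):
    return make_map(small_spec)


@pytest.fixture
def founders(small_spec, small_map):
    return make_founders(small_spec, small_map)


def random_population(n, gmap, rng, freq=0.5):
    from breedsim import Population

    genome = (rng.random((n, gmap.n_markers, 2)) < freq).astype(np.int8)
    return Population(genome)
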