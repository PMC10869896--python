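import numpy as np
import pytest

from funcniche.functional_space import build_space
from funcniche.synthetic import SimulationConfig, generate_dataset
from funcniche.traits import compute_traits, standardize


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study: 111 individuals over 11 transects."""
    return generate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def individuals(dataset):
    return dataset[0]


@pytest.fixture(scope="session")
def transects(dataset):
    return dataset[1]


@pytest.fixture(scope="session")
def std_traits(individuals):
    return standardize(compute_traits(individuals))


@pytest.fixture(scope="session")
def space(std_traits):
    return build_space(std_traits)


@pytest.fixture(scope="session")
def group_points(space, individuals):
    coords = space.coordinates.to_numpy()
    groups = individuals.set_index("id").loc[space.coordinates.index, "group"]
    return {g: coords[(groups == g).to_numpy()] for g in ("juvenile", "male", "female")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240215)
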