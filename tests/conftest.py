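import numpy as np
import pytest

from edisom import (
    SyntheticSpec,
    apply_floor,
    build_grid,
    fold_change,
    generate,
    map_bmu,
    regulation_filter,
    train,
)
from edisom.synthetic import ARCHETYPES


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced planted-archetype dataset (fast to train) plus its truth."""
    spec = SyntheticSpec(
        archetype_counts={name: 40 for name in ARCHETYPES}, n_null=100, seed=11
    )
    matrix, truth = generate(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def small_trained(small_dataset):
    """Filtered fold changes, trained grid and BMU map for the small dataset."""
    _spec, matrix, _truth = small_dataset
    fc = fold_change(apply_floor(matrix))
    kept, _report = regulation_filter(fc)
    grid = train(build_grid(kept, seed=11), kept)
    bmu = map_bmu(grid, kept)
    return kept, grid, bmu


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
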