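import dataclasses

import numpy as np
import pytest

from amphistoma import synthetic
from amphistoma.leaf_data import SurfaceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def unit_square_corners():
    return SurfaceRecord(
        surface_id="corners", window=(1.0, 1.0),
        xy=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )


@pytest.fixture
def random50():
    return synthetic.random_surface(50, seed=11)


def make_study_group(n_leaves=8, n=50, alpha=18.0, beta=400.0, sigma=2.0,
                     seed=0, treatment="low", surface="abaxial",
                     leaves_per_plant=2):
    """Leaves with planted length-zone association, grouped into plants."""
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_leaves):
        rec = synthetic.random_surface(n, seed=rng, surface=surface)
        rec = dataclasses.replace(
            rec, surface_id=f"p{k // leaves_per_plant}:l{k}:{surface}",
            plant_id=f"p{k // leaves_per_plant}", leaf_id=f"l{k}",
            treatment=treatment)
        records.append(synthetic.attach_lengths(rec, alpha, beta, sigma, seed=rng))
    return records
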