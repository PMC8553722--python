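import numpy as np
import pytest

from myomol import (
    PhantomSpec,
    PlacementModel,
    compute_distance_map,
    generate_cell_phantom,
    partition_regions,
    place_puncta,
)

# A small myocyte phantom (40 x 12 x 8 um at 0.5 um isotropic sampling)
# keeps the geometry-heavy tests fast while preserving the rod shape,
# two nuclei and a nontrivial distance map.
SMALL_SPEC = PhantomSpec(
    cell_length=40.0, cell_width=12.0, cell_depth=8.0,
    n_nuclei=2, nucleus_semiaxes=(1.5, 2.0, 4.0),
    voxel_size=(0.5, 0.5, 0.5), seed=0,
)


@pytest.fixture(scope="session")
def small_labels():
    return generate_cell_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_dmap(small_labels):
    return compute_distance_map(small_labels)


@pytest.fixture(scope="session")
def small_partition(small_labels, small_dmap):
    return partition_regions(small_labels, small_dmap)


@pytest.fixture(scope="session")
def default_labels():
    """The full-size (100 x 20 x 10 um) phantom at confocal sampling."""
    return generate_cell_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_dmap(default_labels):
    return compute_distance_map(default_labels)


@pytest.fixture(scope="session")
def uniform_puncta(small_labels, small_dmap):
    model = PlacementModel(kind="uniform", n_puncta=5000, seed=11)
    return place_puncta(small_labels, model, small_dmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
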