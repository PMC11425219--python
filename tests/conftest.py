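import numpy as np
import pytest

from wm_morphnet import SimilarityNetwork, make_toy_atlas


@pytest.fixture(scope="session")
def toy_atlas():
    """Small mirrored atlas: 4 homotopic pairs + 2 midline, 216-voxel blocks."""
    return make_toy_atlas(n_pairs=4, n_midline=2, block_voxels=216)


@pytest.fixture(scope="session")
def full_atlas():
    """Default 48-region mirrored atlas."""
    return make_toy_atlas()


def random_similarity(n: int, seed: int) -> SimilarityNetwork:
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return SimilarityNetwork(matrix=m, region_ids=list(range(1, n + 1)))


@pytest.fixture()
def sim48():
    return random_similarity(48, seed=7)
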