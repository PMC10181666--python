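import numpy as np
import pytest

from leafcloud import BranchSpec, LabeledCloud, LeafSpec, make_branch, make_leaf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unit_grid_cloud():
    """10x10 unit-spaced planar grid (100 points)."""
    g = np.stack(np.meshgrid(np.arange(10), np.arange(10), indexing="ij"), -1).reshape(-1, 2)
    return LabeledCloud(np.column_stack([g, np.zeros(len(g))]).astype(float))


@pytest.fixture(scope="session")
def default_leaf():
    spec = LeafSpec(chord=0.08, droop=0.12, width_max=0.045, tilt_deg=30.0,
                    yaw_deg=40.0, noise_sigma=0.0005)
    return make_leaf(spec, seed=3)


@pytest.fixture(scope="session")
def small_branch():
    """Labeled branch with 10 leaves, used by pipeline-level tests."""
    return make_branch(BranchSpec(n_leaves=10, length=0.6), seed=0)


@pytest.fixture(scope="session")
def separated_branch():
    """12 leaves whose centroids are pairwise > 95 mm apart."""
    spec = BranchSpec(n_leaves=12, length=1.1, min_separation=0.095,
                      tilt_range_deg=(10.0, 60.0))
    return make_branch(spec, seed=11)
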