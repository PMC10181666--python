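import numpy as np
import pytest
from scipy.spatial.distance import cdist

from leafcloud import (
    CloudError,
    LabeledCloud,
    denormalize,
    farthest_point_sample,
    normalize,
    remove_outliers,
    voxel_thin,
)


def brute_force_sor_keep(coords, k, std_ratio):
    """O(n^2) oracle: per-point mean distance to its k nearest neighbors."""
    d = cdist(coords, coords)
    mean_d = np.sort(d, axis=1)[:, 1 : k + 1].mean(axis=1)
    return mean_d <= mean_d.mean() + std_ratio * mean_d.std()


class TestRemoveOutliers:
    def test_far_point_removed(self, unit_grid_cloud):
        coords = np.vstack([unit_grid_cloud.coords, [100.0, 100.0, 100.0]])
        cloud = LabeledCloud(coords)
        out = remove_outliers(cloud, k=8, std_ratio=1.0)
        assert out.n == 100
        assert np.abs(out.coords).max() < 50

    def test_uniform_grid_untouched(self, unit_grid_cloud):
        # with k=2 every grid point's mean k-NN distance is exactly 1,
        # so nothing exceeds the threshold
        out = remove_outliers(unit_grid_cloud, k=2, std_ratio=1.0)
        assert out.n == unit_grid_cloud.n

    def test_duplicate_point_retained(self, unit_grid_cloud):
        coords = np.vstack([unit_grid_cloud.coords, unit_grid_cloud.coords[37]])
        out = remove_outliers(LabeledCloud(coords), k=8, std_ratio=1.0)
        dup = (np.linalg.norm(out.coords - coords[37], axis=1) < 1e-12).sum()
        assert dup == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.random((300, 3))
        coords[:5] += 5.0  # a far clump
        keep = brute_force_sor_keep(coords, k=10, std_ratio=1.0)
        out = remove_outliers(LabeledCloud(coords), k=10, std_ratio=1.0)
        np.testing.assert_allclose(out.coords, coords[keep])

    def test_too_few_points(self):
        with pytest.raises(CloudError):
            remove_outliers(LabeledCloud(np.random.default_rng(0).random((5, 3))), k=8)


class TestVoxelThin:
    def test_merge_within_voxel(self):
        c = LabeledCloud(np.array([[0.0, 0.0, 0.0], [0.001, 0.0, 0.0]]))
        out = voxel_thin(c, voxel=0.003)
        assert out.n == 1
        np.testing.assert_allclose(out.coords[0], [0.0005, 0.0, 0.0])

    def test_distinct_voxels_untouched(self):
        c = LabeledCloud(np.array([[0.0, 0.0, 0.0], [0.010, 0.0, 0.0]]))
        out = voxel_thin(c, voxel=0.003)
        assert out.n == 2

    def test_output_voxels_unique_and_idempotent(self, rng):
        cloud = LabeledCloud(rng.random((1000, 3)) * 0.1)
        out = voxel_thin(cloud, voxel=0.003)
        idx = np.floor(out.coords / 0.003).astype(int)
        assert np.unique(idx, axis=0).shape[0] == out.n
        assert out.n <= cloud.n
        # a much finer grid than the output spacing leaves the cloud alone
        again = voxel_thin(out, voxel=1e-6)
        assert again.n == out.n

    def test_majority_label_tie_goes_to_branch(self):
        c = LabeledCloud(
            np.array([[0.0, 0.0, 0.0], [0.001, 0.0, 0.0]]),
            semantic=np.array([0, 1]),
        )
        out = voxel_thin(c, voxel=0.003)
        assert out.semantic[0] == 0


class TestFPS:
    def test_sample_size_exact(self, small_branch):
        cloud, _ = small_branch
        out = farthest_point_sample(cloud, m=2048, seed=0)
        assert out.n == 2048

    def test_square_corners_give_diagonal(self):
        sq = LabeledCloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float))
        for seed in range(4):  # any start point yields a diagonal pair
            out = farthest_point_sample(sq, m=2, seed=seed)
            assert np.isclose(np.linalg.norm(out.coords[0] - out.coords[1]), np.sqrt(2))

    def test_m_at_least_n_returns_unchanged(self, rng):
        cloud = LabeledCloud(rng.random((10, 3)))
        out = farthest_point_sample(cloud, m=50, seed=0)
        np.testing.assert_array_equal(out.coords, cloud.coords)

    def test_subset_deterministic_and_monotone(self, rng):
        cloud = LabeledCloud(rng.random((200, 3)))
        a = farthest_point_sample(cloud, m=50, seed=7)
        b = farthest_point_sample(cloud, m=50, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)
        # every sample point is an input point
        d = cdist(a.coords, cloud.coords)
        assert (d.min(axis=1) == 0).all()
        # min pairwise distance shrinks (weakly) as m grows
        def min_pair(m):
            s = farthest_point_sample(cloud, m=m, seed=7).coords
            dd = cdist(s, s)
            return dd[np.triu_indices(m, 1)].min()
        assert min_pair(10) >= min_pair(30) >= min_pair(60)

    def test_invalid_m(self, rng):
        with pytest.raises(ValueError):
            farthest_point_sample(LabeledCloud(rng.random((5, 3))), m=0)


class TestNormalize:
    def test_extent_and_roundtrip(self, rng):
        cloud = LabeledCloud(rng.random((500, 3)) * [3.0, 1.0, 0.5] + 7.0)
        norm, t = normalize(cloud)
        ext = norm.coords.max(axis=0) - norm.coords.min(axis=0)
        assert np.isclose(ext.max(), 2.0)
        np.testing.assert_allclose(norm.coords.mean(axis=0), 0.0, atol=1e-12)
        back = denormalize(norm, t)
        assert np.abs(back.coords - cloud.coords).max() < 1e-9

    def test_unit_cube_closed_form(self):
        corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1], indexing="ij")).reshape(3, -1).T.astype(float)
        norm, t = normalize(LabeledCloud(corners))
        assert np.isclose(t.scale, 0.5)  # 1 m extent -> 2 m cube
        np.testing.assert_allclose(t.center, 0.5)
        np.testing.assert_allclose(np.abs(norm.coords), 1.0)

    def test_already_normalized_is_fixed_point(self):
        corners = np.array(np.meshgrid([-1, 1], [-1, 1], [-1, 1], indexing="ij")).reshape(3, -1).T.astype(float)
        _, t = normalize(LabeledCloud(corners))
        assert np.isclose(t.scale, 1.0)
        np.testing.assert_allclose(t.center, 0.0, atol=1e-15)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(CloudError):
            normalize(LabeledCloud(np.zeros((5, 3))))
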