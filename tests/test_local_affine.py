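import numpy as np
import pytest

from eareg.errors import RegistrationFailureError
from eareg.features import MatchSet
from eareg.geodesics import DamageMask, GridMetric, wavefront_distance
from eareg.local_affine import (
    AffineTransform,
    fit_affine_lstsq,
    fit_cluster_affines,
    path_kmeans,
)


def _matchset(moving, reference=None):
    moving = np.asarray(moving, dtype=float)
    reference = moving if reference is None else np.asarray(reference, dtype=float)
    return MatchSet(moving, reference, np.zeros(len(moving)))


class TestPathKMeans:
    def test_k1_gives_single_cluster_with_mean_centroid(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(5, 58, (40, 2))
        clusters = path_kmeans(_matchset(pts), DamageMask.empty((64, 64)), k=1, seed=1)
        assert len(clusters) == 1
        assert len(clusters[0]) == 40
        assert np.linalg.norm(clusters[0].centroid - pts.mean(axis=0)) <= 1.0

    def test_barrier_wall_separates_sides_exactly(self):
        rng = np.random.default_rng(1)
        g = np.zeros((64, 64), dtype=bool)
        g[:, 32] = True
        left = rng.uniform([5, 5], [59, 28], (25, 2))
        right = rng.uniform([5, 36], [59, 59], (25, 2))
        clusters = path_kmeans(
            _matchset(np.vstack([left, right])), DamageMask(g), k=2, seed=2
        )
        assert len(clusters) == 2
        for c in clusters:
            cols = c.moving_pts[:, 1]
            assert (cols < 32).all() or (cols > 32).all()
        # brute-force optimum under the same metric: every point is assigned
        # to the geodesically reachable centroid (the other side is at inf)
        for c in clusters:
            d = wavefront_distance(DamageMask(g), [c.centroid]).values
            pix = np.rint(c.moving_pts).astype(int)
            assert np.isfinite(d[pix[:, 0], pix[:, 1]]).all()

    def test_same_seed_reproduces_assignment(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 63, (60, 2))
        g = rng.random((64, 64)) < 0.1
        a = path_kmeans(_matchset(pts), DamageMask(g), k=4, seed=7)
        b = path_kmeans(_matchset(pts), DamageMask(g), k=4, seed=7)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.member_indices, cb.member_indices)
            assert np.array_equal(ca.centroid, cb.centroid)

    def test_fewer_matches_than_k_reduces_k_with_warning(self):
        pts = np.array([[1.0, 1.0], [10.0, 10.0], [20.0, 20.0]])
        with pytest.warns(UserWarning, match="reducing k"):
            clusters = path_kmeans(_matchset(pts), DamageMask.empty((32, 32)), k=10)
        assert len(clusters) <= 3

    def test_objective_non_increasing_over_iterations(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 63, (80, 2))
        g = rng.random((64, 64)) < 0.15
        mask = DamageMask(g)
        ms = _matchset(pts)

        def objective(clusters):
            total = 0.0
            for c in clusters:
                d = wavefront_distance(mask, [c.centroid]).values
                pix = np.rint(c.moving_pts).astype(int)
                vals = d[pix[:, 0], pix[:, 1]]
                total += vals[np.isfinite(vals)].sum()
            return total

        objs = [
            objective(path_kmeans(ms, mask, k=4, seed=9, max_iter=i))
            for i in range(1, 6)
        ]
        assert all(b <= a + 1e-6 for a, b in zip(objs, objs[1:]))


class TestClusterRansac:
    A = np.array([[1.02, 0.05, 3.0], [-0.04, 0.98, -2.0]])

    def _cluster(self, src, dst):
        return path_kmeans(_matchset(src, dst), DamageMask.empty((64, 64)), k=1, seed=0)

    def test_noiseless_affine_recovered_exactly(self):
        rng = np.random.default_rng(10)
        src = rng.uniform(0, 60, (50, 2))
        dst = src @ self.A[:, :2].T + self.A[:, 2]
        cs = fit_cluster_affines(self._cluster(src, dst), seed=1)
        assert len(cs) == 1
        assert np.abs(cs.clusters[0].affine.matrix - self.A).max() < 1e-6
        assert cs.clusters[0].inlier_flags.all()

    def test_outlier_rejection_with_noise(self):
        rng = np.random.default_rng(11)
        src = rng.uniform(0, 60, (50, 2))
        dst = src @ self.A[:, :2].T + self.A[:, 2] + rng.normal(0, 0.5, (50, 2))
        out = rng.choice(50, 15, replace=False)
        dst[out] = rng.uniform(0, 60, (15, 2))
        cs = fit_cluster_affines(
            self._cluster(src, dst), ransac_threshold_px=3.0, seed=2
        )
        c = cs.clusters[0]
        truth = np.ones(50, dtype=bool)
        truth[out] = False
        recovered = c.inlier_flags
        assert (recovered & truth).sum() >= 0.95 * truth.sum()
        clean_dst = src @ self.A[:, :2].T + self.A[:, 2]
        err = np.linalg.norm(c.affine.apply(src[truth]) - clean_dst[truth], axis=1)
        assert err.mean() < 0.5

    def test_small_cluster_discarded_and_failure_when_none_left(self):
        rng = np.random.default_rng(12)
        src = rng.uniform(0, 60, (5, 2))
        clusters = self._cluster(src, src)
        with pytest.raises(RegistrationFailureError, match="local-affine"):
            fit_cluster_affines(clusters, min_inliers=8, seed=3)

    def test_mixed_clusters_keep_only_large_one(self):
        rng = np.random.default_rng(13)
        big_src = rng.uniform(0, 30, (40, 2))
        small_src = rng.uniform(40, 60, (5, 2))
        g = np.zeros((64, 64), dtype=bool)
        g[:, 35] = True
        src = np.vstack([big_src, small_src])
        clusters = path_kmeans(_matchset(src), DamageMask(g), k=2, seed=4)
        cs = fit_cluster_affines(clusters, min_inliers=8, seed=5)
        assert len(cs) == 1
        assert len(cs.clusters[0]) == 40

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(14)
        src = rng.uniform(0, 60, (40, 2))
        dst = src + rng.normal(0, 1.0, (40, 2))
        a = fit_cluster_affines(self._cluster(src, dst), seed=6)
        b = fit_cluster_affines(self._cluster(src, dst), seed=6)
        assert np.array_equal(a.clusters[0].inlier_flags, b.clusters[0].inlier_flags)
        assert np.array_equal(a.clusters[0].affine.matrix, b.clusters[0].affine.matrix)


def test_lstsq_affine_and_inverse_round_trip():
    rng = np.random.default_rng(20)
    src = rng.uniform(0, 10, (12, 2))
    A = AffineTransform(np.array([[0.9, 0.1, 4.0], [-0.2, 1.1, -1.0]]))
    fitted = fit_affine_lstsq(src, A.apply(src))
    assert np.allclose(fitted.matrix, A.matrix, atol=1e-9)
    back = fitted.inverse().apply(fitted.apply(src))
    assert np.allclose(back, src, atol=1e-9)
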