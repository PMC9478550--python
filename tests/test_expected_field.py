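import numpy as np
import pytest

from eareg.expected_field import (
    DensityField,
    ExpectedAffineField,
    expected_affine_field,
    knn_density,
    posterior,
    warp_moving,
)
from eareg.geodesics import DamageMask, wavefront_distance
from eareg.local_affine import AffineTransform, Cluster, ClusterSet


def _cluster_set(point_groups, affines=None, mask_shape=(32, 32)):
    """Build a ClusterSet whose inliers are the given point groups."""
    clusters = []
    for i, pts in enumerate(point_groups):
        pts = np.asarray(pts, dtype=float)
        aff = (
            AffineTransform.identity()
            if affines is None
            else AffineTransform(affines[i])
        )
        clusters.append(
            Cluster(
                member_indices=np.arange(len(pts)),
                moving_pts=pts,
                reference_pts=pts,
                centroid=pts.mean(axis=0),
                inlier_flags=np.ones(len(pts), dtype=bool),
                affine=aff,
            )
        )
    return ClusterSet(clusters=clusters, k_requested=len(clusters))


class TestKnnDensity:
    def test_direct_substitution_of_the_density_formula(self):
        # cluster A: 3 inliers on row 0; at pixel (0, 6) the 3rd-nearest is at
        # geodesic distance 6, so p = (3/n) / 6^2 with n = total inliers = 13
        groups = [
            [(0, 0), (0, 1), (0, 2)],
            [(20, c) for c in range(10, 20)],  # 10 far-away inliers
        ]
        cs = _cluster_set(groups, mask_shape=(32, 32))
        df = knn_density(cs, DamageMask.empty((32, 32)), K=3)
        assert df.n_total == 13
        assert df.values[0, 0, 6] == pytest.approx((3 / 13) / 36.0)
        # at a pixel ON an inlier the clamp bounds the density: d >= 0.5
        assert df.values[0, 0, 0] == pytest.approx((3 / 13) / (2.0**2))
        # d(0,0)=0 is clamped, but the 3rd nearest is (0,2) at distance 2

    def test_unreachable_cluster_has_zero_density(self):
        g = np.zeros((16, 16), dtype=bool)
        g[:, 8] = True
        cs = _cluster_set([[(2, 2), (3, 3), (4, 2)], [(2, 12), (3, 13), (4, 12)]])
        df = knn_density(cs, DamageMask(g), K=3)
        assert (df.values[0][:, 9:] == 0).all()
        assert (df.values[1][:, :8] == 0).all()
        assert (df.values[0][:, :8] > 0).all()

    def test_matches_bruteforce_knn_oracle(self):
        rng = np.random.default_rng(8)
        barrier = rng.random((24, 24)) < 0.15
        mask = DamageMask(barrier)
        free = np.argwhere(~barrier)
        groups = [
            free[rng.choice(len(free), 6, replace=False)],
            free[rng.choice(len(free), 9, replace=False)],
        ]
        cs = _cluster_set(groups)
        df = knn_density(cs, mask, K=3)
        n = 15
        for i, pts in enumerate(groups):
            maps = np.stack(
                [wavefront_distance(mask, [p]).values for p in pts]
            )
            d = np.sort(maps, axis=0)[2]
            expect = np.where(
                np.isfinite(d), (3 / n) / np.maximum(d, 0.5) ** 2, 0.0
            )
            assert np.allclose(df.values[i], expect, atol=1e-12)


class TestPosterior:
    def _df(self, planes, nearest=None):
        planes = np.asarray(planes, dtype=float)
        return DensityField(
            values=planes, n_total=10, K=3,
            nearest=np.asarray(nearest, dtype=float) if nearest is not None else None,
        )

    def test_equal_densities_split_evenly(self):
        p = posterior(self._df([[[0.2]], [[0.2]]]))
        assert np.allclose(p.values[:, 0, 0], [0.5, 0.5])

    def test_direct_normalization(self):
        p = posterior(self._df([[[0.3]], [[0.1]]]))
        assert np.allclose(p.values[:, 0, 0], [0.75, 0.25])

    def test_single_cluster_posterior_is_one_where_reachable(self):
        p = posterior(self._df([[[0.4, 0.0]]], nearest=[[[1.0, np.inf]]]))
        assert p.values[0, 0, 0] == 1.0
        assert p.values[0, 0, 1] == 1.0  # fallback assigns the only cluster

    def test_all_zero_density_falls_back_to_nearest_cluster(self):
        planes = [[[0.0, 0.2]], [[0.0, 0.2]]]
        nearest = [[[5.0, 1.0]], [[2.0, 1.0]]]  # cluster 1 nearer at pixel 0
        p = posterior(self._df(planes, nearest))
        assert np.allclose(p.values[:, 0, 0], [0.0, 1.0])
        assert np.allclose(p.values[:, 0, 1], [0.5, 0.5])

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(9)
        planes = rng.uniform(0, 1, (4, 8, 8))
        p = posterior(self._df(planes))
        assert np.allclose(p.values.sum(axis=0), 1.0, atol=1e-9)


class TestExpectedAffineField:
    def test_single_cluster_reduces_to_its_affine(self):
        A = np.array([[1.1, 0.0, 2.0], [0.1, 0.9, -1.0]])
        cs = _cluster_set([[(1, 1), (5, 5), (3, 7)]], affines=[A])
        from eareg.expected_field import PosteriorField

        post = PosteriorField(values=np.ones((1, 8, 8)))
        f = expected_affine_field(post, cs)
        assert np.allclose(f.matrices, A, atol=0)

    def test_even_blend_of_identity_and_translation(self):
        A1 = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        A2 = np.array([[1.0, 0, 2.0], [0, 1.0, 0.0]])
        cs = _cluster_set([[(0, 0)], [(1, 1)]], affines=[A1, A2])
        from eareg.expected_field import PosteriorField

        post = PosteriorField(values=np.full((2, 4, 4), 0.5))
        f = expected_affine_field(post, cs)
        assert np.allclose(f.matrices[..., 0, 2], 1.0)
        assert np.allclose(f.matrices[..., 0, 0], 1.0)

    def test_matches_entrywise_weighted_sum_oracle(self):
        rng = np.random.default_rng(10)
        r, H, W = 5, 6, 7
        affines = rng.standard_normal((r, 2, 3)) + np.array([[1, 0, 0], [0, 1, 0]])
        w = rng.uniform(0, 1, (r, H, W))
        w /= w.sum(axis=0)
        cs = _cluster_set([[(0, 0)]] * r, affines=affines, mask_shape=(H, W))
        from eareg.expected_field import PosteriorField

        f = expected_affine_field(PosteriorField(values=w), cs)
        oracle = np.zeros((H, W, 2, 3))
        for i in range(r):
            oracle += w[i][..., None, None] * affines[i]
        assert np.abs(f.matrices - oracle).max() < 1e-12

    def test_entries_stay_in_convex_hull_of_cluster_affines(self, crack_run):
        _, res = crack_run
        mats = res.clusters.affines
        lo = mats.min(axis=0) - 1e-9
        hi = mats.max(axis=0) + 1e-9
        f = res.field.matrices
        assert (f >= lo).all() and (f <= hi).all()


class TestWarp:
    def test_identity_field_returns_input(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(0, 1, (32, 32))
        f = ExpectedAffineField.from_affine(AffineTransform.identity(), (32, 32))
        out, valid = warp_moving(img, f)
        assert valid.all()
        assert np.allclose(out, img, atol=1e-9)

    def test_pure_translation_shifts_columns(self):
        ramp = np.tile(np.arange(32, dtype=float), (32, 1))
        A = AffineTransform(np.array([[1.0, 0, 0], [0, 1.0, 3.0]]))
        f = ExpectedAffineField.from_affine(A, (32, 32))
        out, valid = warp_moving(ramp, f)
        # u maps moving col c to reference col c + 3; sampling back shifts by -3
        assert np.allclose(out[5, 10], ramp[5, 7], atol=1e-6)
        assert np.allclose(out[:, 4:], np.maximum(ramp[:, 4:] - 3, 0), atol=1e-6)
        assert not valid[:, :2].all()

    def test_truth_field_roundtrip_on_synthetic_scene(self, crack_run):
        from scipy import ndimage

        from eareg.metrics import patch_ncc

        scene, _ = crack_run
        # build a field whose coordinate map IS the truth map: identity linear
        # part with the per-pixel displacement in the translation entries
        mats = np.zeros(scene.shape + (2, 3))
        H, W = scene.shape
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        mats[..., 0, 0] = 1.0
        mats[..., 1, 1] = 1.0
        mats[..., 0, 2] = scene.truth_field[0] - rr
        mats[..., 1, 2] = scene.truth_field[1] - cc
        out, valid = warp_moving(scene.moving, ExpectedAffineField(mats))
        excl = ndimage.binary_dilation(scene.mask.grid, iterations=10)
        rep = patch_ncc(out, scene.reference, patch=32, valid_mask=valid & ~excl)
        assert rep.mean >= 0.99


def test_field_tiff_round_trip(tmp_path, crack_run):
    _, res = crack_run
    path = tmp_path / "field.tif"
    res.field.to_tiff(path)
    back = ExpectedAffineField.from_tiff(path)
    assert np.allclose(back.matrices, res.field.matrices, atol=1e-6)


def test_pipeline_posteriors_sum_to_one_off_barriers(crack_run):
    scene, res = crack_run
    total = res.posteriors.values.sum(axis=0)
    off_barrier = ~scene.mask.grid
    assert np.abs(total[off_barrier] - 1.0).max() <= 1e-9
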