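import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eareg.errors import ConfigurationError, InvalidInputError
from eareg.features import (
    KeypointSet,
    MatchSet,
    equalize_histogram,
    extract_keypoints_gridded,
    mutual_nn_match,
)
from eareg.synthetic import generate_texture


class TestEqualizeHistogram:
    def test_constant_image_stays_constant(self):
        out = equalize_histogram(np.full((32, 32), 77, dtype=np.uint8))
        assert out.dtype == np.uint8
        assert len(np.unique(out)) == 1

    def test_two_levels_stay_distinct_and_ordered(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        out = equalize_histogram(img)
        lo, hi = out[0, 0], out[0, 5]
        assert lo < hi

    def test_ramp_yields_uniform_histogram(self):
        # direct CDF oracle: each of the 256 input levels occupies 256 pixels,
        # so every output bin must hold exactly 256 counts (+-1 from rounding)
        ramp = np.tile(np.arange(256, dtype=np.uint8), (256, 1))
        hist = np.bincount(equalize_histogram(ramp).ravel(), minlength=256)
        occupied = hist[hist > 0]
        assert np.abs(occupied - 256).max() <= 1

    def test_16bit_input_supported(self):
        img = (np.arange(65536, dtype=np.uint16).reshape(256, 256))
        out = equalize_histogram(img)
        assert out.dtype == np.uint8
        assert out.min() == 0 and out.max() == 255

    def test_multichannel_rejected(self):
        with pytest.raises(InvalidInputError):
            equalize_histogram(np.zeros((4, 4, 3), dtype=np.uint8))


class TestGriddedExtraction:
    def test_blank_image_yields_no_keypoints(self):
        assert len(extract_keypoints_gridded(np.full((100, 100), 128, np.uint8))) == 0

    def test_per_patch_cap_and_score_ordering(self):
        # backend contract test: 300 synthetic keypoints inside one patch
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 9, (300, 2))  # all in patch (0, 0) of a 100x100
        scores = rng.uniform(0.02, 1.0, 300)
        desc = rng.standard_normal((300, 8))

        kps = extract_keypoints_gridded(
            np.zeros((100, 100), np.uint8), backend=lambda img: (pos, scores, desc)
        )
        assert len(kps) == 50
        # the survivors are exactly the 50 highest-scoring candidates
        assert np.allclose(
            np.sort(kps.scores), np.sort(scores)[-50:]
        )
        assert (np.sort(kps.scores)[::-1] == kps.scores).all()

    def test_threshold_filters_low_scores(self):
        def fake_backend(image):
            pos = np.array([[5.0, 5.0], [6.0, 6.0]])
            return pos, np.array([0.5, 0.001]), np.zeros((2, 4))

        kps = extract_keypoints_gridded(np.zeros((100, 100), np.uint8), backend=fake_backend)
        assert len(kps) == 1 and kps.scores[0] == 0.5

    def test_texture_fills_every_patch(self):
        # the point of gridded extraction: even coverage on textured sections
        tex = (generate_texture((200, 200), seed=5) * 255).astype(np.uint8)
        kps = extract_keypoints_gridded(tex, grid=(10, 10))
        pr = np.minimum(kps.positions[:, 0] // 20, 9).astype(int)
        pc = np.minimum(kps.positions[:, 1] // 20, 9).astype(int)
        filled = np.zeros((10, 10), dtype=bool)
        filled[pr, pc] = True
        assert filled.all()
        counts = np.bincount(pr * 10 + pc, minlength=100)
        assert counts.max() <= 50

    def test_unknown_backend_is_config_error(self):
        with pytest.raises(ConfigurationError):
            extract_keypoints_gridded(np.zeros((64, 64), np.uint8), backend="nope")


def _random_kps(rng, n, d=64):
    return KeypointSet(
        rng.uniform(0, 100, (n, 2)), rng.uniform(0, 1, n), rng.standard_normal((n, d))
    )


class TestMutualNN:
    def test_identical_descriptors_recover_permutation(self):
        rng = np.random.default_rng(1)
        a = _random_kps(rng, 30)
        perm = rng.permutation(30)
        b = KeypointSet(a.positions[perm], a.scores[perm], a.descriptors[perm])
        ms = mutual_nn_match(a, b)
        assert len(ms) == 30
        assert np.allclose(ms.distance, 0.0, atol=1e-5)
        assert (perm[ms.reference_index] == ms.moving_index).all()

    def test_non_mutual_pairs_are_dropped(self):
        # u's nearest ref is v1, but v1's nearest moving point is w
        u = np.array([[1.0, 0.0]])
        w = np.array([[0.93, 0.0]])
        moving = KeypointSet([[0, 0], [1, 1]], [1, 1], np.vstack([u, w]))
        refs = KeypointSet([[2, 2], [3, 3]], [1, 1], np.array([[0.95, 0.0], [5.0, 5.0]]))
        ms = mutual_nn_match(moving, refs)
        assert len(ms) == 1
        assert ms.moving_index[0] == 1  # w <-> v1 is the mutual pair; u is dropped

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        a, b = _random_kps(rng, 200), _random_kps(rng, 200)
        ms = mutual_nn_match(a, b)
        # O(n^2) oracle
        d = np.linalg.norm(a.descriptors[:, None] - b.descriptors[None], axis=2)
        pairs = {
            (i, int(np.argmin(d[i])))
            for i in range(200)
            if int(np.argmin(d[:, np.argmin(d[i])])) == i
        }
        assert set(zip(ms.moving_index.tolist(), ms.reference_index.tolist())) == pairs

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetry_under_input_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_kps(rng, 25, d=8), _random_kps(rng, 30, d=8)
        fwd = mutual_nn_match(a, b)
        rev = mutual_nn_match(b, a)
        assert set(zip(fwd.moving_index.tolist(), fwd.reference_index.tolist())) == set(
            zip(rev.reference_index.tolist(), rev.moving_index.tolist())
        )

    def test_descriptor_length_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(InvalidInputError):
            mutual_nn_match(_random_kps(rng, 5, 16), _random_kps(rng, 5, 32))


def test_match_file_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    ms = MatchSet(
        rng.uniform(0, 50, (10, 2)), rng.uniform(0, 50, (10, 2)),
        rng.uniform(0, 1, 10), (64, 64), (64, 64),
    )
    path = tmp_path / "matches.txt"
    ms.to_text(path)
    back = MatchSet.from_text(path)
    assert np.allclose(back.moving_pos, ms.moving_pos, atol=1e-5)
    assert np.allclose(back.reference_pos, ms.reference_pos, atol=1e-5)
    assert back.moving_shape == (64, 64)
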