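"""Anomaly-map operations against brute-force reimplementations."""

import numpy as np
import pytest

from ctanomaly import (
    AnomalyConfig,
    Generator,
    close_mask,
    majority_vote,
    multi_slice_filter,
    residual_map,
    threshold_mask,
)
from ctanomaly.anomaly import detect, disk_element, reconstruct
from ctanomaly.encoder import EncoderNet


class TestResidualMap:
    def test_identity_pair_all_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, (8, 8))
        for kind in ("abs", "positive_part"):
            assert residual_map(x, x, kind=kind).sum() == 0.0

    def test_direct_evaluation_byte_scale(self):
        x = np.array([[0.0, 10 / 255]])
        xhat = np.array([[5 / 255, 0.0]])
        np.testing.assert_allclose(residual_map(x, xhat, "abs"), [[5.0, 10.0]],
                                   atol=1e-4)
        np.testing.assert_allclose(residual_map(x, xhat, "positive_part"),
                                   [[0.0, 10.0]], atol=1e-4)

    def test_positive_part_bounded_by_abs(self):
        rng = np.random.default_rng(1)
        x, xhat = rng.uniform(0, 1, (16, 16)), rng.uniform(0, 1, (16, 16))
        assert (residual_map(x, xhat, "positive_part")
                <= residual_map(x, xhat, "abs") + 1e-7).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residual_map(np.zeros((4, 4)), np.zeros((2, 2)))


class TestThreshold:
    def test_operating_point_strict_inequality(self):
        r = np.array([30.0, 36.0, 40.0])
        np.testing.assert_array_equal(threshold_mask(r, 36.0),
                                      [False, False, True])

    def test_zero_threshold_gives_support(self):
        r = np.array([[0.0, 1.0], [2.0, 0.0]])
        np.testing.assert_array_equal(threshold_mask(r, 0.0), r > 0)

    def test_above_max_gives_empty(self):
        r = np.random.default_rng(2).uniform(0, 50, (8, 8))
        assert not threshold_mask(r, r.max() + 1).any()

    def test_mask_size_monotone_in_threshold(self):
        r = np.random.default_rng(3).uniform(0, 255, (16, 16))
        sizes = [threshold_mask(r, t).sum() for t in range(0, 256, 16)]
        assert (np.diff(sizes) <= 0).all()


def _bruteforce_closing(m, radius):
    """Pad, dilate, erode with a disk — the infinite-background convention."""
    selem = disk_element(radius)
    k = selem.shape[0] // 2
    pad = np.pad(m, radius + k, constant_values=False)
    dil = np.zeros_like(pad)
    H, W = pad.shape
    for y in range(k, H - k):
        for x in range(k, W - k):
            if pad[y, x]:
                dil[y - k:y + k + 1, x - k:x + k + 1] |= selem.astype(bool)
    ero = np.zeros_like(dil)
    for y in range(k, H - k):
        for x in range(k, W - k):
            win = dil[y - k:y + k + 1, x - k:x + k + 1]
            ero[y, x] = bool(np.all(win[selem.astype(bool)]))
    r = radius + k
    return ero[r:-r, r:-r]


class TestCloseMask:
    def test_radius_zero_identity(self):
        m = np.random.default_rng(4).random((8, 8)) > 0.5
        np.testing.assert_array_equal(close_mask(m, 0), m)

    def test_one_pixel_gap_filled(self):
        m = np.zeros((7, 7), bool)
        m[3, 2] = m[3, 4] = True
        closed = close_mask(m, 1)
        assert closed[3, 3]

    def test_contains_input_and_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = rng.random((20, 20)) > 0.7
            c = close_mask(m, 2)
            assert (c | m == c).all()          # extensive
            np.testing.assert_array_equal(close_mask(c, 2), c)  # idempotent

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_bruteforce_dilate_erode(self, radius):
        rng = np.random.default_rng(6)
        for _ in range(5):
            m = rng.random((16, 16)) > 0.75
            np.testing.assert_array_equal(close_mask(m, radius),
                                          _bruteforce_closing(m, radius))


class TestMajorityVote:
    def test_basic_majority(self):
        a = np.array([[True, True]])
        b = np.array([[True, False]])
        c = np.array([[False, False]])
        np.testing.assert_array_equal(majority_vote([a, b, c]),
                                      [[True, False]])

    def test_three_identical_masks(self):
        m = np.random.default_rng(7).random((8, 8)) > 0.5
        np.testing.assert_array_equal(majority_vote([m, m, m]), m)

    def test_even_count_rejected(self):
        m = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            majority_vote([m, m])

    def test_matches_perpixel_counting(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            masks = [rng.random((16, 16)) > 0.5 for _ in range(3)]
            voted = majority_vote(masks)
            for y in range(16):
                for x in range(16):
                    votes = sum(m[y, x] for m in masks)
                    assert voted[y, x] == (votes > 1)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        masks = [rng.random((8, 8)) > 0.5 for _ in range(5)]
        a = majority_vote(masks)
        b = majority_vote(masks[::-1])
        np.testing.assert_array_equal(a, b)

    def test_no_pixel_created_from_nothing(self):
        rng = np.random.default_rng(10)
        masks = [rng.random((8, 8)) > 0.6 for _ in range(3)]
        voted = majority_vote(masks)
        union = masks[0] | masks[1] | masks[2]
        assert not (voted & ~union).any()


def _bruteforce_components(stack):
    """26-connectivity flood fill over a (S, H, W) boolean stack."""
    comps = []
    seen = np.zeros_like(stack, dtype=bool)
    S, H, W = stack.shape
    for s in range(S):
        for y in range(H):
            for x in range(W):
                if stack[s, y, x] and not seen[s, y, x]:
                    comp = []
                    todo = [(s, y, x)]
                    seen[s, y, x] = True
                    while todo:
                        cs, cy, cx = todo.pop()
                        comp.append((cs, cy, cx))
                        for ds in (-1, 0, 1):
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    ns, ny, nx = cs + ds, cy + dy, cx + dx
                                    if (0 <= ns < S and 0 <= ny < H
                                            and 0 <= nx < W
                                            and stack[ns, ny, nx]
                                            and not seen[ns, ny, nx]):
                                        seen[ns, ny, nx] = True
                                        todo.append((ns, ny, nx))
                    comps.append(comp)
    return comps


class TestMultiSliceFilter:
    def test_single_voxel_removed_by_min_size(self):
        masks = [np.zeros((6, 6), bool) for _ in range(3)]
        masks[1][3, 3] = True
        out = multi_slice_filter(masks, min_size=2)
        assert not any(m.any() for m in out)

    def test_min_size_one_span_one_is_identity(self):
        rng = np.random.default_rng(11)
        masks = [rng.random((8, 8)) > 0.6 for _ in range(4)]
        out = multi_slice_filter(masks, min_size=1, min_span=1)
        for a, b in zip(out, masks):
            np.testing.assert_array_equal(a, b)

    def test_span_filter_keeps_multislice_component(self):
        masks = [np.zeros((6, 6), bool) for _ in range(4)]
        masks[0][1, 1] = True                    # single-slice blip
        masks[2][4, 4] = masks[3][4, 4] = True   # spans two slices
        out = multi_slice_filter(masks, min_size=1, min_span=2)
        assert not out[0][1, 1]
        assert out[2][4, 4] and out[3][4, 4]

    def test_component_sizes_match_flood_fill(self):
        rng = np.random.default_rng(12)
        masks = [rng.random((10, 10)) > 0.8 for _ in range(4)]
        stack = np.stack(masks)
        comps = _bruteforce_components(stack)
        min_size = 4
        expected = np.zeros_like(stack)
        for comp in comps:
            if len(comp) >= min_size:
                for (s, y, x) in comp:
                    expected[s, y, x] = True
        out = np.stack(multi_slice_filter(masks, min_size=min_size))
        np.testing.assert_array_equal(out, expected)


class TestDetect:
    def _models(self, n=3):
        models = []
        for k in range(n):
            g = Generator(32, 8, 8, rng=np.random.default_rng(20 + k))
            g.eval()
            e = EncoderNet(32, 8, 4, rng=np.random.default_rng(30 + k))
            e.eval()
            models.append((g, e))
        return models

    def test_pipeline_equals_manual_composition(self):
        x = np.random.default_rng(13).uniform(0, 1, (32, 32)).astype(np.float32)
        models = self._models()
        cfg = AnomalyConfig(residual_kind="abs", threshold=20.0,
                            closing_radius=1)
        voted, residuals, mean_recon = detect(x, models, cfg, mode="encoder")
        member = []
        recons = []
        for g, e in models:
            xhat = reconstruct(x, g, e, mode="encoder")
            recons.append(xhat)
            r = residual_map(x, xhat, kind="abs")
            member.append(close_mask(threshold_mask(r, 20.0), 1))
        np.testing.assert_array_equal(voted, majority_vote(member))
        np.testing.assert_allclose(mean_recon, np.mean(recons, axis=0),
                                   atol=1e-6)

    def test_perfect_reconstruction_gives_empty_mask(self):
        x = np.random.default_rng(14).uniform(0, 1, (32, 32)).astype(np.float32)

        class IdentityGen:
            resolution = 32
            latent_dim = 8

            def eval(self):
                return self

            def generate(self, z):
                return x[None]

        class ZeroEnc:
            def eval(self):
                return self

            def encode(self, _):
                return np.zeros((1, 8), dtype=np.float32)

        models = [(IdentityGen(), ZeroEnc()) for _ in range(3)]
        cfg = AnomalyConfig(threshold=0.0, closing_radius=0)
        voted, _, _ = detect(x, models, cfg, mode="encoder")
        assert not voted.any()

    def test_vote_symmetric_under_model_permutation(self):
        x = np.random.default_rng(15).uniform(0, 1, (32, 32)).astype(np.float32)
        models = self._models()
        cfg = AnomalyConfig(threshold=20.0)
        a, _, _ = detect(x, models, cfg, mode="encoder")
        b, _, _ = detect(x, models[::-1], cfg, mode="encoder")
        np.testing.assert_array_equal(a, b)

    def test_encoder_mode_without_encoder_rejected(self):
        x = np.zeros((32, 32), dtype=np.float32)
        g = Generator(32, 8, 8, rng=np.random.default_rng(16))
        with pytest.raises(ValueError):
            reconstruct(x, g, None, mode="encoder")

    def test_ensemble_size_mismatch_rejected(self):
        x = np.zeros((32, 32), dtype=np.float32)
        cfg = AnomalyConfig(ensemble_size=3)
        with pytest.raises(ValueError):
            detect(x, self._models(1), cfg, mode="encoder")
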