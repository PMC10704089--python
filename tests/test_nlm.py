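"""Guided NLM: GLR arithmetic, weight identities, limits, oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from specklehilo.nlm import (
    GuidedDenoiseRequest,
    NLMParams,
    glr_pixel,
    log_glr,
    nlm_denoise,
    nlm_denoise_reference,
    nlm_weights,
    patch_log_likelihood,
)


class TestGlr:
    @pytest.mark.parametrize("a", [0.0, 0.5, 1.0, 7.0, 1000.0])
    def test_identical_intensities_give_exactly_one(self, a):
        assert glr_pixel(a, a) == 1.0

    def test_one_two(self):
        assert abs(glr_pixel(1.0, 2.0) - 27.0 / 32.0) < 1e-12

    def test_zero_two_uses_zero_power_zero_convention(self):
        # (0+2)^2 / (2^2 * 0^0 * 2^2) = 4/16 = 1/4
        assert abs(glr_pixel(0.0, 2.0) - 0.25) < 1e-15

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            glr_pixel(-1.0, 2.0)

    @given(
        a=st.floats(0, 300, allow_nan=False),
        b=st.floats(0, 300, allow_nan=False),
    )
    def test_symmetric_and_bounded(self, a, b):
        va, vb = glr_pixel(a, b), glr_pixel(b, a)
        assert va == vb
        assert 0.0 < va <= 1.0
        if a != b:
            assert va < 1.0

    def test_extreme_disparity_underflows_gracefully(self):
        # log LG stays finite; the ratio itself underflows to 0.0 without error
        assert log_glr(0.0, 2000.0) == pytest.approx(-2000.0 * math.log(2))
        assert glr_pixel(0.0, 2000.0) == 0.0

    def test_vectorized_matches_scalar(self, rng):
        a = rng.random(50) * 100
        b = rng.random(50) * 100
        vec = glr_pixel(a, b)
        assert np.allclose(vec, [glr_pixel(x, y) for x, y in zip(a, b)], rtol=1e-14)


class TestPatchLogLikelihood:
    def test_self_similarity_is_zero(self, rng):
        guide = rng.random((9, 9)) * 10
        assert patch_log_likelihood(guide, (4, 4), (4, 4), 1) == 0.0

    def test_single_pixel_patch(self):
        guide = np.array([[1.0, 2.0]])
        L = patch_log_likelihood(guide, (0, 0), (0, 1), 0)
        assert np.isclose(L, math.log(27 / 32), rtol=1e-14)

    def test_nine_identical_offsets(self):
        guide = np.ones((4, 8))
        guide[:, 4:] = 2.0
        # patches centered at (1,1) and (1,6) see all-ones vs all-twos
        L = patch_log_likelihood(guide, (1, 1), (1, 6), 1)
        assert np.isclose(L, 9 * math.log(27 / 32), rtol=1e-12)

    def test_symmetry_and_out_of_range(self, rng):
        guide = rng.random((8, 8))
        assert patch_log_likelihood(guide, (2, 3), (5, 6), 1) == pytest.approx(
            patch_log_likelihood(guide, (5, 6), (2, 3), 1)
        )
        with pytest.raises(IndexError):
            patch_log_likelihood(guide, (2, 3), (8, 0), 1)


class TestWeights:
    def test_self_weight_is_one(self, rng):
        guide = rng.random((11, 11)) * 5
        params = NLMParams(patch_halfwidth=1, search_halfwidth=3)
        w = nlm_weights(guide, (5, 5), params, h=2.0)
        assert w.shape == (7, 7)
        assert w[3, 3] == 1.0
        assert np.all(w > 0) and np.all(w <= 1.0)

    def test_infinite_h_gives_all_ones(self, rng):
        guide = rng.random((9, 9))
        params = NLMParams(patch_halfwidth=1, search_halfwidth=2)
        w = nlm_weights(guide, (4, 4), params, h=np.inf)
        assert np.allclose(w, 1.0)

    def test_known_weight_value(self):
        # N = 0: similarity of pixel values 1 and 2 with h = 1 -> 27/32
        guide = np.array([[1.0, 2.0, 1.0]])
        params = NLMParams(patch_halfwidth=0, search_halfwidth=1)
        w = nlm_weights(guide, (0, 1), params, h=1.0)
        assert np.isclose(w[1, 0], 27 / 32, rtol=1e-12)
        assert np.isclose(w[1, 2], 27 / 32, rtol=1e-12)

    def test_rejects_nonpositive_h(self, rng):
        with pytest.raises(ValueError):
            nlm_weights(rng.random((5, 5)), (2, 2), NLMParams(), h=0.0)


def _request(guide, target, n=1, ny=2, h=5.0):
    params = NLMParams(patch_halfwidth=n, search_halfwidth=ny, h_lo=h, h_hi=h)
    return GuidedDenoiseRequest(guide, target, params, "lo")


class TestDenoise:
    def test_infinite_h_equals_moving_mean(self, rng):
        guide = rng.random((20, 22)) * 10
        target = rng.random((20, 22))
        ny = 3
        out = nlm_denoise(_request(guide, target, n=1, ny=ny, h=np.inf))
        expected = ndimage.uniform_filter(target, size=2 * ny + 1, mode="mirror")
        assert np.max(np.abs(out - expected)) < 1e-10

    def test_constant_guide_equals_moving_mean(self, rng):
        target = rng.random((16, 16))
        out = nlm_denoise(_request(np.ones((16, 16)), target, n=1, ny=2, h=0.5))
        expected = ndimage.uniform_filter(target, size=5, mode="mirror")
        assert np.max(np.abs(out - expected)) < 1e-10

    def test_tiny_h_returns_target(self, rng):
        # continuous random guide: all patches distinct, self weight dominates
        guide = 1.0 + rng.random((14, 14)) * 50
        target = rng.random((14, 14))
        out = nlm_denoise(_request(guide, target, h=1e-4))
        assert np.allclose(out, target, atol=1e-12)

    def test_constant_target_fixed_point(self, rng):
        guide = rng.random((12, 12)) * 10
        out = nlm_denoise(_request(guide, np.full((12, 12), 3.25)))
        assert np.allclose(out, 3.25, atol=1e-12)

    def test_output_within_local_window_range(self, rng):
        guide = rng.random((18, 18)) * 10
        target = rng.standard_normal((18, 18))
        ny = 2
        out = nlm_denoise(_request(guide, target, ny=ny, h=3.0))
        padded = np.pad(target, ny, mode="reflect")
        lo = ndimage.minimum_filter(padded, size=2 * ny + 1)[ny:-ny, ny:-ny]
        hi = ndimage.maximum_filter(padded, size=2 * ny + 1)[ny:-ny, ny:-ny]
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_mirror_symmetry(self, rng):
        guide = rng.random((15, 13)) * 8
        target = rng.random((15, 13))
        req = _request(guide, target)
        mirrored = _request(guide[:, ::-1], target[:, ::-1])
        assert np.allclose(nlm_denoise(mirrored), nlm_denoise(req)[:, ::-1], atol=1e-12)

    def test_variance_reduction_on_noisy_constant(self):
        reductions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            guide = np.full((24, 24), 50.0)
            target = 1.0 + 0.3 * rng.standard_normal((24, 24))
            out = nlm_denoise(_request(guide, target, h=5.0))
            reductions.append(out.var() < target.var())
        assert all(reductions)

    def test_manual_center_pixel_value(self):
        # N = 0, Ny = 1, h = 1: weights are GLR(center, neighbor) directly.
        guide = np.array([[1.0, 2.0, 1.0], [2.0, 1.0, 2.0], [1.0, 2.0, 1.0]])
        target = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        out = nlm_denoise(_request(guide, target, n=0, ny=1, h=1.0))
        w_diff = 27.0 / 32.0  # GLR(1, 2)
        weights = np.full((3, 3), w_diff)
        weights[1, 1] = 1.0  # self
        weights[0, 0] = weights[0, 2] = weights[2, 0] = weights[2, 2] = 1.0  # value 1 == 1
        expected_center = np.sum(weights * target) / np.sum(weights)
        assert np.isclose(out[1, 1], expected_center, rtol=1e-12)


class TestReference:
    def test_single_pixel_unchanged(self):
        req = _request(np.array([[4.0]]), np.array([[2.5]]), n=0, ny=0, h=1.0)
        assert nlm_denoise_reference(req)[0, 0] == 2.5

    def test_constant_image_unchanged(self):
        req = _request(np.ones((2, 2)), np.full((2, 2), 1.5), n=1, ny=1, h=1.0)
        assert np.allclose(nlm_denoise_reference(req), 1.5)

    def test_fast_path_matches_reference(self, rng):
        for _ in range(5):
            guide = rng.random((20, 20)) * 20
            target = rng.random((20, 20)) * 5
            req = _request(guide, target, n=1, ny=4, h=8.0)
            fast = nlm_denoise(req)
            ref = nlm_denoise_reference(req)
            assert np.max(np.abs(fast - ref)) < 1e-10


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            NLMParams(patch_halfwidth=-1)
        with pytest.raises(ValueError):
            NLMParams(patch_halfwidth=3, search_halfwidth=2)
        with pytest.raises(ValueError):
            NLMParams(h_lo=0.0)
        with pytest.raises(ValueError):
            NLMParams(channels="none")

    def test_request_validation(self, rng):
        with pytest.raises(ValueError):
            GuidedDenoiseRequest(-rng.random((4, 4)), rng.random((4, 4)), NLMParams())
        with pytest.raises(ValueError):
            GuidedDenoiseRequest(rng.random((4, 4)), rng.random((4, 5)), NLMParams())
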