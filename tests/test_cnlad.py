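import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psidenoise.cnlad import (
    RING_KERNEL,
    DenoiseConfig,
    cnlad_step,
    cosine_similarity,
    denoise,
    diffusion_coefficient,
    mean_k_middle,
    type2_gate,
    variation_field,
)
from psidenoise.gvc import CalibrationCurve


def brute_force_variation_field(image, search=9, patch=3):
    """Independent scalar-loop oracle for the q field."""
    sr, pr = search // 2, patch // 2
    orad = sr - pr
    side = 2 * orad + 1
    G = 1.0 - 0.2 * np.maximum(
        np.abs(np.arange(-orad, orad + 1))[:, None],
        np.abs(np.arange(-orad, orad + 1))[None, :],
    )
    padded = np.pad(image, sr, mode="reflect")
    h, w = image.shape
    q = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            ci, cj = i + sr, j + sr
            f0 = padded[ci - pr : ci + pr + 1, cj - pr : cj + pr + 1].ravel()
            acc = 0.0
            for a in range(-orad, orad + 1):
                for b in range(-orad, orad + 1):
                    fk = padded[ci + a - pr : ci + a + pr + 1, cj + b - pr : cj + b + pr + 1].ravel()
                    acc += G[a + orad, b + orad] * cosine_similarity(f0, fk)
            q[i, j] = acc / G.sum()
    return q


class TestCosineSimilarity:
    def test_identical_patches(self, rng):
        p = rng.random((3, 3))
        assert cosine_similarity(p, p) == pytest.approx(1.0)

    def test_orthogonal_supports(self):
        a = np.array([1.0, 0, 0, 0])
        b = np.array([0, 1.0, 0, 0])
        assert cosine_similarity(a, b) == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, c, seed):
        p = np.random.default_rng(seed).random(9) + 0.01
        assert cosine_similarity(p, c * p) == pytest.approx(1.0, abs=1e-10)

    def test_zero_norm_conventions(self):
        z = np.zeros(9)
        p = np.ones(9)
        assert cosine_similarity(z, z) == 1.0
        assert cosine_similarity(z, p) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.ones(4), np.ones(9))


class TestVariationField:
    def test_constant_image_q_one_T_one(self):
        vf = variation_field(np.full((20, 20), 8.0))
        np.testing.assert_allclose(vf.q, 1.0, atol=1e-12)
        assert vf.T == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.random((16, 16)) * 100 + 1
        vf = variation_field(img)
        oracle = brute_force_variation_field(img)
        np.testing.assert_allclose(vf.q, oracle, atol=1e-10)
        assert vf.T == pytest.approx(oracle.mean(), abs=1e-12)

    def test_edge_scores_below_flat_noisy_region(self, rng):
        # two-level step image with mild noise: q dips at the edge
        img = np.full((20, 20), 20.0)
        img[:, 10:] = 200.0
        img += rng.random((20, 20))
        vf = variation_field(img)
        edge_q = vf.q[:, 9:11].mean()
        flat_q = vf.q[:, :5].mean()
        assert edge_q < flat_q

    def test_ring_kernel_center_is_maximum(self):
        assert RING_KERNEL[3, 3] == 1.0
        assert RING_KERNEL.max() == RING_KERNEL[3, 3]
        # ring structure: chebyshev rings at 0.8 / 0.6 / 0.4
        assert RING_KERNEL[3, 2] == RING_KERNEL[2, 3] == 0.8
        assert RING_KERNEL[0, 0] == 0.4

    def test_even_sizes_rejected(self):
        with pytest.raises(ValueError):
            variation_field(np.ones((12, 12)), search_size=8)


class TestDiffusionCoefficient:
    def test_at_threshold_equals_one(self):
        assert diffusion_coefficient(np.array(0.7), 0.7) == 1.0

    def test_unit_deviation_halves(self):
        assert diffusion_coefficient(np.array(1.7), 0.7) == pytest.approx(0.5)

    def test_even_and_decreasing_in_deviation(self):
        dev = np.linspace(0, 1, 11)
        c_plus = diffusion_coefficient(0.5 + dev, 0.5)
        c_minus = diffusion_coefficient(0.5 - dev, 0.5)
        np.testing.assert_allclose(c_plus, c_minus)
        assert all(a >= b for a, b in zip(c_plus, c_plus[1:]))


class TestMeanKMiddle:
    @pytest.mark.parametrize("k,expected", [(1, 5.0), (2, 5.0), (5, 5.0)])
    def test_one_to_nine(self, k, expected):
        assert mean_k_middle(np.arange(1, 10), k) == expected

    def test_k2_is_mean_of_three_middle(self):
        vals = np.array([1, 1, 1, 4, 5, 9, 9, 9, 9])
        assert mean_k_middle(vals, 2) == pytest.approx((4 + 5 + 9) / 3)

    def test_even_sample_uses_2k_middle(self):
        assert mean_k_middle(np.array([1, 2, 3, 4]), 1) == 2.5

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            mean_k_middle(np.arange(9), 6)


class TestType2Gate:
    def test_center_equal_to_window_m2_gives_full_membership(self):
        gate = type2_gate(np.full((8, 8), 99.0), normalize=False)
        np.testing.assert_allclose(gate.U, 1.0)
        np.testing.assert_allclose(gate.umf, 1.0)

    def test_far_from_window_statistic_gives_zero(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 200.0  # isolated spike, raw scale
        gate = type2_gate(img, normalize=False)
        assert gate.U[4, 4] < 1e-6

    def test_lower_membership_below_upper_everywhere(self, rng):
        img = rng.random((16, 16)) * 255
        gate = type2_gate(img)
        assert np.all(gate.lmf <= gate.umf + 1e-15)
        assert np.all((gate.U >= 0) & (gate.U <= 1))


class TestCnladStep:
    def test_constant_image_is_fixed_point(self):
        img = np.full((10, 10), 5.0)
        out = cnlad_step(img, np.ones_like(img), np.zeros_like(img), 0.25)
        np.testing.assert_array_equal(out, img)

    def test_full_membership_freezes_pixel(self, rng):
        img = rng.random((10, 10)) * 100
        out = cnlad_step(img, np.ones_like(img), np.ones_like(img), 0.25)
        np.testing.assert_allclose(out, img)

    def test_heat_step_oracle_5x5(self):
        # with c=1, U=0, dt=0.25 one update is the standard 4-neighbor
        # explicit heat step with mirrored boundary
        rng = np.random.default_rng(3)
        img = rng.random((5, 5)) * 10
        out = cnlad_step(img, np.ones_like(img), np.zeros_like(img), 0.25)
        expected = np.empty_like(img)
        for i in range(5):
            for j in range(5):
                nb = [
                    img[max(i - 1, 0), j], img[min(i + 1, 4), j],
                    img[i, max(j - 1, 0)], img[i, min(j + 1, 4)],
                ]
                expected[i, j] = img[i, j] + 0.25 / 4 * sum(n - img[i, j] for n in nb)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.25))
    def test_discrete_max_principle(self, seed, dt):
        rng = np.random.default_rng(seed)
        img = rng.random((8, 8)) * 100
        c = rng.random((8, 8))
        u = rng.random((8, 8))
        out = cnlad_step(img, c, u, dt)
        assert out.min() >= img.min() - 1e-9
        assert out.max() <= img.max() + 1e-9


class TestDenoisePipeline:
    def test_noiseless_constant_image_is_fixed_point(self):
        img = np.full((128, 128), 50.0)
        out = denoise(img, DenoiseConfig(n_iter=20))
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_deterministic(self, constant50):
        from psidenoise.noise import apply_multiplicative_noise

        noisy = apply_multiplicative_noise(constant50[:96, :96], 0.3, seed=5)
        cfg = DenoiseConfig(n_iter=30)
        curve = CalibrationCurve(deltas=np.array([1.0]), k_values=np.array([2.0]))
        np.testing.assert_array_equal(denoise(noisy, cfg, curve), denoise(noisy, cfg, curve))

    def test_masked_denoise_leaves_outside_untouched(self, rng):
        img = rng.random((64, 64)) * 30 + 20
        mask = np.zeros((64, 64), dtype=bool)
        mask[16:48, 16:48] = True
        cfg = DenoiseConfig(n_iter=30, gvc_k_max=1)
        out = denoise(img, cfg, mask=mask)
        np.testing.assert_array_equal(out[~mask], img[~mask])
        assert out[mask].std() < img[mask].std()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DenoiseConfig(dt=0.3)
        with pytest.raises(ValueError):
            DenoiseConfig(n_iter=-1)
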