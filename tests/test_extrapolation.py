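"""Latent-space enhancement: the Euclidean and L-infinity schemes, their
geometric characterizations (constrained-minimizer oracles), and the full
image pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import NonlinearConstraint, minimize

from eggpale import (
    EnhanceParams,
    build_hyperplane,
    enhance_image,
    extrapolate_euclidean,
    extrapolate_final,
    interpolate_linf,
)
from eggpale.errors import ConfigurationError, InputError, ParameterError
from eggpale.flow.model import image_space, model_space
from eggpale.hyperplane import NormalBasis
from eggpale.image import ImageGrid


class TestEuclidean:
    def test_endpoint_identities(self, rng):
        z, z0 = rng.standard_normal(5), rng.standard_normal(5)
        assert np.array_equal(extrapolate_euclidean(z, z0, 1.0), z)
        assert np.array_equal(extrapolate_euclidean(z, z0, 0.0), z0)

    def test_extrapolation_beyond_input(self):
        out = extrapolate_euclidean(np.array([2.0, 0.0]), np.zeros(2), 1.5)
        assert np.allclose(out, [3.0, 0.0])

    @pytest.mark.parametrize("gamma", [0.2, 0.5, 0.9])
    def test_matches_constrained_minimizer_oracle(self, gamma, rng):
        """For 0 <= gamma <= 1 the straight-line interpolation solves
        min ||z - z_in||_2 subject to ||z - z0||_2 <= gamma * ||z_in - z0||_2."""
        z_in = rng.standard_normal(5)
        z0 = rng.standard_normal(5)
        radius = gamma * np.linalg.norm(z_in - z0)
        res = minimize(
            lambda z: ((z - z_in) ** 2).sum(), x0=(z_in + z0) / 2,
            constraints=NonlinearConstraint(
                lambda z: np.linalg.norm(z - z0), 0.0, radius),
            method="trust-constr", options={"xtol": 1e-12, "gtol": 1e-12},
        )
        assert np.allclose(extrapolate_euclidean(z_in, z0, gamma), res.x, atol=1e-5)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            extrapolate_euclidean(np.zeros(3), np.zeros(4), 0.5)


class TestLinfInterpolation:
    def test_endpoint_identities(self, rng):
        z, z0 = rng.standard_normal(6), rng.standard_normal(6)
        assert np.array_equal(interpolate_linf(z, z0, 0.0), z0)
        assert np.array_equal(interpolate_linf(z, z0, 1.0), z)

    def test_hand_example(self):
        out = interpolate_linf(np.array([3.0, 1.0]), np.zeros(2), 0.5)
        assert np.allclose(out, [1.5, 1.0])

    def test_is_l1_minimizer_over_hypercube(self):
        """Brute-force grid search over the cube confirms the clamp is the
        L1-nearest feasible point."""
        z_in, z0, gamma = np.array([3.0, 1.0]), np.zeros(2), 0.5
        big_g = gamma * np.abs(z_in - z0).max()
        out = interpolate_linf(z_in, z0, gamma)
        grid = np.linspace(-big_g, big_g, 301)
        pts = np.stack(np.meshgrid(grid, grid), axis=-1).reshape(-1, 2) + z0
        best = np.abs(pts - z_in).sum(axis=1).min()
        assert np.abs(out - z_in).sum() <= best + 1e-9
        assert np.abs(out - z0).max() <= big_g + 1e-12

    def test_gamma_out_of_range(self):
        with pytest.raises(ParameterError):
            interpolate_linf(np.zeros(2), np.zeros(2), 1.5)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_elementwise_betweenness_and_monotonicity(self, seed, g1, g2):
        rng = np.random.default_rng(seed)
        z_in, z0 = rng.standard_normal(8), rng.standard_normal(8)
        lo, hi = min(g1, g2), max(g1, g2)
        out_lo = interpolate_linf(z_in, z0, lo)
        out_hi = interpolate_linf(z_in, z0, hi)
        between = (np.minimum(z0, z_in) - 1e-12 <= out_lo) & \
                  (out_lo <= np.maximum(z0, z_in) + 1e-12)
        assert between.all()
        # element-wise monotone approach toward z_in as gamma grows
        assert np.all(np.abs(out_hi - z_in) <= np.abs(out_lo - z_in) + 1e-12)
        # the altered-element count is non-increasing in gamma, zero at 1
        assert (out_hi != z_in).sum() <= (out_lo != z_in).sum()
        assert np.array_equal(interpolate_linf(z_in, z0, 1.0), z_in)


class TestFinalExtrapolation:
    def test_beta_one_is_identity(self, rng):
        z, zi = rng.standard_normal(5), rng.standard_normal(5)
        assert np.array_equal(extrapolate_final(z, zi, 1.0), z)

    def test_hand_example_and_sparsity(self):
        out = extrapolate_final(np.array([3.0, 1.0]), np.array([1.5, 1.0]), 1.2)
        assert np.allclose(out, [3.3, 1.0])
        assert out[1] == 1.0  # untouched element preserved bit-exactly

    def test_sparsity_matches_clamp_support(self, rng):
        z_in, z0 = rng.standard_normal(50), rng.standard_normal(50)
        gamma = 0.2
        big_g = gamma * np.abs(z_in - z0).max()
        z_interp = interpolate_linf(z_in, z0, gamma)
        out = extrapolate_final(z_in, z_interp, 1.2)
        altered = out != z_in
        expected = np.abs(z_in - z0) > big_g
        assert np.array_equal(altered, expected)


class TestEnhanceImage:
    @pytest.fixture()
    def basis_for(self, mini_trained, rng):
        x = rng.uniform(-0.5, 0.5, (30, 1, 16, 16))
        z, _ = mini_trained.forward_array(x)
        return build_hyperplane(z.T, model_hash=mini_trained.param_hash())

    def test_null_enhancement_returns_input(self, mini_trained, basis_for, rng):
        img = image_space(rng.uniform(-0.4, 0.4, (16, 16)))
        out = enhance_image(mini_trained, basis_for, img,
                            EnhanceParams(gamma=0.2, beta=1.0))
        assert np.abs(out.pixels - img.pixels).max() < 1e-4 * 256
        assert out.value_range == img.value_range

    def test_output_respects_value_range(self, mini_trained, basis_for, rng):
        img = image_space(rng.uniform(-0.5, 0.5, (16, 16)))
        out = enhance_image(mini_trained, basis_for, img,
                            EnhanceParams(gamma=0.2, beta=1.5))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 255.0

    def test_model_basis_hash_mismatch_rejected(self, mini_trained, rng):
        z = rng.standard_normal((mini_trained.latent_dim, 10))
        basis = build_hyperplane(z, model_hash="not-the-right-model")
        img = image_space(rng.uniform(-0.4, 0.4, (16, 16)))
        with pytest.raises(ConfigurationError):
            enhance_image(mini_trained, basis, img)

    def test_dimension_mismatch_rejected(self, mini_trained, rng):
        basis = build_hyperplane(rng.standard_normal((64, 5)))
        img = image_space(rng.uniform(-0.4, 0.4, (16, 16)))
        with pytest.raises(ConfigurationError):
            enhance_image(mini_trained, basis, img)

    def test_default_parameters(self):
        params = EnhanceParams()
        assert params.gamma == 0.2 and params.beta == 1.2 and params.mode == "linf"
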