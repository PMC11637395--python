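"""Model-level contracts: invertibility, change-of-variables correctness,
the singular-value re-projection, sampling and persistence."""

import numpy as np
import pytest

from eggpale import FlowConfig, FlowModel, ImageGrid, svd_reproject_weights
from eggpale.errors import InputError
from eggpale.flow.model import (
    LOG_2PI,
    forward_map,
    inverse_map,
    log_likelihood,
    sample,
)
from eggpale.flow.model import LatentVector


def _finite_difference_logdet(model, x, eps=1e-6):
    d = x.size
    jac = np.zeros((d, d))
    shape = (1, 1) + x.shape
    for i in range(d):
        xp, xm = x.ravel().copy(), x.ravel().copy()
        xp[i] += eps
        xm[i] -= eps
        zp, _ = model.forward_array(xp.reshape(shape))
        zm, _ = model.forward_array(xm.reshape(shape))
        jac[:, i] = (zp[0] - zm[0]) / (2 * eps)
    _, logdet = np.linalg.slogdet(jac)
    return logdet


class TestIdentityFlow:
    def test_latent_is_permutation_of_pixels_with_zero_logdet(self, identity_model, rng):
        x = rng.uniform(-0.5, 0.5, (4, 4))
        z, logdet = forward_map(identity_model, ImageGrid(x, (-0.5, 0.5)))
        assert logdet == 0.0
        assert np.array_equal(np.sort(z.values), np.sort(x.ravel()))
        assert np.array_equal(inverse_map(identity_model, z).pixels, x)

    def test_zero_latent_maps_to_zero_image(self, identity_model):
        z = LatentVector(np.zeros(16), identity_model.layout)
        assert np.array_equal(inverse_map(identity_model, z).pixels, np.zeros((4, 4)))

    def test_log_likelihood_closed_form_at_zero(self, identity_model):
        img = ImageGrid(np.zeros((4, 4)), (-0.5, 0.5))
        # d = 16 here; the prior at z = 0 is -d/2 * log 2pi
        assert log_likelihood(identity_model, img) == pytest.approx(-8 * LOG_2PI)

    def test_log_likelihood_reduces_to_prior(self, identity_model, rng):
        x = rng.uniform(-0.5, 0.5, (4, 4))
        expected = -8 * LOG_2PI - 0.5 * np.sum(x ** 2)
        got = log_likelihood(identity_model, ImageGrid(x, (-0.5, 0.5)))
        assert got == pytest.approx(expected, rel=1e-12)


class TestInvertibility:
    def test_roundtrip_through_trained_model(self, mini_trained, rng):
        x = rng.uniform(-0.5, 0.5, (20, 1, 16, 16))
        z, _ = mini_trained.forward_array(x)
        assert np.abs(mini_trained.inverse_array(z) - x).max() < 1e-4

    def test_shape_mismatch_raises_input_error(self, mini_trained):
        with pytest.raises(InputError):
            mini_trained.forward_array(np.zeros((1, 1, 8, 8)))
        with pytest.raises(InputError):
            mini_trained.inverse_array(np.zeros((1, 99)))

    def test_uninitialized_actnorm_rejected(self, tiny_config):
        model = FlowModel(tiny_config, init="random")
        with pytest.raises(InputError, match="actnorm"):
            forward_map(model, ImageGrid(np.zeros((8, 8)), (-0.5, 0.5)))


@pytest.mark.parametrize("config_kwargs", [
    dict(image_size=8, n_levels=1, n_steps=1, hidden_width=4),
    dict(image_size=8, n_levels=2, n_steps=2, hidden_width=8),
    dict(image_size=16, n_levels=3, n_steps=1, hidden_width=4),
])
def test_latent_dimension_equals_pixel_count(config_kwargs, rng):
    cfg = FlowConfig(batch_size=2, **config_kwargs)
    model = FlowModel(cfg, init="random")
    model.initialize_actnorm(
        rng.uniform(-0.5, 0.5, (4, 1, cfg.image_size, cfg.image_size)))
    x = rng.uniform(-0.5, 0.5, (2, 1, cfg.image_size, cfg.image_size))
    z, _ = model.forward_array(x)
    assert z.shape[1] == cfg.image_size ** 2
    assert sum(c * h * w for c, h, w in model.layout) == cfg.image_size ** 2


def test_forward_logdet_matches_finite_difference_jacobian(tiny_config, rng):
    model = FlowModel(tiny_config, init="random")
    model.initialize_actnorm(rng.uniform(-0.5, 0.5, (8, 1, 8, 8)))
    x = rng.uniform(-0.5, 0.5, (8, 8))
    _, logdet = model.forward_array(x[None, None])
    fd = _finite_difference_logdet(model, x)
    assert logdet[0] == pytest.approx(fd, rel=1e-3)


def test_log_likelihood_matches_prior_plus_fd_logdet(tiny_config, rng):
    model = FlowModel(tiny_config, init="random")
    model.initialize_actnorm(rng.uniform(-0.5, 0.5, (8, 1, 8, 8)))
    x = rng.uniform(-0.5, 0.5, (8, 8))
    z, _ = model.forward_array(x[None, None])
    expected = (-0.5 * 64 * LOG_2PI - 0.5 * (z ** 2).sum()
                + _finite_difference_logdet(model, x))
    got = log_likelihood(model, ImageGrid(x, (-0.5, 0.5)))
    assert got == pytest.approx(expected, rel=1e-3)


class TestSvdReprojection:
    def test_orthogonal_matrix_unchanged(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        assert np.allclose(svd_reproject_weights(q), q, atol=1e-6)

    def test_diagonal_matrix_cropped(self):
        w = np.diag([2.0, 1e-5])
        out = svd_reproject_weights(w, 1e-3, 1e3)
        assert np.allclose(np.sort(np.linalg.svd(out, compute_uv=False)),
                           [1e-3, 2.0])
        assert np.allclose(out, np.diag([2.0, 1e-3]), atol=1e-12)

    def test_idempotent_and_condition_bounded(self, rng):
        w = rng.standard_normal((6, 6)) * np.logspace(-6, 4, 6)
        once = svd_reproject_weights(w, 1e-3, 1e3)
        twice = svd_reproject_weights(once, 1e-3, 1e3)
        sv = np.linalg.svd(once, compute_uv=False)
        assert sv.min() >= 1e-3 * (1 - 1e-12) and sv.max() <= 1e3 * (1 + 1e-12)
        assert np.allclose(once, twice, atol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            svd_reproject_weights(np.zeros((2, 3)))
        with pytest.raises(InputError):
            svd_reproject_weights(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestSample:
    def test_zero_temperature_collapses_to_mode(self, mini_trained):
        imgs = sample(mini_trained, 3, temperature=0.0, seed=5)
        assert all(np.array_equal(im.pixels, imgs[0].pixels) for im in imgs)

    def test_same_seed_is_deterministic(self, mini_trained):
        a = sample(mini_trained, 2, temperature=0.7, seed=9)
        b = sample(mini_trained, 2, temperature=0.7, seed=9)
        for ia, ib in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)

    def test_samples_are_finite_and_in_range(self, mini_trained):
        for img in sample(mini_trained, 4, temperature=0.7, seed=2):
            assert np.all(np.isfinite(img.pixels))
            assert img.pixels.min() >= 0.0 and img.pixels.max() <= 255.0


def test_checkpoint_roundtrip(tmp_path, mini_trained, rng):
    path = tmp_path / "model.npz"
    mini_trained.save(path)
    loaded = FlowModel.load(path)
    assert loaded.param_hash() == mini_trained.param_hash()
    x = rng.uniform(-0.5, 0.5, (2, 1, 16, 16))
    za, _ = mini_trained.forward_array(x)
    zb, _ = loaded.forward_array(x)
    assert np.array_equal(za, zb)
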