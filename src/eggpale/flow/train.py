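"""Maximum-likelihood training of the flow by stochastic gradient descent."""

from __future__ import annotations

import logging

import numpy as np

from ..config import FlowConfig
from ..errors import InputError, NumericalError
from ..image import ImageGrid
from .model import LOG_2PI, FlowModel, model_space, reproject_model_weights

log = logging.getLogger(__name__)


class Adam:
    """Adam optimizer over the model's named parameters."""

    def __init__(self, model: FlowModel, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.state = {
            name: (np.zeros_like(p), np.zeros_like(p))
            for name, p, _ in model.parameters()
        }
        self.t = 0

    def step(self, model: FlowModel) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, param, grad in model.parameters():
            m, v = self.state[name]
            m += (1.0 - self.beta1) * (grad - m)
            v += (1.0 - self.beta2) * (grad ** 2 - v)
            param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_training_array(images, config: FlowConfig) -> np.ndarray:
    s = config.image_size
    if len(images) == 0:
        raise InputError("no training images supplied")
    stack = []
    for img in images:
        arr = img.pixels if isinstance(img, ImageGrid) else np.asarray(img)
        if arr.shape != (s, s):
            raise InputError(f"training image has shape {arr.shape}, expected {(s, s)}")
        if isinstance(img, ImageGrid):
            stack.append(model_space(img))
        else:
            stack.append(arr / 256.0 - 0.5)
    return np.asarray(stack)[:, None, :, :]


def train_flow(model: FlowModel, images, config: FlowConfig | None = None) -> FlowModel:
    """Train the flow on normal images by minimizing mean NLL.

    The first batch performs the data-dependent actnorm initialization; at the
    end of each epoch every invertible 1x1 weight is re-projected so its
    singular values stay inside ``[sv_min, sv_max]``. Per-epoch mean losses
    are recorded on ``model.epoch_losses`` (in nats per image). Training is
    fully reproducible given ``config.seed``.

    Images are accepted either as :class:`ImageGrid` in display units (any
    declared range; mapped to the flow's [-0.5, 0.5] working range) or as raw
    arrays in [0, 255]. Uniform dequantization noise of width 1/256 is added
    during training only.
    """
    if config is None:
        config = model.config
    data = _as_training_array(images, config)
    n = data.shape[0]
    if n < config.batch_size:
        raise InputError(
            f"need at least batch_size={config.batch_size} images, got {n}"
        )
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model, config.learning_rate)
    d = model.latent_dim
    model.epoch_losses = []
    for epoch in range(config.n_epochs):
        perm = rng.permutation(n)
        batch_losses = []
        n_batches = n // config.batch_size
        for bi in range(n_batches):
            idx = perm[bi * config.batch_size:(bi + 1) * config.batch_size]
            xb = data[idx] + rng.uniform(0.0, 1.0 / 256.0, size=data[idx].shape)
            if not model.actnorm_initialized:
                model.initialize_actnorm(xb)
            z, logdet, caches = model.forward_array(xb, want_cache=True)
            b = z.shape[0]
            nll = 0.5 * d * LOG_2PI + 0.5 * (z ** 2).sum(axis=1) - logdet
            loss = float(nll.mean())
            if not np.isfinite(loss):
                raise NumericalError(
                    f"NaN/inf loss at epoch {epoch} batch {bi}"
                )
            model.zero_grads()
            model.backward_array(z / b, caches, g=-1.0 / b)
            optimizer.step(model)
            batch_losses.append(loss)
        reproject_model_weights(model)
        epoch_loss = float(np.mean(batch_losses))
        model.epoch_losses.append(epoch_loss)
        log.info("epoch=%d loss=%.3f", epoch, epoch_loss)
    return model
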