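"""Multi-scale coupling-flow generative model with exact log-likelihood.

The model realizes an invertible map ``f_theta`` between images and a latent
vector of identical dimension. Each of ``n_levels`` levels starts with a
squeeze (spatial-to-channel reshape), applies ``n_steps`` flow steps
(actnorm, invertible 1x1 convolution, affine coupling), and — at every level
except the last — factors half of the channels out into the latent code. The
last level contributes all of its channels. The prior over the latent is
fixed to the standard Gaussian N(0, I), so log p(x) = log N(z; 0, I) +
log |det dz/dx| is available in closed form and Euclidean / L-infinity
distances in latent space are meaningful.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from ..config import FlowConfig
from ..errors import InputError, NumericalError
from ..image import ImageGrid
from .layers import FlowStep, squeeze, unsqueeze

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LatentVector:
    """Flat latent code plus the layout needed to unflatten it exactly.

    ``layout`` records, per factored-out tensor, its ``(channels, height,
    width)`` shape in concatenation order (level 1 first); each chunk is
    flattened in channel-major (C, H, W) raster order.
    """

    values: np.ndarray
    layout: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        expected = sum(c * h * w for c, h, w in self.layout)
        if self.values.size != expected:
            raise InputError(
                f"latent length {self.values.size} does not match layout "
                f"(expects {expected})"
            )


def model_space(img: ImageGrid) -> np.ndarray:
    """Map declared-range intensities onto the flow's working range [-0.5, 0.5]."""
    lo, hi = img.value_range
    return (img.pixels - lo) / (hi - lo + 1.0) - 0.5


def image_space(x: np.ndarray, value_range=(0.0, 255.0), clip: bool = True) -> ImageGrid:
    """Inverse of :func:`model_space`; optionally clip into the declared range."""
    lo, hi = value_range
    pixels = (x + 0.5) * (hi - lo + 1.0) + lo
    if clip:
        pixels = np.clip(pixels, lo, hi)
    return ImageGrid(pixels, value_range)


class FlowModel:
    """Invertible multi-scale coupling flow.

    Parameters
    ----------
    config
        Architecture/training hyperparameters.
    init
        ``"random"`` builds a trainable model (orthogonal 1x1 weights,
        He-initialized coupling nets with zero-initialized final layers, so the
        whole flow starts close to a volume-preserving permutation);
        ``"identity"`` builds an exact identity flow (unit actnorm, identity
        1x1 weights, zero coupling nets), mainly useful for verification.
    """

    def __init__(self, config: FlowConfig, init: str = "random"):
        self.config = config
        rng = np.random.default_rng(config.seed) if init == "random" else None
        self.levels: list[list[FlowStep]] = []
        channels = config.channels
        for _ in range(config.n_levels):
            channels *= 4
            steps = [
                FlowStep(channels, config.hidden_width, config.n_coupling_convs,
                         config.kernel_size, rng)
                for _ in range(config.n_steps)
            ]
            self.levels.append(steps)
            channels //= 2  # split factors half the channels into the latent
        self.layout = self._compute_layout()
        self.actnorm_initialized = init == "identity"

    # -- structure ----------------------------------------------------------

    def _compute_layout(self) -> tuple[tuple[int, int, int], ...]:
        layout = []
        c, s = self.config.channels, self.config.image_size
        for level in range(self.config.n_levels):
            c, s = c * 4, s // 2
            if level < self.config.n_levels - 1:
                layout.append((c // 2, s, s))
                c //= 2
            else:
                layout.append((c, s, s))
        return tuple(layout)

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def _all_layers(self):
        for steps in self.levels:
            for step in steps:
                yield from step.layers_with_params()

    def parameters(self):
        """Yield ``(name, param_array, grad_array)`` triples."""
        for i, layer in enumerate(self._all_layers()):
            for key in layer.params:
                yield f"layer{i}.{key}", layer.params[key], layer.grads[key]

    def zero_grads(self) -> None:
        for layer in self._all_layers():
            for key in layer.grads:
                layer.grads[key][:] = 0.0

    def param_hash(self) -> str:
        """SHA-256 over the config and all parameter bytes (provenance check)."""
        digest = hashlib.sha256()
        digest.update(json.dumps(self.config.__dict__, sort_keys=True).encode())
        for name, param, _ in self.parameters():
            digest.update(name.encode())
            digest.update(np.ascontiguousarray(param).tobytes())
        return digest.hexdigest()

    # -- forward / inverse --------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        s, c = self.config.image_size, self.config.channels
        if x.ndim != 4 or x.shape[1:] != (c, s, s):
            raise InputError(
                f"expected input of shape (B, {c}, {s}, {s}), got {x.shape}"
            )

    def forward_array(self, x: np.ndarray, want_cache: bool = False):
        """Run the flow on a batch of model-space images.

        Returns ``(z, logdet)`` with ``z`` of shape ``(B, latent_dim)``, or
        ``(z, logdet, caches)`` when ``want_cache`` is set (for backprop).
        """
        x = np.asarray(x, dtype=np.float64)
        self._check_input(x)
        h = x
        logdet = np.zeros(x.shape[0])
        zs, caches = [], []
        for level, steps in enumerate(self.levels):
            h = squeeze(h)
            for si, step in enumerate(steps):
                h, ld, cache = step.forward(h)
                if not np.all(np.isfinite(h)):
                    raise NumericalError(
                        f"non-finite activations after level {level} step {si}"
                    )
                logdet += ld
                caches.append(cache)
            if level < len(self.levels) - 1:
                z_part, h = np.split(h, 2, axis=1)
                zs.append(z_part)
            else:
                zs.append(h)
        z = np.concatenate([p.reshape(p.shape[0], -1) for p in zs], axis=1)
        if want_cache:
            return z, logdet, caches
        return z, logdet

    def _split_latent(self, z: np.ndarray) -> list[np.ndarray]:
        parts = []
        offset = 0
        for c, h, w in self.layout:
            n = c * h * w
            parts.append(z[:, offset:offset + n].reshape(z.shape[0], c, h, w))
            offset += n
        return parts

    def inverse_array(self, z: np.ndarray) -> np.ndarray:
        """Exact inverse of :meth:`forward_array` (batchwise)."""
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 2 or z.shape[1] != self.latent_dim:
            raise InputError(
                f"expected latent of shape (B, {self.latent_dim}), got {z.shape}"
            )
        parts = self._split_latent(z)
        h = parts[-1]
        for level in reversed(range(len(self.levels))):
            if level < len(self.levels) - 1:
                h = np.concatenate([parts[level], h], axis=1)
            for step in reversed(self.levels[level]):
                h = step.inverse(h)
            h = unsqueeze(h)
        return h

    def backward_array(self, dz: np.ndarray, caches, g: float) -> None:
        """Accumulate parameter gradients given dL/dz and dL/d(logdet_i)=g."""
        parts = self._split_latent(dz)
        dh = parts[-1]
        cache_iter = iter(reversed(caches))
        for level in reversed(range(len(self.levels))):
            if level < len(self.levels) - 1:
                dh = np.concatenate([parts[level], dh], axis=1)
            for step in reversed(self.levels[level]):
                dh = step.backward(dh, next(cache_iter), g)
            dh = unsqueeze(dh)

    # -- actnorm init -------------------------------------------------------

    def initialize_actnorm(self, x: np.ndarray) -> None:
        """Data-dependent actnorm initialization on one batch.

        Runs the flow forward; just before each actnorm layer is applied its
        scale/bias are set so its output has per-channel zero mean and unit
        variance on this batch.
        """
        x = np.asarray(x, dtype=np.float64)
        self._check_input(x)
        h = x
        for level, steps in enumerate(self.levels):
            h = squeeze(h)
            for step in steps:
                step.actnorm.initialize(h)
                h, _, _ = step.forward(h)
            if level < len(self.levels) - 1:
                _, h = np.split(h, 2, axis=1)
        self.actnorm_initialized = True

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write a single-file checkpoint (npz: params + config + layout)."""
        arrays = {name: param for name, param, _ in self.parameters()}
        meta = {
            "schema_version": 1,
            "config": self.config.__dict__,
            "actnorm_initialized": bool(self.actnorm_initialized),
            "layout": self.layout,
        }
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "FlowModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            model = cls(FlowConfig(**meta["config"]), init="random")
            for name, param, _ in model.parameters():
                param[:] = data[name]
        model.actnorm_initialized = meta["actnorm_initialized"]
        for steps in model.levels:
            for step in steps:
                step.actnorm.initialized = model.actnorm_initialized
        return model


# ---------------------------------------------------------------------------
# Spec-level operations on single images
# ---------------------------------------------------------------------------

def forward_map(model: FlowModel, x: ImageGrid) -> tuple[LatentVector, float]:
    """Map one image to its latent code; returns ``(z, logdet)``.

    The image is consumed as-is (no intensity rescaling); callers working in
    display units should first convert with :func:`model_space`.
    """
    if not model.actnorm_initialized:
        raise InputError(
            "actnorm is not initialized; train the model or supply an "
            "initialization batch via initialize_actnorm"
        )
    arr = x.pixels[None, None, :, :]
    z, logdet = model.forward_array(arr)
    return LatentVector(z[0], model.layout), float(logdet[0])


def inverse_map(model: FlowModel, z: LatentVector) -> ImageGrid:
    """Map a latent code back to image space (exact inverse of forward_map)."""
    if z.values.size != model.latent_dim:
        raise InputError(
            f"latent length {z.values.size} != model latent dim {model.latent_dim}"
        )
    x = model.inverse_array(z.values[None, :])
    s = model.config.image_size
    return ImageGrid(x[0, 0].reshape(s, s), value_range=(-np.inf, np.inf))


def log_prior(z: np.ndarray) -> np.ndarray:
    """log N(z; 0, I) along the last axis."""
    z = np.atleast_2d(z)
    d = z.shape[-1]
    return -0.5 * d * LOG_2PI - 0.5 * (z ** 2).sum(axis=-1)


def log_likelihood(model: FlowModel, x: ImageGrid) -> float:
    """Exact log p(x) = log N(z; 0, I) + log |det dz/dx|."""
    z, logdet = forward_map(model, x)
    return float(log_prior(z.values[None, :])[0] + logdet)


def sample(model: FlowModel, n: int, temperature: float = 0.7,
           seed: int = 0) -> list[ImageGrid]:
    """Draw n images from the model: z ~ N(0, temperature^2 I), x = f^-1(z).

    Outputs are converted from model space to [0, 255] and clipped.
    """
    rng = np.random.default_rng(seed)
    z = temperature * rng.standard_normal((n, model.latent_dim))
    x = model.inverse_array(z)
    return [image_space(x[i, 0]) for i in range(n)]


def svd_reproject_weights(weight: np.ndarray, sv_min: float = 1e-3,
                          sv_max: float = 1e3) -> np.ndarray:
    """Re-project a square weight so all singular values lie in [sv_min, sv_max].

    W = U S V^T is recomposed as U clip(S) V^T, which guarantees an inverse
    with condition number at most sv_max / sv_min. Matrices already in range
    are returned unchanged up to floating-point round-off, and the operation
    is idempotent.
    """
    weight = np.asarray(weight, dtype=np.float64)
    if weight.ndim != 2 or weight.shape[0] != weight.shape[1]:
        raise InputError(f"expected a square matrix, got shape {weight.shape}")
    if not np.all(np.isfinite(weight)):
        raise InputError("weight matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(weight)
    if s.size and s.min() >= sv_min and s.max() <= sv_max:
        return weight
    s_new = np.clip(s, sv_min, sv_max)
    return (u * s_new) @ vt


def reproject_model_weights(model: FlowModel) -> None:
    """Apply the singular-value crop to every 1x1 convolution in the model."""
    cfg = model.config
    for steps in model.levels:
        for step in steps:
            w = step.inv1x1.params["weight"]
            w[:] = svd_reproject_weights(w, cfg.sv_min, cfg.sv_max)
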