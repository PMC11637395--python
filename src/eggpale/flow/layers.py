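"""Invertible layers of the coupling flow, with manual reverse-mode gradients.

All layers operate on activations of shape ``(B, C, H, W)`` in float64 and
follow the same protocol:

* ``forward(x)   -> (y, logdet, cache)`` — ``logdet`` has shape ``(B,)`` and is
  the per-sample log |det dy/dx|.
* ``inverse(y)   -> x`` — the exact algebraic inverse.
* ``backward(dy, cache, g) -> dx`` — reverse-mode propagation of the loss
  gradient. ``g`` is dL/d(logdet_i), a scalar identical for every sample
  (``-1/B`` when the loss is the mean negative log-likelihood); each layer adds
  its own logdet contribution to its parameter gradients.

Gradients are accumulated into each layer's ``grads`` dict, keyed like
``params``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import InvertibilityError


# ---------------------------------------------------------------------------
# Plain 3x3 'same' convolution (the coupling-net building block)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H, W, C*k*k) patch matrix with zero 'same' padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    b, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h, w, c * k * k)


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Same-padded 2-D convolution.

    ``weight`` has shape ``(C_out, C_in * k * k)``; returns ``(y, cache)``.
    """
    k = int(np.sqrt(weight.shape[1] // x.shape[1]))
    cols = _im2col(x, k)
    y = cols @ weight.T + bias  # (B, H, W, C_out)
    return y.transpose(0, 3, 1, 2), (cols, x.shape, k)


def conv2d_backward(dy: np.ndarray, weight: np.ndarray, cache):
    """Gradients of conv2d_forward. Returns ``(dx, dweight, dbias)``."""
    cols, x_shape, k = cache
    b, c, h, w = x_shape
    dyp = dy.transpose(0, 2, 3, 1)  # (B, H, W, C_out)
    dweight = np.tensordot(dyp, cols, axes=([0, 1, 2], [0, 1, 2]))
    dbias = dyp.sum(axis=(0, 1, 2))
    dcols = dyp @ weight  # (B, H, W, C_in*k*k)
    dcols = dcols.reshape(b, h, w, c, k, k)
    pad = k // 2
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    dx = dxp[:, :, pad:pad + h, pad:pad + w]
    return dx, dweight, dbias


# ---------------------------------------------------------------------------
# Squeeze (spatial-to-channel reshaping; volume-preserving, logdet = 0)
# ---------------------------------------------------------------------------

def squeeze(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, 4C, H/2, W/2)."""
    b, c, h, w = x.shape
    x = x.reshape(b, c, h // 2, 2, w // 2, 2)
    return x.transpose(0, 1, 3, 5, 2, 4).reshape(b, 4 * c, h // 2, w // 2)


def unsqueeze(y: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`squeeze`."""
    b, c4, h2, w2 = y.shape
    c = c4 // 4
    y = y.reshape(b, c, 2, 2, h2, w2)
    return y.transpose(0, 1, 4, 2, 5, 3).reshape(b, c, 2 * h2, 2 * w2)


# ---------------------------------------------------------------------------
# Actnorm
# ---------------------------------------------------------------------------

class ActNorm:
    """Per-channel affine normalization ``y = exp(logs) * x + bias``.

    The parameters are data-dependently initialized on the first training
    batch so the post-actnorm activations have zero mean and unit variance
    per channel.
    """

    def __init__(self, channels: int):
        self.params = {"logs": np.zeros(channels), "bias": np.zeros(channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.initialized = False

    def initialize(self, x: np.ndarray, eps: float = 1e-8) -> None:
        mean = x.mean(axis=(0, 2, 3))
        std = x.std(axis=(0, 2, 3)) + eps
        self.params["logs"][:] = -np.log(std)
        self.params["bias"][:] = -mean / std
        self.initialized = True

    def forward(self, x: np.ndarray):
        s = np.exp(self.params["logs"])
        y = x * s[None, :, None, None] + self.params["bias"][None, :, None, None]
        hw = x.shape[2] * x.shape[3]
        logdet = np.full(x.shape[0], hw * self.params["logs"].sum())
        return y, logdet, x

    def inverse(self, y: np.ndarray) -> np.ndarray:
        s = np.exp(self.params["logs"])
        return (y - self.params["bias"][None, :, None, None]) / s[None, :, None, None]

    def backward(self, dy: np.ndarray, cache, g: float) -> np.ndarray:
        x = cache
        b, _, h, w = x.shape
        s = np.exp(self.params["logs"])
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        # logdet_i = H*W*sum(logs) for every sample -> total logdet grad g*B*H*W
        self.grads["logs"] += (dy * x).sum(axis=(0, 2, 3)) * s + g * b * h * w
        return dy * s[None, :, None, None]


# ---------------------------------------------------------------------------
# Invertible 1x1 convolution
# ---------------------------------------------------------------------------

class Invertible1x1:
    """Channel-mixing linear map ``y[.,:,h,w] = W @ x[.,:,h,w]``."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        if rng is None:
            weight = np.eye(channels)
        else:
            # random rotation: logdet starts at exactly 0
            q, _ = np.linalg.qr(rng.standard_normal((channels, channels)))
            weight = q
        self.params = {"weight": weight}
        self.grads = {"weight": np.zeros_like(weight)}

    def forward(self, x: np.ndarray):
        weight = self.params["weight"]
        y = np.einsum("ij,bjhw->bihw", weight, x)
        sign, logabsdet = np.linalg.slogdet(weight)
        if sign == 0 or not np.isfinite(logabsdet):
            raise InvertibilityError(
                "1x1 convolution weight is singular; run svd_reproject_weights"
            )
        hw = x.shape[2] * x.shape[3]
        logdet = np.full(x.shape[0], hw * logabsdet)
        return y, logdet, x

    def inverse(self, y: np.ndarray) -> np.ndarray:
        weight = self.params["weight"]
        try:
            w_inv = np.linalg.inv(weight)
        except np.linalg.LinAlgError as exc:
            raise InvertibilityError(
                "1x1 convolution weight is singular; run svd_reproject_weights"
            ) from exc
        return np.einsum("ij,bjhw->bihw", w_inv, y)

    def backward(self, dy: np.ndarray, cache, g: float) -> np.ndarray:
        x = cache
        b, _, h, w = x.shape
        weight = self.params["weight"]
        self.grads["weight"] += np.einsum("bihw,bjhw->ij", dy, x)
        # d(log|det W|)/dW = inv(W).T, identical per sample
        self.grads["weight"] += g * b * h * w * np.linalg.inv(weight).T
        return np.einsum("ji,bjhw->bihw", weight, dy)


# ---------------------------------------------------------------------------
# Affine coupling
# ---------------------------------------------------------------------------

class CouplingNet:
    """Small conv net predicting (scale, shift) from the untouched half.

    ``n_convs`` same-padded convolutions with ReLU between them; the final
    convolution is zero-initialized so the enclosing coupling layer starts as
    the identity map.
    """

    def __init__(self, c_in: int, c_out: int, hidden: int, n_convs: int,
                 kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        widths = [c_in] + [hidden] * (n_convs - 1) + [c_out]
        self.params = {}
        for i in range(n_convs):
            fan_in = widths[i] * kernel * kernel
            if i == n_convs - 1:
                w = np.zeros((widths[i + 1], fan_in))
            else:
                w = rng.standard_normal((widths[i + 1], fan_in)) * np.sqrt(2.0 / fan_in)
            self.params[f"w{i}"] = w
            self.params[f"b{i}"] = np.zeros(widths[i + 1])
        self.n_convs = n_convs
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray):
        caches = []
        h = x
        for i in range(self.n_convs):
            h, cache = conv2d_forward(h, self.params[f"w{i}"], self.params[f"b{i}"])
            relu_mask = None
            if i < self.n_convs - 1:
                relu_mask = h > 0
                h = h * relu_mask
            caches.append((cache, relu_mask))
        return h, caches

    def backward(self, dout: np.ndarray, caches) -> np.ndarray:
        dh = dout
        for i in reversed(range(self.n_convs)):
            cache, relu_mask = caches[i]
            if relu_mask is not None:
                dh = dh * relu_mask
            dh, dw, db = conv2d_backward(dh, self.params[f"w{i}"], cache)
            self.grads[f"w{i}"] += dw
            self.grads[f"b{i}"] += db
        return dh


class AffineCoupling:
    """Affine coupling: the first half of the channels passes through and
    parameterizes an element-wise affine map of the second half.

    The log-scale is ``tanh`` of the net output, i.e. ``s = exp(tanh(raw))``,
    which is bounded inside ``[1/e, e]`` — away from zero — and equals 1 when
    the (zero-initialized) net outputs 0, so every step starts as identity.
    """

    def __init__(self, channels: int, hidden: int, n_convs: int, kernel: int,
                 rng: np.random.Generator):
        self.c_half = channels // 2
        self.net = CouplingNet(self.c_half, 2 * (channels - self.c_half),
                               hidden, n_convs, kernel, rng)
        self.params = self.net.params
        self.grads = self.net.grads

    def _scale_shift(self, x_a: np.ndarray):
        out, caches = self.net.forward(x_a)
        raw, t = np.split(out, 2, axis=1)
        th = np.tanh(raw)
        s = np.exp(th)
        return s, th, t, caches

    def forward(self, x: np.ndarray):
        x_a, x_b = x[:, :self.c_half], x[:, self.c_half:]
        s, th, t, net_caches = self._scale_shift(x_a)
        y_b = s * x_b + t
        y = np.concatenate([x_a, y_b], axis=1)
        logdet = th.sum(axis=(1, 2, 3))
        return y, logdet, (x_a, x_b, s, th, net_caches)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        y_a, y_b = y[:, :self.c_half], y[:, self.c_half:]
        s, _, t, _ = self._scale_shift(y_a)
        x_b = (y_b - t) / s
        return np.concatenate([y_a, x_b], axis=1)

    def backward(self, dy: np.ndarray, cache, g: float) -> np.ndarray:
        x_a, x_b, s, th, net_caches = cache
        dy_a, dy_b = dy[:, :self.c_half], dy[:, self.c_half:]
        dx_b = dy_b * s
        # logdet_i = sum(th); both the y_b path and the logdet path reach th
        dth = dy_b * s * x_b + g
        draw = dth * (1.0 - th ** 2)
        dt = dy_b
        dout = np.concatenate([draw, dt], axis=1)
        dx_a = self.net.backward(dout, net_caches)
        return np.concatenate([dy_a + dx_a, dx_b], axis=1)


class FlowStep:
    """One (actnorm, invertible 1x1 convolution, affine coupling) step."""

    def __init__(self, channels: int, hidden: int, n_convs: int, kernel: int,
                 rng: np.random.Generator | None):
        self.actnorm = ActNorm(channels)
        self.inv1x1 = Invertible1x1(channels, rng)
        net_rng = rng if rng is not None else np.random.default_rng(0)
        self.coupling = AffineCoupling(channels, hidden, n_convs, kernel, net_rng)
        if rng is None:
            # identity construction: zero coupling net already guarantees it
            for key in self.coupling.params:
                if key.startswith("w"):
                    self.coupling.params[key][:] = 0.0
            self.actnorm.initialized = True
        self.sublayers = [self.actnorm, self.inv1x1, self.coupling]

    def forward(self, x: np.ndarray):
        logdet = np.zeros(x.shape[0])
        caches = []
        h = x
        for layer in self.sublayers:
            h, ld, cache = layer.forward(h)
            logdet += ld
            caches.append(cache)
        return h, logdet, caches

    def inverse(self, y: np.ndarray) -> np.ndarray:
        h = y
        for layer in reversed(self.sublayers):
            h = layer.inverse(h)
        return h

    def backward(self, dy: np.ndarray, caches, g: float) -> np.ndarray:
        dh = dy
        for layer, cache in zip(reversed(self.sublayers), reversed(caches)):
            dh = layer.backward(dh, cache, g)
        return dh

    def layers_with_params(self):
        return self.sublayers
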