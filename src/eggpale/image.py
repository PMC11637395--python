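"""Grayscale image container used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass
class ImageGrid:
    """A 2-D grayscale image with declared intensity range.

    Parameters
    ----------
    pixels
        2-D float array of intensities, shape ``(height, width)``.
    value_range
        Declared ``(min, max)`` of the intensity encoding. Pixel values are
        expected to lie inside this range (enforced by :meth:`validate`).
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError(f"expected a 2-D image, got ndim={self.pixels.ndim}")

    @property
    def size(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape  # type: ignore[return-value]

    def validate(self, require_square: bool = False, atol: float = 1e-6) -> None:
        lo, hi = self.value_range
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("image contains non-finite pixels")
        if self.pixels.min() < lo - atol or self.pixels.max() > hi + atol:
            raise InputError(
                f"pixels outside declared value range [{lo}, {hi}]: "
                f"observed [{self.pixels.min()}, {self.pixels.max()}]"
            )
        if require_square and self.pixels.shape[0] != self.pixels.shape[1]:
            raise InputError(f"image must be square, got {self.pixels.shape}")

    def clipped(self) -> "ImageGrid":
        """Return a copy with pixels clipped into the declared range."""
        lo, hi = self.value_range
        return ImageGrid(np.clip(self.pixels, lo, hi), self.value_range)
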