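"""Radiograph normalization: windowing, geometry standardization, up-sampling.

The chain mirrors common PA-chest preprocessing: raw intensities are windowed
(window center / width, taken from DICOM tags when present) onto [0, 255];
the image is rescaled so its width matches a square canvas, with taller
images symmetrically truncated and shorter ones symmetrically zero-padded;
the canvas is then down-sampled (area-averaged, anti-aliased) to the model
resolution. After enhancement, outputs are up-sampled back to display size
with bicubic interpolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize

from .errors import InputError, ParameterError
from .image import ImageGrid

log = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Intensity window: the raw range [center - width/2, center + width/2]
    is mapped linearly onto [0, 255]; values outside saturate."""

    center: float
    width: float
    source: str = "explicit"  # dicom_tags | explicit | full_range

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")


def full_range_window(raw: np.ndarray) -> WindowSpec:
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi <= lo:
        hi = lo + 1.0
    return WindowSpec(center=(lo + hi) / 2.0, width=hi - lo, source="full_range")


def window_to_unit_range(raw: ImageGrid, w: WindowSpec) -> ImageGrid:
    """Linearly map the window onto [0, 255], clamping outside values."""
    if not np.all(np.isfinite(raw.pixels)):
        raise InputError("raw image contains non-finite intensities")
    lo = w.center - w.width / 2.0
    scaled = (raw.pixels - lo) / w.width * 255.0
    return ImageGrid(np.clip(scaled, 0.0, 255.0), value_range=(0.0, 255.0))


def standardize_geometry(img: ImageGrid, target_canvas: int,
                         model_size: int) -> ImageGrid:
    """Rescale to canvas width, square the height, down-sample to model size.

    The image is resized so its width equals ``target_canvas`` (aspect ratio
    preserved), the height is symmetrically truncated (taller) or
    symmetrically zero-padded (shorter) to ``target_canvas``, and the square
    canvas is area-averaged down to ``model_size x model_size``.
    """
    h, w = img.pixels.shape
    if h == 0 or w == 0:
        raise InputError("degenerate image with a zero dimension")
    new_h = max(1, round(h * target_canvas / w))
    arr = img.pixels
    if (new_h, target_canvas) != (h, w):
        arr = resize(arr, (new_h, target_canvas), order=1,
                     mode="edge", anti_aliasing=new_h < h, preserve_range=True)
    if new_h > target_canvas:
        top = (new_h - target_canvas) // 2
        arr = arr[top:top + target_canvas, :]
    elif new_h < target_canvas:
        pad_top = (target_canvas - new_h) // 2
        pad_bottom = target_canvas - new_h - pad_top
        arr = np.pad(arr, ((pad_top, pad_bottom), (0, 0)))
    if model_size != target_canvas:
        arr = resize(arr, (model_size, model_size), order=1,
                     mode="edge", anti_aliasing=True, preserve_range=True)
    lo, hi = img.value_range
    return ImageGrid(np.clip(arr, lo, hi), value_range=img.value_range)


def upsample_output(img: ImageGrid, display_size: int) -> ImageGrid:
    """Bicubic up-sampling of a square image to display resolution."""
    h, w = img.pixels.shape
    if h != w:
        raise InputError(f"expected a square image, got {img.pixels.shape}")
    if display_size == h:
        return ImageGrid(img.pixels.copy(), img.value_range)
    arr = resize(img.pixels, (display_size, display_size), order=3,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    lo, hi = img.value_range
    return ImageGrid(np.clip(arr, lo, hi), value_range=img.value_range)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_image(path: str | Path, window: WindowSpec | None = None,
               invert_monochrome1: bool = True) -> ImageGrid:
    """Read a PNG/TIFF (8/16-bit) or DICOM radiograph, windowed onto [0, 255].

    For DICOM, the window center/width tags (0028,1050)/(0028,1051) are
    honored when present; otherwise — and always for PNG/TIFF unless an
    explicit window is given — a full-range min/max window is used (with a
    logged warning for DICOM).
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        raw = ds.pixel_array.astype(np.float64)
        if invert_monochrome1 and getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
            raw = raw.max() - raw
        if window is None:
            center = getattr(ds, "WindowCenter", None)
            width = getattr(ds, "WindowWidth", None)
            if center is not None and width is not None:
                if isinstance(center, pydicom.multival.MultiValue):
                    center = center[0]
                if isinstance(width, pydicom.multival.MultiValue):
                    width = width[0]
                window = WindowSpec(float(center), float(width), source="dicom_tags")
            else:
                log.warning("DICOM %s lacks window tags; using full-range scaling", path)
                window = full_range_window(raw)
    else:
        with PILImage.open(path) as im:
            raw = np.asarray(im, dtype=np.float64)
        if raw.ndim == 3:
            raw = raw.mean(axis=2)
        if window is None:
            window = full_range_window(raw)
    lo, hi = raw.min(), raw.max()
    grid = ImageGrid(raw, value_range=(min(lo, 0.0), max(hi, 1.0)))
    return window_to_unit_range(grid, window)


def write_png(img: ImageGrid, path: str | Path) -> None:
    """Write an 8-bit PNG, rescaling the declared range to [0, 255]."""
    lo, hi = img.value_range
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    arr = np.clip((img.pixels - lo) * scale, 0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(str(path))


def write_sidecar(path: str | Path, **provenance) -> None:
    """Write a JSON sidecar with run provenance next to an output image."""
    Path(path).write_text(json.dumps(provenance, indent=2, sort_keys=True))
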