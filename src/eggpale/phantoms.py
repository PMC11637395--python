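"""Synthetic PA-chest phantoms with injectable nodules and ground-truth masks.

The generator emulates the gross structure of a posteroanterior chest
radiograph at low resolution: a bright thorax field on a dark frame, two
darker elliptical lung fields, a bright mediastinal column between them, and
periodic rib-like bands across the lungs. Per-image geometric jitter and
Gaussian intensity noise make every phantom unique but reproducible from its
seed. Nodules are Gaussian blobs of configurable full-width-at-half-maximum
diameter and peak contrast, injected inside the lung-field mask together
with a half-maximum ROI mask — a stand-in for manually outlined clinical
nodule ROIs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, PlacementError
from .image import ImageGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Parameters of the normal-phantom generator (intensities in [0, 255])."""

    size: int = 32
    n_ribs: int = 4
    rib_contrast: float = 14.0
    mediastinum_width_frac: float = 0.22
    noise_sd: float = 4.0
    jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ParameterError("phantom size must be >= 16")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 < self.mediastinum_width_frac < 1.0:
            raise ParameterError("mediastinum_width_frac must be in (0, 1)")


@dataclass
class NoduleSpec:
    """One synthetic nodule: Gaussian blob with FWHM ``diameter`` pixels and
    ``contrast`` intensity units added at the peak."""

    center: tuple[int, int]  # (row, col), 0-based
    diameter: float
    contrast: float
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        if self.diameter < 2:
            raise ParameterError("nodule diameter must be >= 2 pixels")
        if self.profile != "gaussian":
            raise ParameterError(f"unknown nodule profile {self.profile!r}")


@dataclass
class PhantomRecord:
    """A phantom image, its lung-field mask and per-nodule ROI masks."""

    image: ImageGrid
    lung_mask: np.ndarray
    nodule_masks: list[np.ndarray] = field(default_factory=list)
    nodules: list[NoduleSpec] = field(default_factory=list)
    spec: PhantomSpec | None = None
    case_id: int = 0

    def manifest_entry(self) -> dict:
        return {
            "case_id": self.case_id,
            "spec": dataclasses.asdict(self.spec) if self.spec else None,
            "nodules": [dataclasses.asdict(n) for n in self.nodules],
        }


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size]
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def _render_phantom(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one normal phantom; returns (image array, lung mask)."""
    s = spec.size
    j = spec.jitter

    def jit(scale: float = 1.0) -> float:
        return 1.0 + scale * j * rng.standard_normal()

    img = np.full((s, s), 30.0)  # dark frame outside the body

    # thorax: bright ellipse filling most of the frame
    thorax_cy, thorax_cx = s * 0.55 * jit(), s * 0.5 * jit()
    thorax_ry, thorax_rx = s * 0.46 * jit(), s * 0.44 * jit()
    thorax = _ellipse_mask(s, thorax_cy, thorax_cx, thorax_ry, thorax_rx)
    img[thorax] = 185.0

    # lung fields: two darker ellipses inside the thorax
    lung_ry, lung_rx = s * 0.30 * jit(), s * 0.155 * jit()
    lung_cy = s * 0.48 * jit()
    offset = s * (spec.mediastinum_width_frac / 2.0 + 0.16) * jit(0.5)
    lungs = np.zeros((s, s), dtype=bool)
    for sign in (-1.0, 1.0):
        lungs |= _ellipse_mask(s, lung_cy, s * 0.5 + sign * offset, lung_ry, lung_rx)
    lungs &= thorax
    img[lungs] = 95.0

    # rib-like periodic bands across the lung fields
    rows = np.arange(s)[:, None]
    # the rib phase is part of the per-image jitter; zero jitter freezes it
    phase = rng.uniform(0.0, 2.0 * np.pi) * (1.0 if j > 0 else 0.0)
    bands = 0.5 * (1.0 + np.sin(2.0 * np.pi * spec.n_ribs * rows / s + phase))
    img[lungs] += (spec.rib_contrast * bands * np.ones((s, s)))[lungs]

    # mediastinal bright column between the lungs
    half_w = s * spec.mediastinum_width_frac / 2.0 * jit(0.5)
    cols = np.arange(s)[None, :]
    medi = (np.abs(cols - s * 0.5) <= half_w) & thorax & ~lungs
    img[medi] = 205.0

    img += rng.normal(0.0, spec.noise_sd, size=(s, s))
    return np.clip(img, 0.0, 255.0), lungs


def generate_normal(spec: PhantomSpec, n: int) -> list[PhantomRecord]:
    """Generate n normal phantoms (no nodules), reproducible from spec.seed."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(n):
        arr, lungs = _render_phantom(spec, rng)
        records.append(PhantomRecord(
            image=ImageGrid(arr, (0.0, 255.0)), lung_mask=lungs,
            spec=spec, case_id=i,
        ))
    return records


def _nodule_blob(size: int, nodule: NoduleSpec) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.mgrid[0:size, 0:size]
    cy, cx = nodule.center
    sigma = nodule.diameter * FWHM_TO_SIGMA
    r2 = (rows - cy) ** 2.0 + (cols - cx) ** 2.0
    blob = np.exp(-r2 / (2.0 * sigma ** 2))
    roi = blob >= 0.5  # half-maximum disc, radius = diameter / 2
    return nodule.contrast * blob, roi


def inject_nodules(record: PhantomRecord, nodules: list[NoduleSpec]) -> PhantomRecord:
    """Return a new record with Gaussian nodules added inside the lung field.

    The original record is left unmodified. Each nodule's ROI mask is the
    half-maximum disc of its blob; nodule centers (and their ROIs) must lie
    inside the lung-field mask.
    """
    size = record.image.pixels.shape[0]
    arr = record.image.pixels.copy()
    masks = [m.copy() for m in record.nodule_masks]
    for nodule in nodules:
        cy, cx = nodule.center
        if not (0 <= cy < size and 0 <= cx < size) or not record.lung_mask[cy, cx]:
            raise PlacementError(
                f"nodule center {nodule.center} is outside the lung field"
            )
        blob, roi = _nodule_blob(size, nodule)
        if not np.all(record.lung_mask[roi]):
            raise PlacementError(
                f"nodule at {nodule.center} (diameter {nodule.diameter}) "
                "extends outside the lung field"
            )
        arr = np.clip(arr + blob, 0.0, 255.0)
        masks.append(roi)
    return PhantomRecord(
        image=ImageGrid(arr, record.image.value_range),
        lung_mask=record.lung_mask.copy(),
        nodule_masks=masks,
        nodules=list(record.nodules) + list(nodules),
        spec=record.spec,
        case_id=record.case_id,
    )


DEFAULT_NODULE_COUNT_DIST = {1: 0.70, 2: 0.27, 3: 0.03}  # mean 1.33 nodules/case


def generate_eval_set(spec: PhantomSpec, n_cases: int,
                      nodules_per_case: dict[int, float] | None = None,
                      seed: int = 1,
                      diameter_range: tuple[float, float] = (4.0, 8.0),
                      contrast_range: tuple[float, float] = (20.0, 45.0),
                      ) -> list[PhantomRecord]:
    """Generate a reproducible evaluation set of phantoms with nodules.

    Per-case nodule counts are drawn from ``nodules_per_case`` (a mapping
    count -> probability; default mean 1.33 nodules per case); diameters and
    contrasts are uniform over the given ranges; centers are uniform over
    lung-field pixels whose half-maximum disc fits inside the lung mask.
    """
    if n_cases < 1:
        raise ParameterError("n_cases must be >= 1")
    if nodules_per_case is None:
        nodules_per_case = DEFAULT_NODULE_COUNT_DIST
    counts = np.array(sorted(nodules_per_case))
    probs = np.array([nodules_per_case[c] for c in counts], dtype=np.float64)
    probs /= probs.sum()
    base_spec = dataclasses.replace(spec, seed=seed)
    normals = generate_normal(base_spec, n_cases)
    rng = np.random.default_rng(seed + 1)
    out = []
    for record in normals:
        n_nod = int(rng.choice(counts, p=probs))
        nodules = []
        for _ in range(n_nod):
            for _attempt in range(200):
                diameter = float(rng.uniform(*diameter_range))
                contrast = float(rng.uniform(*contrast_range))
                lung_idx = np.argwhere(record.lung_mask)
                cy, cx = lung_idx[rng.integers(len(lung_idx))]
                candidate = NoduleSpec((int(cy), int(cx)), diameter, contrast)
                _, roi = _nodule_blob(spec.size, candidate)
                if np.all(record.lung_mask[roi]):
                    nodules.append(candidate)
                    break
            else:
                raise PlacementError(
                    "could not place a nodule inside the lung field; "
                    "lung mask too small for the requested diameter range"
                )
        out.append(inject_nodules(record, nodules))
    return out
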