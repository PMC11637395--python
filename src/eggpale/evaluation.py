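"""Contrast-to-noise-ratio evaluation of enhancement.

For each nodule, the contrast-to-noise ratio

    CNR = (mu_nodule - mu_lungfield) / sigma_lungfield

is computed on the original image (CNR-) and on the enhanced image (CNR+),
where mu_nodule is the mean intensity over the nodule ROI and
mu_lungfield / sigma_lungfield are the mean and standard deviation over the
lung field. Delta_CNR = CNR+ - CNR- summarizes the per-nodule conspicuity
gain; its distribution is reported as the count/fraction improved, mean and
median, and a histogram.

Lung-field statistics are computed over the lung mask with all nodule ROIs
excluded, so the "noise" term is not contaminated by the lesions themselves;
the exclusion is recorded in the report.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .image import ImageGrid


@dataclass
class CnrRecord:
    """Per-nodule CNR before/after enhancement; delta = cnr_plus - cnr_minus."""

    case_id: int
    nodule_id: int
    cnr_minus: float
    cnr_plus: float
    delta: float


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ImageGrid) else np.asarray(img, dtype=np.float64)


def compute_cnr(img, nodule_mask: np.ndarray, lung_mask: np.ndarray) -> float:
    """CNR = (mean over nodule ROI - mean over lung field) / lung-field SD."""
    arr = _pixels(img)
    nodule_mask = np.asarray(nodule_mask, dtype=bool)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if arr.shape != nodule_mask.shape or arr.shape != lung_mask.shape:
        raise InputError("image and mask shapes differ")
    if not nodule_mask.any() or not lung_mask.any():
        raise InputError("empty nodule or lung mask")
    lung_vals = arr[lung_mask]
    sigma = float(lung_vals.std())
    if sigma == 0.0:
        raise InputError("lung field has zero intensity variance")
    return float((arr[nodule_mask].mean() - lung_vals.mean()) / sigma)


def delta_cnr(original, enhanced, nodule_mask: np.ndarray, lung_mask: np.ndarray,
              case_id: int = 0, nodule_id: int = 0) -> CnrRecord:
    """CNR change of one nodule between the original and enhanced image."""
    if _pixels(original).shape != _pixels(enhanced).shape:
        raise InputError("original and enhanced image sizes differ")
    cnr_minus = compute_cnr(original, nodule_mask, lung_mask)
    cnr_plus = compute_cnr(enhanced, nodule_mask, lung_mask)
    return CnrRecord(case_id, nodule_id, cnr_minus, cnr_plus,
                     cnr_plus - cnr_minus)


def lung_background_mask(lung_mask: np.ndarray,
                         nodule_masks: list[np.ndarray]) -> np.ndarray:
    """Lung field with every nodule ROI removed (the noise-statistics region)."""
    out = np.asarray(lung_mask, dtype=bool).copy()
    for mask in nodule_masks:
        out &= ~np.asarray(mask, dtype=bool)
    return out


def histogram_edges(records_delta: np.ndarray, bin_width: float = 0.1) -> np.ndarray:
    """Bin edges of width ``bin_width`` centered on zero, covering all deltas."""
    lo = np.floor(records_delta.min() / bin_width) - 1
    hi = np.ceil(records_delta.max() / bin_width) + 1
    return np.arange(lo, hi + 1) * bin_width


def summarize_evaluation(records: list[CnrRecord], bins: int | None = None,
                         bin_width: float = 0.1, out_dir: str | Path | None = None) -> dict:
    """Summarize per-nodule Delta_CNR records.

    Returns a dict with the count/fraction improved (delta > 0), mean and
    median delta, and histogram counts with their bin edges. When ``out_dir``
    is given, writes ``cnr_records.csv``, ``summary.json`` and
    ``delta_cnr_hist.png`` there.
    """
    if not records:
        raise InputError("no CNR records to summarize")
    deltas = np.array([r.delta for r in records])
    if bins is not None:
        edges = np.histogram_bin_edges(deltas, bins=bins)
    else:
        edges = histogram_edges(deltas, bin_width)
    counts, edges = np.histogram(deltas, bins=edges)
    summary = {
        "n_nodules": len(records),
        "n_improved": int((deltas > 0).sum()),
        "fraction_improved": float((deltas > 0).mean()),
        "mean_delta": float(deltas.mean()),
        "median_delta": float(np.median(deltas)),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
        "lung_statistics_exclude_nodule_rois": True,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "cnr_records.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["case_id", "nodule_id", "cnr_minus", "cnr_plus", "delta"]
            )
            writer.writeheader()
            for rec in records:
                writer.writerow(asdict(rec))
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        _plot_histogram(deltas, edges, out_dir / "delta_cnr_hist.png")
    return summary


def _plot_histogram(deltas: np.ndarray, edges: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(deltas, bins=edges, edgecolor="black")
    ax.axvline(0.0, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel(r"$\Delta$CNR")
    ax.set_ylabel("nodule count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
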