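"""Per-slice evaluation metrics and distribution summaries.

Areas are pixel counts scaled by the squared pixel spacing.  Errors are
signed: the myocardial error is relative (percent of the reference
myocardial area) while the scar error is expressed in percentage points
of the reference myocardial area, so that slices with little or no scar
remain comparable.  Dice uses the convention that two empty masks agree
perfectly (score 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AreaMeasure",
    "SliceErrors",
    "SummaryStats",
    "tissue_area",
    "myo_error",
    "scar_error",
    "dice",
    "summarize",
    "density_estimate",
    "slice_errors",
]


@dataclass(frozen=True)
class AreaMeasure:
    """Area of one tissue class on one slice."""

    tissue: str  # "MYO" or "SCAR"
    area_mm2: float
    dx_mm: float


@dataclass(frozen=True)
class SliceErrors:
    """Signed errors and Dice scores for a single slice."""

    delta_myo: float  # percent
    delta_scar: float  # percentage points of reference myocardial area
    dice_myo: float
    dice_scar: float


@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr: float
    q1: float
    q3: float
    n: int


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must be binary, got values {uniq[:10]}")
    return arr.astype(bool)


def tissue_area(mask: np.ndarray, dx_mm: float) -> float:
    """Area in mm^2 of a binary mask: dx^2 times the number of set pixels."""
    if dx_mm <= 0:
        raise ValueError("dx_mm must be positive")
    m = _as_binary(mask)
    return float(dx_mm * dx_mm * int(m.sum()))


def myo_error(pred_area_mm2: float, ref_area_mm2: float) -> float:
    """Signed relative myocardial area error in percent."""
    if ref_area_mm2 <= 0:
        raise ValueError("reference myocardial area must be positive")
    return 100.0 * (pred_area_mm2 - ref_area_mm2) / ref_area_mm2


def scar_error(
    pred_scar_mm2: float, ref_scar_mm2: float, ref_myo_mm2: float
) -> float:
    """Signed scar area error in percentage points of reference myocardium.

    Both the predicted and the reference scar areas are normalized by the
    *reference* myocardial area before differencing.
    """
    if ref_myo_mm2 <= 0:
        raise ValueError("reference myocardial area must be positive")
    return 100.0 * (pred_scar_mm2 - ref_scar_mm2) / ref_myo_mm2


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Sorensen-Dice coefficient; two empty masks score 1 by convention."""
    p = _as_binary(pred, "pred")
    r = _as_binary(ref, "ref")
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & r).sum()) / denom


def slice_errors(
    pred_myo: np.ndarray,
    pred_scar: np.ndarray,
    ref_myo: np.ndarray,
    ref_scar: np.ndarray,
    dx_mm: float,
) -> SliceErrors:
    """Bundle all four per-slice metrics against the reference masks."""
    a_ref_myo = tissue_area(ref_myo, dx_mm)
    a_ref_scar = tissue_area(ref_scar, dx_mm)
    a_pred_myo = tissue_area(pred_myo, dx_mm)
    a_pred_scar = tissue_area(pred_scar, dx_mm)
    return SliceErrors(
        delta_myo=myo_error(a_pred_myo, a_ref_myo),
        delta_scar=scar_error(a_pred_scar, a_ref_scar, a_ref_myo),
        dice_myo=dice(pred_myo, ref_myo),
        dice_scar=dice(pred_scar, ref_scar),
    )


def summarize(values) -> SummaryStats:
    """Median, quartiles and IQR using the linear-interpolation (type-7)
    quantile convention."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return SummaryStats(
        median=float(med), iqr=float(q3 - q1), q1=float(q1), q3=float(q3),
        n=int(arr.size),
    )


def density_estimate(
    values, bandwidth: float | None = None, grid_size: int = 512
):
    """Gaussian-kernel density estimate on a regular grid.

    Bandwidth defaults to Scott's rule (n^(-1/5) * sample SD).  The grid
    spans the data range padded by three bandwidths.  Returns
    ``(grid, density)``; the density integrates to ~1 (trapezoid rule).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values for a density estimate")
    sd = float(arr.std(ddof=1))
    if bandwidth is None:
        if sd == 0:
            warnings.warn("zero-variance input; density is a degenerate spike")
            bandwidth = 1e-3 * max(abs(arr[0]), 1.0)
        else:
            bandwidth = sd * arr.size ** (-1 / 5)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if sd == 0:
        warnings.warn("zero-variance input; density is a degenerate spike")
    lo = arr.min() - 3.0 * bandwidth
    hi = arr.max() + 3.0 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - arr[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (
        arr.size * bandwidth * np.sqrt(2.0 * np.pi)
    )
    return grid, dens
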