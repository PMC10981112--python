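"""Reference (REF) masks: remote statistics, SD5 thresholding, denoising.

The scar threshold is ``tau = mu_remote + n_sd * sigma_remote`` computed
from the magnitude image over the remote healthy ROI (sample SD,
ddof=1).  Pixels strictly above tau inside the myocardium are scar; ties
go to healthy.  The raw mask is then denoised: morphological opening
removes isolated pixels, and a dilation of the opened mask intersected
with the raw mask re-includes individual pixels adjacent to the
surviving scar clusters.  Reference masks are always built at the native
resolution and reused unchanged for every degraded test resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_opening

__all__ = [
    "RemoteStats",
    "ThresholdSpec",
    "ReferenceLabels",
    "remote_statistics",
    "sd_threshold",
    "threshold_scar",
    "denoise_mask",
    "build_reference",
    "rg_overlay",
    "DEFAULT_FOOTPRINT",
]

#: 3x3 square (8-connected) structuring element; smallest SE that removes
#: isolated pixels.  Configurable because the original choice is unknown.
DEFAULT_FOOTPRINT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RemoteStats:
    mu_remote: float
    sigma_remote: float
    n_pixels: int


@dataclass(frozen=True)
class ThresholdSpec:
    n_sd: float
    tau: float


@dataclass(frozen=True)
class ReferenceLabels:
    myo: np.ndarray  # bool; ground-truth stand-in for expert contours
    scar_raw: np.ndarray  # bool, before denoising
    scar: np.ndarray  # bool, denoised
    tau: float
    pixel_mm: float


def remote_statistics(magnitude: np.ndarray, remote_roi: np.ndarray) -> RemoteStats:
    """Mean and sample SD (ddof=1) of the magnitude over the remote ROI."""
    mag = np.asarray(magnitude, dtype=float)
    roi = np.asarray(remote_roi, dtype=bool)
    if mag.shape != roi.shape:
        raise ValueError("magnitude and ROI shapes differ")
    vals = mag[roi]
    if vals.size < 2:
        raise ValueError("remote ROI must contain at least two pixels")
    return RemoteStats(
        mu_remote=float(vals.mean()),
        sigma_remote=float(vals.std(ddof=1)),
        n_pixels=int(vals.size),
    )


def sd_threshold(stats: RemoteStats, n_sd: float = 5.0) -> ThresholdSpec:
    """tau = mu_remote + n_sd * sigma_remote (default n = 5, i.e. SD5)."""
    if n_sd < 0:
        raise ValueError("n_sd must be non-negative")
    return ThresholdSpec(n_sd=n_sd, tau=stats.mu_remote + n_sd * stats.sigma_remote)


def threshold_scar(
    magnitude: np.ndarray, myo: np.ndarray, tau: float
) -> np.ndarray:
    """Pixels strictly above tau and inside the myocardium."""
    mag = np.asarray(magnitude, dtype=float)
    myo = np.asarray(myo, dtype=bool)
    if mag.shape != myo.shape:
        raise ValueError("magnitude and myocardium mask shapes differ")
    return (mag > tau) & myo


def denoise_mask(
    scar_raw: np.ndarray, footprint: np.ndarray = DEFAULT_FOOTPRINT
) -> np.ndarray:
    """Opening followed by dilation-and-intersect with the raw mask.

    Opening removes structures that cannot contain the structuring
    element (isolated pixels and thin strands); dilating the opened mask
    and intersecting with the raw mask re-includes single raw pixels
    adjacent to the surviving clusters.  The result is a subset of the
    raw mask.
    """
    raw = np.asarray(scar_raw, dtype=bool)
    opened = binary_opening(raw, structure=footprint)
    recovered = binary_dilation(opened, structure=footprint) & raw
    return recovered


def build_reference(slc, n_sd: float = 5.0, footprint: np.ndarray = DEFAULT_FOOTPRINT) -> ReferenceLabels:
    """Compose the full reference pipeline on a native-resolution slice."""
    mag = slc.magnitude
    stats = remote_statistics(mag, slc.remote_roi)
    spec = sd_threshold(stats, n_sd)
    raw = threshold_scar(mag, slc.gt_myo, spec.tau)
    scar = denoise_mask(raw, footprint)
    return ReferenceLabels(
        myo=slc.gt_myo.copy(),
        scar_raw=raw,
        scar=scar,
        tau=spec.tau,
        pixel_mm=slc.pixel_mm,
    )


def rg_overlay(labels: ReferenceLabels) -> np.ndarray:
    """Red-green class image: healthy myocardium green, scar red."""
    h, w = labels.myo.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    healthy = labels.myo & ~labels.scar
    rgb[healthy, 1] = 255
    rgb[labels.scar, 0] = 255
    return rgb
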