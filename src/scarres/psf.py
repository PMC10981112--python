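"""Retrospective in-plane resolution degradation via k-space filtering.

The complex image is Fourier transformed, multiplied with an isotropic
2D Gaussian low-pass of unit DC gain, and transformed back.  Field of
view and matrix size never change; only the effective resolution does.
Effective resolution is defined as the full-width-at-half-maximum
(FWHM) of the point-spread function obtained as the inverse Fourier
transform of the (sampled, truncated) filter.

Conventions
-----------
* k-space is centered: DC sits at index ``matrix // 2`` on each axis.
* The filter is real, isotropic and has value 1 at k = 0, so constant
  images pass through unchanged.
* A target equal to the native resolution returns an identity design
  (no filtering at all): the native image *is* the highest resolution,
  and a Gaussian on the truncated grid cannot produce a PSF narrower
  than the sampling window's sinc mainlobe.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ResolutionSpec",
    "FilterDesign",
    "calibrate_filter",
    "measure_psf_fwhm",
    "apply_lowpass",
    "degrade_slice",
    "PAPER_RESOLUTIONS_MM",
]

#: the seven test resolutions used throughout the study, in mm
PAPER_RESOLUTIONS_MM = (0.7, 0.9, 1.1, 1.2, 1.3, 1.5, 1.7)


@dataclass(frozen=True)
class ResolutionSpec:
    """Grid geometry of the acquisition: square matrix at fixed FOV."""

    matrix: int = 128
    fov_mm: float = 128 * 0.7
    native_dx_mm: float = 0.7

    def __post_init__(self):
        if self.matrix <= 0:
            raise ValueError("matrix must be positive")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix

    def k_axes(self):
        """Centered spatial-frequency axes in cycles/mm."""
        n = self.matrix
        k = (np.arange(n) - n // 2) / self.fov_mm
        return k, k


@dataclass(frozen=True)
class FilterDesign:
    """A calibrated Gaussian k-space low-pass."""

    sigma_k: float  # Gaussian SD in k-space, cycles/mm (inf => identity)
    target_dx_mm: float
    measured_fwhm_mm: float
    is_identity: bool
    matrix: int
    fov_mm: float

    def kspace_filter(self) -> np.ndarray:
        """The filter sampled on the centered k-space grid."""
        spec = ResolutionSpec(self.matrix, self.fov_mm)
        kx, ky = spec.k_axes()
        if self.is_identity or not np.isfinite(self.sigma_k):
            return np.ones((self.matrix, self.matrix))
        k2 = kx[None, :] ** 2 + ky[:, None] ** 2
        return np.exp(-0.5 * k2 / (self.sigma_k**2))

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma_k": self.sigma_k if np.isfinite(self.sigma_k) else None,
                "target_dx_mm": self.target_dx_mm,
                "measured_fwhm_mm": self.measured_fwhm_mm,
                "is_identity": self.is_identity,
                "matrix": self.matrix,
                "fov_mm": self.fov_mm,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FilterDesign":
        d = json.loads(s)
        if d["sigma_k"] is None:
            d["sigma_k"] = math.inf
        return cls(**d)


def _profile_fwhm(profile: np.ndarray, step: float) -> float:
    """FWHM of a peaked 1D profile via linear interpolation of the
    half-maximum crossings around the global maximum."""
    p = np.abs(profile)
    i_max = int(np.argmax(p))
    half = p[i_max] / 2.0

    def cross(direction: int) -> float:
        i = i_max
        while 0 < i < p.size - 1:
            j = i + direction
            if p[j] < half:
                # linear interpolation between i (>= half) and j (< half)
                frac = (p[i] - half) / (p[i] - p[j])
                return abs(i - i_max) + frac
            i = j
        raise ValueError("half-maximum not bracketed within the padded FOV")

    return (cross(-1) + cross(+1)) * step


def measure_psf_fwhm(
    kfilter: np.ndarray, spec: ResolutionSpec, pad_factor: int = 8
) -> float:
    """FWHM (mm) of the PSF of a centered k-space filter.

    The PSF is the inverse FFT of the filter zero-padded by
    ``pad_factor`` for sub-pixel resolution of the half-maximum
    crossings, measured on the central row through the peak.
    """
    kfilter = np.asarray(kfilter, dtype=float)
    if kfilter.shape != (spec.matrix, spec.matrix):
        raise ValueError("filter shape does not match the spec grid")
    n = spec.matrix
    npad = n * pad_factor
    padded = np.zeros((npad, npad))
    lo = npad // 2 - n // 2
    padded[lo : lo + n, lo : lo + n] = kfilter
    psf = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(padded)))
    center = npad // 2
    profile = np.abs(psf[center, :])
    # each padded pixel spans fov_mm / (matrix * pad_factor)
    step_mm = spec.pixel_mm / pad_factor
    return _profile_fwhm(profile, step_mm)


def _gaussian_filter(sigma_k: float, spec: ResolutionSpec) -> np.ndarray:
    kx, ky = spec.k_axes()
    k2 = kx[None, :] ** 2 + ky[:, None] ** 2
    return np.exp(-0.5 * k2 / (sigma_k**2))


def calibrate_filter(
    target_dx_mm: float,
    spec: ResolutionSpec | None = None,
    tol: float = 0.01,
    max_iter: int = 200,
) -> FilterDesign:
    """Find the Gaussian k-space width whose PSF FWHM equals the target.

    Bisection on ``sigma_k`` (FWHM is strictly decreasing in sigma_k),
    seeded by the continuous closed form
    ``sigma_k = sqrt(2 ln 2) / (pi * FWHM)``.  The native resolution maps
    to the identity design and bypasses filtering entirely.
    """
    spec = spec or ResolutionSpec()
    if target_dx_mm < spec.native_dx_mm - 1e-12:
        raise ValueError(
            f"cannot sharpen: target {target_dx_mm} mm is below the native "
            f"resolution {spec.native_dx_mm} mm"
        )
    if abs(target_dx_mm - spec.native_dx_mm) <= 1e-12:
        return FilterDesign(
            sigma_k=math.inf,
            target_dx_mm=target_dx_mm,
            measured_fwhm_mm=target_dx_mm,
            is_identity=True,
            matrix=spec.matrix,
            fov_mm=spec.fov_mm,
        )

    def fwhm_of(sig: float) -> float:
        return measure_psf_fwhm(_gaussian_filter(sig, spec), spec)

    sig0 = math.sqrt(2.0 * math.log(2.0)) / (math.pi * target_dx_mm)
    lo, hi = sig0, sig0  # lo: fwhm too large; hi: fwhm too small
    while fwhm_of(lo) < target_dx_mm:
        lo /= 2.0
        if lo < 1e-9:
            raise RuntimeError("calibration failed to bracket from below")
    while fwhm_of(hi) > target_dx_mm:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError(
                f"calibration cannot reach {target_dx_mm} mm: target is "
                "narrower than the truncation-window PSF"
            )
    sig, fw = lo, fwhm_of(lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fw = fwhm_of(mid)
        if abs(fw - target_dx_mm) / target_dx_mm <= tol * 0.1:
            sig = mid
            break
        if fw > target_dx_mm:
            lo = mid
        else:
            hi = mid
        sig = mid
    if abs(fw - target_dx_mm) / target_dx_mm > tol:
        raise RuntimeError(
            f"filter calibration did not converge: target {target_dx_mm} mm, "
            f"achieved {fw:.4f} mm after {max_iter} iterations"
        )
    return FilterDesign(
        sigma_k=sig,
        target_dx_mm=target_dx_mm,
        measured_fwhm_mm=fw,
        is_identity=False,
        matrix=spec.matrix,
        fov_mm=spec.fov_mm,
    )


def apply_lowpass(image: np.ndarray, design: FilterDesign) -> np.ndarray:
    """Filter a complex image in k-space.  Shape, FOV and matrix are
    preserved; the identity design returns the input unchanged."""
    img = np.asarray(image)
    if img.shape != (design.matrix, design.matrix):
        raise ValueError(
            f"image shape {img.shape} does not match the design grid "
            f"({design.matrix}x{design.matrix})"
        )
    if not np.all(np.isfinite(img.real)) or not np.all(np.isfinite(img.imag)):
        raise ValueError("image contains non-finite values")
    if design.is_identity:
        return img.copy()
    kspace = np.fft.fftshift(np.fft.fft2(img))
    kspace *= design.kspace_filter()
    return np.fft.ifft2(np.fft.ifftshift(kspace))


def degrade_slice(slc, target_dx_mm: float, design: FilterDesign | None = None):
    """Return a copy of a phantom slice with its image low-pass filtered
    to the target effective resolution.

    Masks and remote ROI are untouched: reference masks live at the
    native resolution and are reused across all test resolutions.  A
    pre-calibrated design may be passed to avoid repeated calibration.
    """
    spec = ResolutionSpec(
        matrix=slc.image.shape[0],
        fov_mm=slc.image.shape[0] * slc.pixel_mm,
        native_dx_mm=slc.pixel_mm,
    )
    if design is None:
        design = calibrate_filter(target_dx_mm, spec)
    elif design.matrix != slc.image.shape[0]:
        raise ValueError("design grid does not match slice")
    filtered = apply_lowpass(slc.image, design)
    return replace(slc, image=filtered, effective_dx_mm=target_dx_mm)
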