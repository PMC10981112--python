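"""Synthetic short-axis LGE-like slice cohorts with known ground truth.

Each slice is a perturbed-annulus myocardium around a bright blood pool,
with zero or more hyperenhanced scar sectors and a remote ROI placed in
healthy myocardium opposite the scar territory.  Images are
complex-valued: a piecewise-constant magnitude phantom modulated by a
smooth low-order polynomial phase, plus independent Gaussian noise on
the real and imaginary channels (so the magnitude is Rician).

Geometry is volume-coherent: ring center, radii, boundary perturbation
and scar territory are sampled once per volume; slices add small
jitters.  Masks are rasterized at pixel centers (0-based indices,
pixel-centered coordinates); areas follow the pixel-count times
squared-spacing convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


import numpy as np
from scipy.special import ndtri

__all__ = [
    "PhantomConfig",
    "VolumeParams",
    "PhantomSlice",
    "PhantomCohort",
    "CohortStats",
    "sample_volume_params",
    "generate_slice",
    "generate_cohort",
    "cohort_summary",
]

_MAX_SECTOR_FRAC = 0.55  # of the full circle, per scar territory
# smallest scar fraction worth drawing: thin arcs below ~45 pixels are
# (partially) removed by the reference morphological opening
_MIN_SCAR_FRAC = 0.02


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generation parameters.

    Intensity levels are arbitrary units; defaults are documented
    choices, not measurements (the source cohort reports no contrast
    ratios or SNR).
    """

    n_volumes: int = 36
    slices_per_volume: tuple[int, int] = (15, 25)
    matrix: int = 128
    pixel_mm: float = 0.7
    myo_area_mean_mm2: float = 1136.0
    myo_area_sd_mm2: float = 349.0
    scar_frac_mean: float = 0.05
    scar_frac_sd: float = 0.09
    p_scar_free: float = 0.30
    intensity_background: float = 0.05
    intensity_blood: float = 1.0
    intensity_remote: float = 0.25
    intensity_scar: float = 0.90
    noise_sd: float = 0.015
    edge_supersample: int = 1  # >1: partial-volume (antialiased) edges
    wall_ratio_range: tuple[float, float] = (0.55, 0.72)  # r_in / r_out
    center_jitter_mm: float = 4.0
    # heterogeneous (patchy) scar: SD amplitude of a smooth multiplicative
    # intensity field inside the scar, in units of the scar-remote contrast,
    # and its correlation length.  0 keeps the scar homogeneous.
    scar_texture_sd: float = 0.0
    scar_texture_corr_px: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.matrix <= 0:
            raise ValueError("matrix must be positive")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if not (0.0 <= self.p_scar_free <= 1.0):
            raise ValueError("p_scar_free must lie in [0, 1]")
        if self.intensity_scar <= self.intensity_remote:
            raise ValueError("scar intensity must exceed remote intensity")
        if self.n_volumes < 1:
            raise ValueError("need at least one volume")
        lo, hi = self.slices_per_volume
        if lo < 1 or hi < lo:
            raise ValueError("invalid slices_per_volume range")
        if self.edge_supersample < 1:
            raise ValueError("edge_supersample must be >= 1")

    @property
    def fov_mm(self) -> float:
        return self.matrix * self.pixel_mm


@dataclass(frozen=True)
class VolumeParams:
    """Per-volume sampled geometry shared by all slices of a volume."""

    volume_id: int
    center_mm: tuple[float, float]
    myo_area_mm2: float
    thickness_ratio: float  # r_in / r_out
    perturb: tuple[tuple[int, float, float], ...]  # (order, amp, phase)
    scar_angle_rad: float
    scar_frac_mean: float  # mean scar fraction for scar-bearing slices
    scar_depth: float  # transmural depth fraction from endocardium
    n_sectors: int
    phase_coeffs: tuple[float, ...]  # smooth image-phase polynomial


@dataclass(frozen=True)
class PhantomSlice:
    image: np.ndarray  # complex, matrix x matrix
    gt_myo: np.ndarray  # bool
    gt_scar: np.ndarray  # bool
    remote_roi: np.ndarray  # bool
    pixel_mm: float
    volume_id: int
    slice_id: int
    effective_dx_mm: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.effective_dx_mm is None:
            object.__setattr__(self, "effective_dx_mm", self.pixel_mm)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.image)


@dataclass(frozen=True)
class PhantomCohort:
    slices: tuple[PhantomSlice, ...]
    config: PhantomConfig

    def volume_ids(self) -> list[int]:
        return sorted({s.volume_id for s in self.slices})

    def by_volume(self, volume_id: int) -> list[PhantomSlice]:
        return [s for s in self.slices if s.volume_id == volume_id]


@dataclass(frozen=True)
class CohortStats:
    myo_area_mm2: np.ndarray  # per slice
    scar_frac: np.ndarray  # per slice, fraction of myocardial area
    scar_free: np.ndarray  # per slice, bool
    myo_area_mean: float
    myo_area_sd: float
    scar_frac_mean: float
    scar_frac_sd: float
    scar_free_prop: float


def sample_volume_params(
    config: PhantomConfig,
    volume_id: int,
    rng: np.random.Generator,
    u_area: float | None = None,
    u_frac: float | None = None,
) -> VolumeParams:
    """Draw the per-volume geometry from the cohort-level targets.

    ``u_area`` / ``u_frac`` are optional uniform quantiles for the
    myocardial area and scar-fraction draws; `generate_cohort` passes
    stratified quantiles (one stratum per volume) so that small cohorts
    recover the configured moments tightly while the marginal
    distributions stay unchanged.
    """
    if u_area is None:
        u_area = float(rng.uniform())
    u_area = float(np.clip(u_area, 1e-4, 1 - 1e-4))
    area = float(
        np.clip(
            config.myo_area_mean_mm2 + config.myo_area_sd_mm2 * ndtri(u_area),
            0.3 * config.myo_area_mean_mm2,
            2.0 * config.myo_area_mean_mm2,
        )
    )
    thickness_ratio = float(rng.uniform(*config.wall_ratio_range))
    j = config.center_jitter_mm
    center = (float(rng.uniform(-j, j)), float(rng.uniform(-j, j)))
    perturb = tuple(
        (order, float(rng.uniform(0.0, 0.04)), float(rng.uniform(0, 2 * np.pi)))
        for order in (2, 3)
    )
    # scar territory: one angular location per volume (single-territory MI)
    scar_angle = float(rng.uniform(0, 2 * np.pi))
    p_free = config.p_scar_free
    cond_mean = config.scar_frac_mean / max(1.0 - p_free, 1e-9)
    # lognormal whose mean matches the conditional (scar-bearing) mean and
    # whose spread reproduces the heavy right tail of the cohort
    cond_sd = max(config.scar_frac_sd, 1e-6)
    sigma2 = math.log(1.0 + (cond_sd / max(cond_mean, 1e-9)) ** 2)
    mu = math.log(max(cond_mean, 1e-9)) - 0.5 * sigma2
    if u_frac is None:
        u_frac = float(rng.uniform())
    u_frac = float(np.clip(u_frac, 1e-4, 1 - 1e-4))
    frac_mean = float(
        np.clip(
            math.exp(mu + math.sqrt(sigma2) * ndtri(u_frac)),
            _MIN_SCAR_FRAC,
            _MAX_SECTOR_FRAC,
        )
    )
    scar_depth = float(rng.uniform(0.65, 1.0))
    n_sectors = int(1 + (rng.random() < 0.25))
    phase_coeffs = tuple(rng.uniform(-np.pi, np.pi, size=6).tolist())
    return VolumeParams(
        volume_id=volume_id,
        center_mm=center,
        myo_area_mm2=area,
        thickness_ratio=thickness_ratio,
        perturb=perturb,
        scar_angle_rad=scar_angle,
        scar_frac_mean=frac_mean,
        scar_depth=scar_depth,
        n_sectors=n_sectors,
        phase_coeffs=phase_coeffs,
    )


def _angular_distance(theta: np.ndarray, center: float) -> np.ndarray:
    d = np.mod(theta - center + np.pi, 2 * np.pi) - np.pi
    return np.abs(d)


def _sector_width(frac: float, t: float, depth: float) -> tuple[float, float]:
    """Angular width (rad) and depth achieving the target scar fraction.

    ``t`` is r_in/r_out.  If the sampled depth would demand an
    implausibly wide sector, the scar is made transmural instead.
    """
    r_in2, r_out2 = t * t, 1.0
    r_d = t + depth * (1.0 - t)
    band = (r_d * r_d - r_in2) / (r_out2 - r_in2)
    width = 2 * np.pi * frac / band
    if width > 2 * np.pi * _MAX_SECTOR_FRAC:
        depth = 1.0
        width = min(2 * np.pi * frac, 2 * np.pi * _MAX_SECTOR_FRAC)
    return width, depth


def generate_slice(
    config: PhantomConfig,
    volume_params: VolumeParams,
    rng: np.random.Generator,
    slice_id: int = 0,
    scar_free: bool | None = None,
) -> PhantomSlice:
    """Rasterize one slice of a volume.

    ``scar_free`` forces the slice to carry no scar (True) or to carry
    the volume's scar territory (False); None draws a Bernoulli with
    probability ``config.p_scar_free``.  Raises if the ring does not fit
    the field of view or the remote ROI would be empty (scar spanning
    essentially the full ring).
    """
    n = config.matrix
    vp = volume_params

    # per-slice jitters around the volume geometry
    area = vp.myo_area_mm2 * float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.15))
    cx = vp.center_mm[0] + float(rng.uniform(-1.0, 1.0))
    cy = vp.center_mm[1] + float(rng.uniform(-1.0, 1.0))
    t = vp.thickness_ratio
    r_out = math.sqrt(area / (np.pi * (1.0 - t * t)))
    r_in = t * r_out

    amp_sum = sum(a for _, a, _ in vp.perturb)
    if r_out * (1 + amp_sum) + max(abs(cx), abs(cy)) > config.fov_mm / 2 - 2 * config.pixel_mm:
        raise ValueError("ring geometry exceeds the field of view")

    if scar_free is None:
        scar_free = bool(rng.random() < config.p_scar_free)
    if scar_free:
        scar_frac = 0.0
    else:
        # per-slice lognormal jitter around the volume mean, centered so
        # the multiplier has unit expectation
        jitter_sd = 0.25
        scar_frac = float(
            np.clip(
                vp.scar_frac_mean
                * rng.lognormal(-0.5 * jitter_sd**2, jitter_sd),
                _MIN_SCAR_FRAC,
                _MAX_SECTOR_FRAC,
            )
        )
    scar_angle = vp.scar_angle_rad + float(rng.uniform(-0.1, 0.1))
    if scar_frac > 0.0:
        sector_width, sector_depth = _sector_width(scar_frac, t, vp.scar_depth)
    else:
        sector_width = sector_depth = 0.0

    def tissue_maps(coords_1d):
        """Blood / myocardium / scar membership plus polar maps on an
        arbitrary square grid of mm coordinates."""
        x = coords_1d[None, :]
        y = coords_1d[:, None]
        rho = np.hypot(x - cx, y - cy)
        theta = np.arctan2(y - cy, x - cx)
        pert = np.zeros_like(theta)
        for order, amp, phase in vp.perturb:
            pert += amp * np.cos(order * theta + phase)
        r_in_map = r_in * (1.0 + pert)
        r_out_map = r_out * (1.0 + pert)
        myo = (rho >= r_in_map) & (rho <= r_out_map)
        blood = rho < r_in_map
        scar = np.zeros_like(myo)
        if scar_frac > 0.0:
            in_depth = rho <= r_in_map + sector_depth * (r_out_map - r_in_map)
            if vp.n_sectors == 2 and sector_width > 0.2 * np.pi:
                gap = np.pi / 12
                half = sector_width / 2.0
                for c in (
                    scar_angle - (half + gap) / 2,
                    scar_angle + (half + gap) / 2,
                ):
                    scar |= (
                        myo & in_depth & (_angular_distance(theta, c) <= half / 2)
                    )
            else:
                scar = myo & in_depth & (
                    _angular_distance(theta, scar_angle) <= sector_width / 2
                )
        return blood, myo, scar, rho, theta, r_in_map, r_out_map

    coords = (np.arange(n) - (n - 1) / 2.0) * config.pixel_mm
    blood, gt_myo, gt_scar, rho, theta, r_in_map, r_out_map = tissue_maps(coords)

    # remote ROI: interior sector opposite the scar territory, one pixel
    # away from the endo/epi borders so its pixels are pure remote tissue
    margin = config.pixel_mm
    interior = (rho >= r_in_map + margin) & (rho <= r_out_map - margin)
    remote = (
        gt_myo
        & interior
        & (_angular_distance(theta, scar_angle + np.pi) <= np.pi / 6)
        & ~gt_scar
    )
    if remote.sum() < 2:
        raise ValueError(
            "remote ROI is empty: scar spans the ring or the wall is too thin"
        )

    def paint(blood_m, myo_m, scar_m):
        mag = np.full(blood_m.shape, config.intensity_background)
        mag[blood_m] = config.intensity_blood
        mag[myo_m] = config.intensity_remote
        mag[scar_m] = config.intensity_scar
        return mag

    s_factor = config.edge_supersample
    scar_coverage = gt_scar.astype(float)
    if s_factor == 1:
        magnitude = paint(blood, gt_myo, gt_scar)
    else:
        # partial-volume edges: paint on a supersampled grid and
        # box-average back; masks stay defined at pixel centers
        nf = n * s_factor
        coords_f = (
            ((np.arange(nf) + 0.5) / s_factor - 0.5) - (n - 1) / 2.0
        ) * config.pixel_mm
        blood_f, myo_f, scar_f, *_ = tissue_maps(coords_f)
        mag_f = paint(blood_f, myo_f, scar_f)
        magnitude = mag_f.reshape(n, s_factor, n, s_factor).mean(axis=(1, 3))
        scar_coverage = (
            scar_f.astype(float).reshape(n, s_factor, n, s_factor).mean(axis=(1, 3))
        )

    if scar_frac > 0.0 and config.scar_texture_sd > 0.0:
        # smooth multiplicative heterogeneity inside the scar: dips can
        # fall below the SD5 threshold, making the reference mask patchy
        from scipy.ndimage import gaussian_filter

        g = gaussian_filter(
            rng.standard_normal((n, n)), config.scar_texture_corr_px
        )
        g /= max(g.std(), 1e-9)
        contrast = config.intensity_scar - config.intensity_remote
        magnitude = magnitude + scar_coverage * (
            contrast * config.scar_texture_sd * g
        )
        magnitude = np.clip(magnitude, 0.0, None)

    c0, c1, c2, c3, c4, c5 = vp.phase_coeffs
    u = coords[None, :] / config.fov_mm
    v = coords[:, None] / config.fov_mm
    phase = c0 + c1 * u + c2 * v + c3 * u * v + c4 * u * u + c5 * v * v
    image = magnitude * np.exp(1j * phase)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, (2, n, n))
        image = image + noise[0] + 1j * noise[1]

    return PhantomSlice(
        image=image,
        gt_myo=gt_myo,
        gt_scar=gt_scar,
        remote_roi=remote,
        pixel_mm=config.pixel_mm,
        volume_id=vp.volume_id,
        slice_id=slice_id,
    )


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate the full cohort; all randomness derives from config.seed.

    Volume-level area and scar-fraction quantiles are stratified across
    volumes, and per-volume scar-free slice counts use a floor-plus-
    uniform rounding of the expected count, so the cohort moments track
    the configured targets even at 36 volumes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_volumes
    u_area = (rng.permutation(n) + rng.uniform(0.0, 1.0, n)) / n
    u_frac = (rng.permutation(n) + rng.uniform(0.0, 1.0, n)) / n
    slices: list[PhantomSlice] = []
    lo, hi = config.slices_per_volume
    for vid in range(n):
        vp = sample_volume_params(
            config, vid, rng, u_area=float(u_area[vid]), u_frac=float(u_frac[vid])
        )
        n_slices = int(rng.integers(lo, hi + 1))
        n_free = int(
            math.floor(n_slices * config.p_scar_free + rng.uniform())
        )
        free_ids = set(rng.choice(n_slices, size=min(n_free, n_slices), replace=False).tolist())
        for sid in range(n_slices):
            slices.append(
                generate_slice(
                    config, vp, rng, slice_id=sid, scar_free=sid in free_ids
                )
            )
    return PhantomCohort(slices=tuple(slices), config=config)


def cohort_summary(cohort: PhantomCohort) -> CohortStats:
    """Per-slice myocardial areas, scar fractions and scar-free flags,
    plus their cohort-level moments (ground-truth masks)."""
    if not cohort.slices:
        raise ValueError("empty cohort")
    px2 = cohort.config.pixel_mm**2
    myo = np.array([s.gt_myo.sum() * px2 for s in cohort.slices])
    scar_px = np.array([int(s.gt_scar.sum()) for s in cohort.slices])
    myo_px = np.array([int(s.gt_myo.sum()) for s in cohort.slices])
    frac = np.where(myo_px > 0, scar_px / np.maximum(myo_px, 1), 0.0)
    free = scar_px == 0
    return CohortStats(
        myo_area_mm2=myo,
        scar_frac=frac,
        scar_free=free,
        myo_area_mean=float(myo.mean()),
        myo_area_sd=float(myo.std(ddof=1)) if myo.size > 1 else 0.0,
        scar_frac_mean=float(frac.mean()),
        scar_frac_sd=float(frac.std(ddof=1)) if frac.size > 1 else 0.0,
        scar_free_prop=float(free.mean()),
    )
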