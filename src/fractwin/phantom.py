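"""Synthetic CT phantoms and gait/insole force curves.

Stands in for patient data that cannot ship with the package: a simplified
plated tibia (cylindrical shaft with cortical shell and trabecular core, a
transverse fracture gap, a lateral plate with locking screws) scanned
together with a six-rod bone-density calibration phantom, plus two-peak
stance-phase knee-force curves at the three weight-bearing levels the
pipeline compares (20 kg partial load, 50% body weight, full weight-bearing).

Everything is deterministic given the spec's seed: the same spec produces
byte-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .gait import GaitForceCurve, GRFCurve, WeightBearingLevel
from .volume import (
    BACKGROUND,
    CORTICAL,
    GAP,
    IMPLANT,
    TRABECULAR,
    VoxelVolume,
    rod_label,
)

__all__ = [
    "PhantomSpec",
    "SyntheticCurveSpec",
    "InsoleCurveSpec",
    "generate_phantom_volume",
    "generate_gait_curve",
    "generate_insole_curve",
    "rod_masks",
]

# Default level-specific axial (Fz) peak magnitudes in %BW.  The 20-kg level
# peaks near one body weight — partial loads of 20 kg are known to drive knee
# contact forces up to ~100 %BW — and the full-weight-bearing level near the
# 2.4-2.6 BW knee contact forces reported for free gait.
_LEVEL_AXIAL_PEAKS = {
    WeightBearingLevel.PWB_20KG: (100.0, 90.0),
    WeightBearingLevel.PWB_50PCT: (180.0, 160.0),
    WeightBearingLevel.FULL: (260.0, 240.0),
}


@dataclass
class PhantomSpec:
    """Geometry, tissue HU statistics and calibration truth for the synthetic scan.

    All lengths in mm, HU dimensionless, rod densities in mg hydroxyapatite/cm³.
    ``calib_slope``/``calib_intercept`` define the *true* density map
    ``rho = slope * HU + intercept`` used to paint the rods; the calibration
    stage must recover it.
    """

    shape: tuple[int, int, int] = (32, 32, 80)
    spacing: float = 1.875  # isotropic, mm
    outer_radius: float = 12.0
    inner_radius: float = 7.0
    cortical_hu_mean: float = 1200.0
    cortical_hu_sd: float = 60.0
    trabecular_hu_mean: float = 300.0
    trabecular_hu_sd: float = 40.0
    gap_thickness: float = 3.0
    gap_hu_mean: float = 50.0
    gap_hu_sd: float = 10.0
    plate_thickness: float = 4.0
    plate_width: float = 12.0
    plate_length: float = 60.0
    screw_radius: float = 2.0
    screw_z_offsets: tuple[float, ...] = (-24.0, -10.0, 10.0, 24.0)
    metal_hu: float = 3000.0
    background_hu: float = 0.0
    rod_densities: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)
    rod_radius: float = 3.0
    calib_slope: float = 0.8  # mg/cm³ per HU
    calib_intercept: float = -2.0  # mg/cm³
    noise_sd: float = 10.0
    seed: int = 0
    # Optional overrides of the automatic layout (mm, world coordinates).
    bone_center: tuple[float, float] | None = None
    rod_row_y: float | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"volume shape must be three positive ints, got {self.shape}")
        self.shape = tuple(int(n) for n in self.shape)
        for name in (
            "spacing",
            "outer_radius",
            "inner_radius",
            "gap_thickness",
            "plate_thickness",
            "plate_width",
            "plate_length",
            "screw_radius",
            "rod_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.inner_radius >= self.outer_radius:
            raise ValueError("inner_radius must be smaller than outer_radius")
        if self.gap_thickness >= self.shaft_length:
            raise ValueError("gap thickness must be smaller than the shaft length")
        rho = np.asarray(self.rod_densities, dtype=float)
        if rho.size < 2 or np.any(np.diff(rho) <= 0):
            raise ValueError("rod densities must be a strictly increasing list of >= 2 values")
        if self.calib_slope <= 0:
            raise ValueError("true calibration slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    # Derived layout ----------------------------------------------------

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths (mm)."""
        return np.asarray(self.shape, dtype=float) * self.spacing

    @property
    def shaft_length(self) -> float:
        return float(self.shape[2] * self.spacing)

    @property
    def center_xy(self) -> tuple[float, float]:
        if self.bone_center is not None:
            return self.bone_center
        lx, ly, _ = self.extent
        return (0.45 * lx, 0.60 * ly)

    @property
    def gap_center_z(self) -> float:
        return 0.5 * self.shaft_length

    def plate_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned (lo, hi) corners of the plate in mm."""
        cx, cy = self.center_xy
        zc = self.gap_center_z
        lo = np.array([cx + self.outer_radius, cy - self.plate_width / 2, zc - self.plate_length / 2])
        hi = np.array([cx + self.outer_radius + self.plate_thickness, cy + self.plate_width / 2, zc + self.plate_length / 2])
        return lo, hi

    def screw_segments(self) -> list[tuple[float, float, float, float]]:
        """Screws as x-axis cylinders: (x_lo, x_hi, y_center, z_center)."""
        cx, cy = self.center_xy
        zc = self.gap_center_z
        x_hi = cx + self.outer_radius + self.plate_thickness
        return [(cx - self.outer_radius, x_hi, cy, zc + dz) for dz in self.screw_z_offsets]

    def rod_layout(self) -> dict:
        """Rod cylinders (axis along z): centres, radius and z-span in mm."""
        lx, ly, lz = self.extent
        y = self.rod_row_y if self.rod_row_y is not None else 0.13 * ly
        n = len(self.rod_densities)
        xs = np.linspace(0.10 * lx, 0.85 * lx, n)
        return {
            "centers_xy": [(float(x), float(y)) for x in xs],
            "radius": self.rod_radius,
            "z_span": (0.2 * lz, 0.8 * lz),
        }

    def rod_hu(self) -> np.ndarray:
        """Noise-free HU each rod is painted with (inverse of the true map)."""
        rho = np.asarray(self.rod_densities, dtype=float)
        return (rho - self.calib_intercept) / self.calib_slope


def generate_phantom_volume(spec: PhantomSpec) -> tuple[VoxelVolume, np.ndarray]:
    """Paint the synthetic scan and its ground-truth label map.

    Returns
    -------
    volume:
        HU volume with the phantom metadata (true calibration map, rod
        geometry, seed) in ``volume.meta``.
    labels:
        int array, same shape, with ``volume`` label constants; rod ``i`` is
        ``rod_label(i)``.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    h = spec.spacing
    # Voxel-centre coordinate grids (mm).
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    cx, cy = spec.center_xy
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    bone = r2 <= spec.outer_radius**2
    trab = r2 <= spec.inner_radius**2
    cort = bone & ~trab

    gap_slab = np.abs(Z - spec.gap_center_z) <= spec.gap_thickness / 2
    gap = bone & gap_slab

    lo, hi = spec.plate_box()
    implant = (
        (X >= lo[0]) & (X < hi[0]) & (Y >= lo[1]) & (Y < hi[1]) & (Z >= lo[2]) & (Z < hi[2])
    )
    for x_lo, x_hi, yc, zc in spec.screw_segments():
        implant |= ((X >= x_lo) & (X < x_hi)) & ((Y - yc) ** 2 + (Z - zc) ** 2 <= spec.screw_radius**2)

    labels = np.full(spec.shape, BACKGROUND, dtype=np.int16)
    labels[cort] = CORTICAL
    labels[trab] = TRABECULAR
    labels[gap] = GAP

    layout = spec.rod_layout()
    z_lo, z_hi = layout["z_span"]
    rod_hu = spec.rod_hu()
    rod_masks_ = []
    for i, (rx, ry) in enumerate(layout["centers_xy"]):
        m = ((X - rx) ** 2 + (Y - ry) ** 2 <= layout["radius"] ** 2) & (Z >= z_lo) & (Z < z_hi)
        m &= labels == BACKGROUND  # rods never overwrite anatomy
        rod_masks_.append(m)
        labels[m] = rod_label(i)
    labels[implant] = IMPLANT  # implant has priority over bone/gap

    hu = np.full(spec.shape, float(spec.background_hu))
    hu[labels == CORTICAL] = spec.cortical_hu_mean + spec.cortical_hu_sd * rng.standard_normal(
        int(np.sum(labels == CORTICAL))
    )
    hu[labels == TRABECULAR] = spec.trabecular_hu_mean + spec.trabecular_hu_sd * rng.standard_normal(
        int(np.sum(labels == TRABECULAR))
    )
    hu[labels == GAP] = spec.gap_hu_mean + spec.gap_hu_sd * rng.standard_normal(
        int(np.sum(labels == GAP))
    )
    for i, m in enumerate(rod_masks_):
        hu[m] = rod_hu[i]
    hu[labels == IMPLANT] = spec.metal_hu
    if spec.noise_sd > 0:
        hu += spec.noise_sd * rng.standard_normal(spec.shape)

    meta = {
        "seed": spec.seed,
        "true_calibration": {"slope": spec.calib_slope, "intercept": spec.calib_intercept},
        "rod_densities_mg_cm3": list(spec.rod_densities),
        "rod_layout": layout,
    }
    vol = VoxelVolume(hu, (h, h, h), meta=meta)
    return vol, labels


def rod_masks(labels: np.ndarray, n_rods: int) -> list[np.ndarray]:
    """Per-rod boolean masks from a label map (ground truth or segmentation)."""
    return [labels == rod_label(i) for i in range(n_rods)]


# ---------------------------------------------------------------------------
# Gait-cycle knee-force curves


@dataclass
class SyntheticCurveSpec:
    """Two-peak stance-phase knee-force curve over one gait cycle.

    Peak magnitudes are in %BW per force component (Fx anterior-posterior,
    Fy medio-lateral, Fz axial along the bone); peak times are fractions of
    the cycle, which runs heel strike to heel strike on [0, 1].
    """

    level: WeightBearingLevel = WeightBearingLevel.FULL
    n_samples: int = 101
    axial_peaks: tuple[float, float] = (260.0, 240.0)
    ap_peaks: tuple[float, float] = (30.0, 26.0)
    ml_peaks: tuple[float, float] = (14.0, 12.0)
    peak_times: tuple[float, float] = (0.15, 0.45)
    stance_fraction: float = 0.62
    valley_fraction: float = 0.7  # mid-stance valley as a fraction of the smaller peak
    baseline: float = 0.0
    noise_sd: float = 0.0  # %BW
    seed: int = 0

    def __post_init__(self) -> None:
        self.level = WeightBearingLevel(self.level)
        if self.n_samples < 11:
            raise ValueError("a gait curve needs at least 11 samples over the cycle")
        t1, t2 = self.peak_times
        if not (0.0 < t1 < t2 < self.stance_fraction < 1.0):
            raise ValueError("need 0 < first peak < second peak < stance end < 1")
        for pair in (self.axial_peaks, self.ap_peaks, self.ml_peaks):
            if min(pair) < 0:
                raise ValueError("peak magnitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    @classmethod
    def for_level(cls, level: WeightBearingLevel, seed: int = 0, **kw) -> "SyntheticCurveSpec":
        """Level-specific defaults for the three weight-bearing scenarios."""
        level = WeightBearingLevel(level)
        p1, p2 = _LEVEL_AXIAL_PEAKS[level]
        kw.setdefault("axial_peaks", (p1, p2))
        kw.setdefault("ap_peaks", (0.12 * p1, 0.12 * p2))
        kw.setdefault("ml_peaks", (0.055 * p1, 0.055 * p2))
        return cls(level=level, seed=seed, **kw)


def _two_peak_profile(t: np.ndarray, spec: SyntheticCurveSpec, peaks: tuple[float, float]) -> np.ndarray:
    """Shape-preserving two-peak stance profile through fixed control points.

    Monotone (PCHIP) interpolation between the knots guarantees the curve
    never overshoots them, so its maximum is exactly ``max(peaks)`` at the
    configured peak time.
    """
    p1, p2 = peaks
    t1, t2 = spec.peak_times
    tm = 0.5 * (t1 + t2)
    valley = spec.baseline + spec.valley_fraction * (min(p1, p2) - spec.baseline)
    knots_t = np.array([0.0, t1, tm, t2, spec.stance_fraction, 1.0])
    knots_v = np.array([spec.baseline, p1, valley, p2, spec.baseline, spec.baseline])
    return PchipInterpolator(knots_t, knots_v)(t)


def generate_gait_curve(spec: SyntheticCurveSpec) -> GaitForceCurve:
    """Synthesize a %BW knee-force curve (Fx, Fy, Fz) over one gait cycle.

    The axial component dominates with two stance peaks; seeded Gaussian
    noise is added to interior samples so the heel-strike endpoints stay at
    the configured baseline.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, 1.0, spec.n_samples)
    F = np.column_stack(
        [
            _two_peak_profile(t, spec, spec.ap_peaks),
            _two_peak_profile(t, spec, spec.ml_peaks),
            _two_peak_profile(t, spec, spec.axial_peaks),
        ]
    )
    if spec.noise_sd > 0:
        noise = spec.noise_sd * rng.standard_normal(F.shape)
        noise[0] = noise[-1] = 0.0
        F = F + noise
    return GaitForceCurve(t, F, unit="%BW", level=spec.level)


# ---------------------------------------------------------------------------
# Insole ground-reaction-force curves


@dataclass
class InsoleCurveSpec:
    """Single-bump stance GRF curve for load-compliance monitoring."""

    n_samples: int = 101
    stance_fraction: float = 0.62
    rel_error_sd: float = 0.0  # sd of the multiplicative peak error
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 11:
            raise ValueError("an insole curve needs at least 11 samples")
        if not 0 < self.stance_fraction <= 1:
            raise ValueError("stance fraction must be in (0, 1]")
        if self.rel_error_sd < 0:
            raise ValueError("relative error sd must be non-negative")


def generate_insole_curve(prescribed_load: float, spec: InsoleCurveSpec | None = None) -> GRFCurve:
    """Vertical GRF over one cycle whose peak is ``prescribed_load`` Newtons
    times ``1 + eps`` with ``eps ~ N(0, rel_error_sd)`` (seeded)."""
    if prescribed_load < 0:
        raise ValueError("prescribed load must be non-negative")
    spec = spec or InsoleCurveSpec()
    rng = np.random.default_rng(spec.seed)
    eps = spec.rel_error_sd * rng.standard_normal() if spec.rel_error_sd > 0 else 0.0
    t = np.linspace(0.0, 1.0, spec.n_samples)
    shape = np.where(
        t <= spec.stance_fraction, np.sin(np.pi * t / spec.stance_fraction) ** 2, 0.0
    )
    peak_shape = shape.max()
    if peak_shape > 0:
        shape = shape / peak_shape  # peak lands exactly on the grid
    fz = prescribed_load * (1.0 + eps) * shape
    return GRFCurve(t, fz)
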