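"""Gait-cycle knee-force curves, %BW normalization and weight-bearing substitution.

Knee joint forces are expressed either in Newtons or as a percentage of body
weight (%BW = 100 * F / (m * g)). A reference database stores mean %BW curves
per weight-bearing level (20 kg partial load, 50% body weight, full); scaling
the mean curve of a level by a patient's body weight yields the amplitude
table (a :class:`~fractwin.fem.LoadCase`) driving the finite-element solve.
Instrumented-insole ground-reaction-force curves are checked against the
prescribed partial load for compliance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import LoadCase

STANDARD_GRAVITY = 9.81  # m/s²

__all__ = [
    "WeightBearingLevel",
    "GaitForceCurve",
    "GRFCurve",
    "ReferenceDatabase",
    "ComplianceReport",
    "normalize_to_bw",
    "denormalize_to_newtons",
    "resample_curve",
    "build_reference",
    "scale_to_patient",
    "check_compliance",
    "STANDARD_GRAVITY",
]


class WeightBearingLevel(str, Enum):
    """Prescribed weight-bearing scenarios compared by the pipeline."""

    PWB_20KG = "PWB_20KG"
    PWB_50PCT = "PWB_50PCT"
    FULL = "FULL"


@dataclass
class GaitForceCurve:
    """Knee-force components sampled over one gait cycle (heel strike to heel strike).

    ``t`` are cycle fractions in [0, 1], strictly increasing; ``F`` has one
    row per sample and columns (Fx, Fy, Fz). The unit tag is '%BW' or 'N';
    converting between them requires the subject's body mass.
    """

    t: np.ndarray
    F: np.ndarray
    unit: str = "%BW"
    body_mass: float | None = None  # kg, required when unit == 'N'
    level: WeightBearingLevel | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("need at least two time samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.t[0] < 0 or self.t[-1] > 1:
            raise ValueError("cycle domain is [0, 1]")
        if self.F.shape != (self.t.size, 3):
            raise ValueError(f"F must be ({self.t.size}, 3), got {self.F.shape}")
        if self.unit not in ("%BW", "N"):
            raise ValueError(f"unit must be '%BW' or 'N', got {self.unit!r}")
        if self.level is not None:
            self.level = WeightBearingLevel(self.level)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"t_frac": self.t, "Fx": self.F[:, 0], "Fy": self.F[:, 1], "Fz": self.F[:, 2]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, unit: str = "%BW", **kw) -> "GaitForceCurve":
        df = pd.read_csv(path)
        return cls(df["t_frac"].to_numpy(), df[["Fx", "Fy", "Fz"]].to_numpy(), unit=unit, **kw)


@dataclass
class GRFCurve:
    """Vertical ground-reaction force from an instrumented insole (N, >= 0)."""

    t: np.ndarray
    fz: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.fz.shape:
            raise ValueError("t and fz must be 1-D arrays of equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.fz < 0):
            raise ValueError("ground reaction forces must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_frac": self.t, "F": self.fz}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "GRFCurve":
        df = pd.read_csv(path)
        return cls(df["t_frac"].to_numpy(), df["F"].to_numpy(), **kw)


# ---------------------------------------------------------------------------
# Unit conversion and resampling


def normalize_to_bw(curve: GaitForceCurve, body_mass: float, g: float = STANDARD_GRAVITY) -> GaitForceCurve:
    """Convert a Newton curve to %BW: divide by body weight (N) and multiply by 100."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    if curve.unit != "N":
        raise ValueError("curve is not in Newtons")
    bw = body_mass * g
    return GaitForceCurve(curve.t.copy(), curve.F * (100.0 / bw), unit="%BW",
                          body_mass=body_mass, level=curve.level)


def denormalize_to_newtons(curve: GaitForceCurve, body_mass: float, g: float = STANDARD_GRAVITY) -> GaitForceCurve:
    """Inverse of :func:`normalize_to_bw`."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    if curve.unit != "%BW":
        raise ValueError("curve is not in %BW")
    bw = body_mass * g
    return GaitForceCurve(curve.t.copy(), curve.F * (bw / 100.0), unit="N",
                          body_mass=body_mass, level=curve.level)


def resample_curve(curve: GaitForceCurve, n_samples: int) -> GaitForceCurve:
    """Linear resampling onto a uniform grid spanning the curve's time range.

    Endpoint values are preserved exactly.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    t_new = np.linspace(curve.t[0], curve.t[-1], n_samples)
    F_new = np.column_stack([np.interp(t_new, curve.t, curve.F[:, c]) for c in range(3)])
    F_new[0] = curve.F[0]
    F_new[-1] = curve.F[-1]
    return GaitForceCurve(t_new, F_new, unit=curve.unit, body_mass=curve.body_mass, level=curve.level)


# ---------------------------------------------------------------------------
# Reference database and weight-bearing substitution


@dataclass
class ReferenceDatabase:
    """Per weight-bearing level: the cohort mean %BW curve plus member curves."""

    mean: dict[WeightBearingLevel, GaitForceCurve]
    members: dict[WeightBearingLevel, list[GaitForceCurve]] = field(default_factory=dict)

    def levels(self) -> list[WeightBearingLevel]:
        return list(self.mean)

    def save(self, directory: str | Path) -> None:
        """Write curves as CSV files plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"levels": {}}
        for level, mean in self.mean.items():
            mean.to_csv(directory / f"{level.value}_mean.csv")
            n = 0
            for i, m in enumerate(self.members.get(level, [])):
                m.to_csv(directory / f"{level.value}_subject{i:02d}.csv")
                n += 1
            manifest["levels"][level.value] = {"n_subjects": n, "grid_size": int(mean.t.size)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceDatabase":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        mean, members = {}, {}
        for level_name, info in manifest["levels"].items():
            level = WeightBearingLevel(level_name)
            mean[level] = GaitForceCurve.from_csv(directory / f"{level_name}_mean.csv", level=level)
            members[level] = [
                GaitForceCurve.from_csv(directory / f"{level_name}_subject{i:02d}.csv", level=level)
                for i in range(info["n_subjects"])
            ]
        return cls(mean=mean, members=members)


def build_reference(
    curves_by_level: dict[WeightBearingLevel, list[GaitForceCurve]], n_grid: int = 101
) -> ReferenceDatabase:
    """Pointwise mean of %BW curves per level, resampled to a common grid."""
    mean: dict[WeightBearingLevel, GaitForceCurve] = {}
    members: dict[WeightBearingLevel, list[GaitForceCurve]] = {}
    if not curves_by_level:
        raise ValueError("reference database needs at least one level")
    for level, curves in curves_by_level.items():
        level = WeightBearingLevel(level)
        if not curves:
            raise ValueError(f"no curves supplied for level {level.value}")
        for c in curves:
            if c.unit != "%BW":
                raise ValueError("reference curves must be %BW-normalized")
        resampled = [resample_curve(c, n_grid) for c in curves]
        F_mean = np.mean([c.F for c in resampled], axis=0)
        mean[level] = GaitForceCurve(resampled[0].t.copy(), F_mean, unit="%BW", level=level)
        members[level] = resampled
    return ReferenceDatabase(mean=mean, members=members)


def scale_to_patient(
    db: ReferenceDatabase,
    level: WeightBearingLevel,
    patient_mass: float,
    g: float = STANDARD_GRAVITY,
) -> LoadCase:
    """Substitute the patient's loading with the weight-scaled reference curve.

    The level's mean %BW curve is multiplied by the patient's body weight in
    Newtons over 100, yielding the amplitude table (N) for the FE solve.
    """
    level = WeightBearingLevel(level)
    if patient_mass <= 0:
        raise ValueError("patient mass must be positive")
    if level not in db.mean:
        raise KeyError(f"level {level.value} not present in the reference database")
    mean = db.mean[level]
    forces = mean.F * (patient_mass * g / 100.0)
    return LoadCase(times=mean.t.copy(), forces=forces, level=level.value)


# ---------------------------------------------------------------------------
# Insole compliance


@dataclass
class ComplianceReport:
    peak_N: float
    target_N: float
    ratio: float
    tolerance: float
    compliant: bool
    verdict: str  # 'compliant' | 'overload' | 'underload'

    def to_dict(self) -> dict:
        return {
            "peak_N": self.peak_N,
            "target_N": self.target_N,
            "ratio": self.ratio,
            "tolerance": self.tolerance,
            "compliant": self.compliant,
            "verdict": self.verdict,
        }


def check_compliance(
    grf: GRFCurve,
    prescribed_load: float,
    tolerance: float = 0.2,
    g: float = STANDARD_GRAVITY,
) -> ComplianceReport:
    """Compare the peak insole GRF against the prescribed partial load (kg).

    Compliant iff peak / (prescribed_load * g) lies within ``1 ± tolerance``.
    """
    if prescribed_load <= 0:
        raise ValueError("prescribed load must be positive")
    if grf.fz.size == 0:
        raise ValueError("empty ground-reaction-force curve")
    target = prescribed_load * g
    peak = float(grf.fz.max())
    ratio = peak / target
    if ratio < 1 - tolerance:
        verdict = "underload"
    elif ratio > 1 + tolerance:
        verdict = "overload"
    else:
        verdict = "compliant"
    return ComplianceReport(
        peak_N=peak, target_N=target, ratio=ratio, tolerance=tolerance,
        compliant=verdict == "compliant", verdict=verdict,
    )
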