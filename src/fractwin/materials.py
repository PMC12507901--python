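"""Heterogeneous bone material mapping from calibrated CT density.

Bone elements receive an isotropic Young's modulus from their local HU via
the calibration map and empirical density-elasticity power laws, with a
fixed Poisson ratio; the implant and the fracture gap are homogeneous. The
chain for a bone element is

    HU -> rho_eqm = slope*HU + intercept          (mg/cm³, clamped >= 0)
       -> rho_ash = c0 + c1 * rho_eqm             (g/cm³)
       -> rho_app = rho_ash / ash_app_ratio       (g/cm³)
       -> E = a_t * rho_app^b_t   (trabecular)  or  a_c * rho_ash^b_c  (cortical)
       -> clamp to [E_floor, E_cap]               (MPa)

with the trabecular/cortical decision made by an ash-density split
(equivalent-density split available via config). The default coefficients
are the conventional literature values for human long bones; every number
is a configurable scientific input, not a code constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import DensityCalibration
from .meshing import TetMesh
from .volume import GAP, IMPLANT, LABEL_NAMES, VoxelVolume

__all__ = ["MaterialModel", "ElementMaterials", "bone_modulus", "map_materials"]


@dataclass
class MaterialModel:
    """Density-elasticity laws and homogeneous implant/gap properties (mm-N-MPa)."""

    # Trabecular power law on apparent density: E = a_t * rho_app^b_t (MPa, g/cm³)
    a_t: float = 6850.0
    b_t: float = 1.49
    # Cortical power law on ash density: E = a_c * rho_ash^b_c
    a_c: float = 10200.0
    b_c: float = 2.01
    # Ash density from equivalent mineral density (both g/cm³)
    c0: float = 0.0633
    c1: float = 0.887
    ash_app_ratio: float = 0.6  # rho_ash / rho_app in mature bone
    split_density: float = 0.6  # g/cm³; at/above -> cortical law
    split_on: str = "ash"  # 'ash' | 'eqm': which density the split tests
    nu: float = 0.3
    E_floor: float = 0.5  # MPa
    E_cap: float = 30000.0
    # Homogeneous materials
    implant_E: float = 110000.0  # Ti alloy
    implant_nu: float = 0.3
    implant_yield: float = 880.0  # MPa, medical TiAl alloy yield strength
    gap_E: float = 3.0  # early soft callus / granulation tissue
    gap_nu: float = 0.3

    def __post_init__(self) -> None:
        for name in ("a_t", "b_t", "a_c", "b_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name, v in (("nu", self.nu), ("implant_nu", self.implant_nu), ("gap_nu", self.gap_nu)):
            if not 0 < v < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if self.E_floor <= 0 or self.E_floor > self.E_cap:
            raise ValueError("need 0 < E_floor <= E_cap")
        if self.split_on not in ("ash", "eqm"):
            raise ValueError("split_on must be 'ash' or 'eqm'")
        if self.implant_yield <= 0:
            raise ValueError("implant yield strength must be positive")


def bone_modulus(rho_eqm_mg_cm3, model: MaterialModel) -> np.ndarray:
    """Young's modulus (MPa) from equivalent mineral density (mg/cm³).

    Negative calibrated densities are clamped to zero before the power law.
    """
    rho_eqm = np.maximum(np.asarray(rho_eqm_mg_cm3, dtype=float), 0.0) / 1000.0  # g/cm³
    rho_ash = model.c0 + model.c1 * rho_eqm
    rho_app = rho_ash / model.ash_app_ratio
    split_rho = rho_ash if model.split_on == "ash" else rho_eqm
    E = np.where(
        split_rho < model.split_density,
        model.a_t * rho_app**model.b_t,
        model.a_c * rho_ash**model.b_c,
    )
    return np.clip(E, model.E_floor, model.E_cap)


@dataclass
class ElementMaterials:
    """Per-element Young's modulus (MPa), Poisson ratio and region label."""

    E: np.ndarray
    nu: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        self.region = np.asarray(self.region, dtype=np.int64)
        if not (self.E.shape == self.nu.shape == self.region.shape):
            raise ValueError("E, nu and region must have one entry per element")
        if np.any(self.E <= 0):
            raise ValueError("all Young's moduli must be positive")

    @property
    def n_elements(self) -> int:
        return self.E.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "element_id": np.arange(self.n_elements),
                "region": [LABEL_NAMES.get(r, str(r)) for r in self.region],
                "E_MPa": self.E,
                "nu": self.nu,
            }
        ).to_csv(path, index=False)


def element_hu(mesh: TetMesh, volume: VoxelVolume) -> np.ndarray:
    """Per-element HU: mean over voxel centres inside the element, falling
    back to the HU at the element centroid's voxel.

    For meshes produced by the voxel decomposition each tet lies inside its
    source voxel, so both rules reduce to that voxel's HU and a fast path
    reads it directly.
    """
    if mesh.element_voxel is not None:
        return volume.data.ravel()[mesh.element_voxel]

    corners = mesh.nodes[mesh.corner_elements()]  # (m, 4, 3)
    centroids = corners.mean(axis=1)
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    shape = np.asarray(volume.shape)
    hu = np.empty(mesh.n_elements)
    for e in range(mesh.n_elements):
        x = corners[e]
        lo = volume.index_of(x.min(axis=0))
        hi = volume.index_of(x.max(axis=0))
        lo_c = np.clip(lo, 0, shape - 1)
        hi_c = np.clip(hi, 0, shape - 1)
        ii, jj, kk = np.meshgrid(
            *(np.arange(lo_c[d], hi_c[d] + 1) for d in range(3)), indexing="ij"
        )
        centers = origin + (np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + 0.5) * spacing
        inside = _points_in_tet(centers, x)
        if np.any(inside):
            idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)[inside]
            hu[e] = volume.data[idx[:, 0], idx[:, 1], idx[:, 2]].mean()
        else:
            ci = volume.index_of(centroids[e])
            if np.any(ci < 0) or np.any(ci >= shape):
                raise ValueError(f"element {e} lies outside the image volume")
            hu[e] = volume.data[tuple(ci)]
    return hu


def _points_in_tet(points: np.ndarray, tet: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Barycentric inside test for points (p, 3) against one tet (4, 3)."""
    T = np.column_stack([tet[1] - tet[0], tet[2] - tet[0], tet[3] - tet[0]])
    try:
        lam = np.linalg.solve(T, (points - tet[0]).T).T
    except np.linalg.LinAlgError:
        return np.zeros(len(points), dtype=bool)
    lam0 = 1 - lam.sum(axis=1)
    return (lam >= -tol).all(axis=1) & (lam0 >= -tol)


def map_materials(
    mesh: TetMesh,
    volume: VoxelVolume,
    calibration: DensityCalibration,
    model: MaterialModel | None = None,
) -> ElementMaterials:
    """Assign every element an (E, nu) pair.

    Implant and gap elements get their homogeneous properties; bone elements
    get the density-elasticity chain evaluated on their sampled HU.
    """
    model = model or MaterialModel()
    region = mesh.region
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)

    implant = region == IMPLANT
    gap = region == GAP
    bone = ~implant & ~gap
    E[implant], nu[implant] = model.implant_E, model.implant_nu
    E[gap], nu[gap] = model.gap_E, model.gap_nu

    if np.any(bone):
        hu = element_hu(mesh, volume)
        rho_eqm = calibration.density(hu[bone])
        E[bone] = bone_modulus(rho_eqm, model)
        nu[bone] = model.nu
    return ElementMaterials(E=E, nu=nu, region=region.copy())
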