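"""Calibrated CT-like voxel volumes.

The coordinate contract used throughout the package: axis order (x, y, z)
with z the long bone axis, distal at low z; spacing in millimetres; voxel
values in Hounsfield units (float by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Label constants shared by the phantom ground truth and the segmentation.
# The segmentation does not distinguish cortical from trabecular bone; it
# uses BONE for both, and ground-truth labels CORTICAL/TRABECULAR both count
# as bone when the two maps are compared.
BACKGROUND = 0
BONE = 1
CORTICAL = 1
TRABECULAR = 2
GAP = 3
IMPLANT = 4
ROD_BASE = 10  # rod i is labelled ROD_BASE + i

LABEL_NAMES = {
    BACKGROUND: "background",
    CORTICAL: "cortical",
    TRABECULAR: "trabecular",
    GAP: "gap",
    IMPLANT: "implant",
}


def rod_label(i: int) -> int:
    return ROD_BASE + i


def is_rod(labels: np.ndarray) -> np.ndarray:
    return labels >= ROD_BASE


def as_bone(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of voxels that count as bone (cortical or trabecular)."""
    return (labels == CORTICAL) | (labels == TRABECULAR)


@dataclass
class VoxelVolume:
    """A 3-D image of Hounsfield units with physical spacing.

    Parameters
    ----------
    data:
        HU values, shape ``(nx, ny, nz)``.
    spacing:
        Voxel edge lengths in mm, one per axis.
    origin:
        World coordinate (mm) of the corner of voxel ``(0, 0, 0)``; the
        centre of that voxel sits at ``origin + spacing / 2``.
    meta:
        Free-form metadata (e.g. the phantom's true calibration map and
        rod geometry).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_size(self) -> np.ndarray:
        """Edge lengths of the volume in mm."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def voxel_center(self, index) -> np.ndarray:
        """World coordinates (mm) of the centre(s) of the given voxel index array."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.spacing)

    def index_of(self, point) -> np.ndarray:
        """Voxel index containing a world point (no bounds check)."""
        p = np.asarray(point, dtype=float)
        return np.floor((p - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)

    def contains(self, point) -> bool:
        idx = self.index_of(point)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    # ------------------------------------------------------------------ I/O

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to world mm (voxel centres)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.spacing)
        return aff

    def to_nifti(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the volume as NIfTI plus a JSON sidecar with the metadata."""
        import nibabel as nib

        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        nib.save(img, str(path))
        if sidecar:
            side = {
                "spacing_mm": list(self.spacing),
                "origin_mm": list(self.origin),
                **_jsonable(self.meta),
            }
            stem = path.name
            for suf in (".nii.gz", ".nii"):
                if stem.endswith(suf):
                    stem = stem[: -len(suf)]
                    break
            (path.parent / f"{stem}.json").write_text(json.dumps(side, indent=2, sort_keys=True))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        origin = tuple(float(aff[i, 3]) - 0.5 * spacing[i] for i in range(3))
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
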