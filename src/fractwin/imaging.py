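"""Density calibration from phantom rods and adaptive-threshold segmentation.

The calibration phantom's rods of known hydroxyapatite density scanned with
the patient establish the linear map from Hounsfield units to equivalent
mineral density, rho_eqm(HU) = slope * HU + intercept (mg/cm³). Segmentation
thresholds are then specified in density units and converted to HU through
the inverse of that map — the "adaptive" part: the same density thresholds
adapt to each scan's calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, BONE, GAP, IMPLANT, VoxelVolume, rod_label

__all__ = [
    "DensityCalibration",
    "SegmentationConfig",
    "SegmentationMasks",
    "calibrate_density",
    "segment_adaptive",
    "rod_masks_from_layout",
]


@dataclass
class DensityCalibration:
    """Linear HU -> equivalent-mineral-density map fitted on the rods.

    slope in mg/cm³ per HU, intercept in mg/cm³; ``rmse`` is the fit
    residual in mg/cm³. ``rods`` lists (known density, mean HU, voxel count)
    per rod.
    """

    slope: float
    intercept: float
    rmse: float
    rods: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("calibration coefficients must be finite")
        if len(self.rods) < 2:
            raise ValueError("calibration needs at least 2 rods")

    def density(self, hu) -> np.ndarray:
        """Equivalent mineral density (mg/cm³) for HU values."""
        return self.slope * np.asarray(hu, dtype=float) + self.intercept

    def hu_at_density(self, rho) -> np.ndarray:
        """Inverse map: HU at a given density (mg/cm³)."""
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        return (np.asarray(rho, dtype=float) - self.intercept) / self.slope

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope_mg_cm3_per_hu": self.slope,
                    "intercept_mg_cm3": self.intercept,
                    "rmse_mg_cm3": self.rmse,
                    "rods": [
                        {"density_mg_cm3": d, "mean_hu": h, "n_voxels": n}
                        for d, h, n in self.rods
                    ],
                },
                indent=2,
                sort_keys=True,
            )
        )


def calibrate_density(
    volume: VoxelVolume, rod_regions: list[np.ndarray], known_densities
) -> DensityCalibration:
    """Ordinary least-squares fit of known rod density on mean rod HU.

    Parameters
    ----------
    rod_regions:
        One boolean mask per rod (same shape as the volume), e.g. from the
        phantom label map or :func:`rod_masks_from_layout`.
    known_densities:
        Certified rod densities, mg hydroxyapatite/cm³.
    """
    rho = np.asarray(known_densities, dtype=float)
    if len(rod_regions) != rho.size:
        raise ValueError("one known density per rod region required")
    if rho.size < 2:
        raise ValueError("calibration needs at least 2 rods")
    mean_hu = np.empty(rho.size)
    counts = np.empty(rho.size, dtype=int)
    for i, mask in enumerate(rod_regions):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != volume.shape:
            raise ValueError(f"rod region {i} shape {mask.shape} != volume shape {volume.shape}")
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"rod region {i} is empty")
        mean_hu[i] = float(volume.data[mask].mean())
        counts[i] = n
    if np.ptp(mean_hu) == 0:
        raise ValueError("degenerate rod HU values: all rods measure the same mean HU")
    slope, intercept = np.polyfit(mean_hu, rho, 1)
    resid = rho - (slope * mean_hu + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return DensityCalibration(
        slope=float(slope),
        intercept=float(intercept),
        rmse=rmse,
        rods=[(float(rho[i]), float(mean_hu[i]), int(counts[i])) for i in range(rho.size)],
    )


def rod_masks_from_layout(volume: VoxelVolume, layout: dict | None = None,
                          shrink: float = 0.7) -> list[np.ndarray]:
    """Cylindrical rod ROIs from the phantom's known rod geometry.

    ``layout`` defaults to ``volume.meta['rod_layout']``. ROIs use a radius
    shrunk by ``shrink`` to avoid partial-volume voxels at the rod boundary.
    """
    layout = layout or volume.meta.get("rod_layout")
    if layout is None:
        raise ValueError("no rod layout available: pass one or use a phantom volume")
    nx, ny, nz = volume.shape
    h = np.asarray(volume.spacing)
    x = (np.arange(nx) + 0.5) * h[0]
    y = (np.arange(ny) + 0.5) * h[1]
    z = (np.arange(nz) + 0.5) * h[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    z_lo, z_hi = layout["z_span"]
    z_band = (Z >= z_lo) & (Z < z_hi)
    masks = []
    for rx, ry in layout["centers_xy"]:
        d2 = (X - rx) ** 2 + (Y - ry) ** 2
        mask = (d2 <= (shrink * layout["radius"]) ** 2) & z_band
        if not mask.any():  # coarse grids: fall back to the full rod radius,
            mask = (d2 <= layout["radius"] ** 2) & z_band
        if not mask.any():  # then to the in-band voxels nearest the rod axis
            mask = (d2 <= d2[z_band].min()) & z_band
        masks.append(mask)
    return masks


# ---------------------------------------------------------------------------
# Segmentation


@dataclass
class SegmentationConfig:
    """Thresholds for the adaptive segmentation.

    Density thresholds are in mg/cm³ and converted to HU through the inverse
    calibration map; the implant threshold is in HU directly (metal sits far
    outside any physiological density and needs no calibration).
    """

    bone_density_threshold: float = 150.0  # mg/cm³: above -> bone
    gap_density_threshold: float = 150.0  # mg/cm³: below, inside envelope -> gap
    metal_hu_threshold: float = 2000.0

    def __post_init__(self) -> None:
        if self.gap_density_threshold > self.bone_density_threshold:
            raise ValueError("thresholds out of order: gap threshold must not exceed bone threshold")


@dataclass
class SegmentationMasks:
    """Mutually exclusive, exhaustive voxel labels plus the HU thresholds used."""

    labels: np.ndarray
    thresholds_hu: dict[str, float]
    spacing: tuple[float, float, float]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def segment_adaptive(
    volume: VoxelVolume,
    calibration: DensityCalibration,
    config: SegmentationConfig | None = None,
    rod_regions: list[np.ndarray] | None = None,
) -> SegmentationMasks:
    """Threshold the volume into background / bone / gap / implant / rod labels.

    Implant voxels are those above the metal HU threshold. Bone voxels map to
    densities above the bone threshold. The fracture gap is whatever lies
    inside the bone envelope — the region spanned by bone along the long
    axis, with in-plane holes filled — but below the gap density threshold
    (soft callus HU). Known rod regions, when supplied (or derivable from
    phantom metadata), are labelled before bone so calibration rods are never
    mistaken for anatomy.
    """
    config = config or SegmentationConfig()
    hu = volume.data
    bone_hu = float(calibration.hu_at_density(config.bone_density_threshold))
    gap_hu = float(calibration.hu_at_density(config.gap_density_threshold))

    labels = np.full(volume.shape, BACKGROUND, dtype=np.int16)

    if rod_regions is None and "rod_layout" in volume.meta:
        rod_regions = rod_masks_from_layout(volume)
    if rod_regions:
        for i, mask in enumerate(rod_regions):
            labels[np.asarray(mask, dtype=bool)] = rod_label(i)

    implant = hu >= config.metal_hu_threshold
    bone = (hu >= bone_hu) & ~implant & (labels == BACKGROUND)

    # Bone envelope: close the structure along z (gap slabs lie between bone
    # above and below), then fill in-plane holes (medullary space).
    solid = bone | implant
    envelope = _z_closure(solid)
    for k in range(envelope.shape[2]):
        envelope[:, :, k] = ndimage.binary_fill_holes(envelope[:, :, k])
    gap = envelope & ~solid & (labels == BACKGROUND) & (hu < gap_hu)

    labels[bone] = BONE
    labels[gap] = GAP
    labels[implant] = IMPLANT
    thresholds = {"bone_hu": bone_hu, "gap_hu": gap_hu, "metal_hu": config.metal_hu_threshold}
    return SegmentationMasks(labels=labels, thresholds_hu=thresholds, spacing=volume.spacing)


def _z_closure(mask: np.ndarray) -> np.ndarray:
    """Per-(x, y) column, mark every voxel between the first and last True z."""
    any_col = mask.any(axis=2)
    nz = mask.shape[2]
    first = np.argmax(mask, axis=2)
    last = nz - 1 - np.argmax(mask[:, :, ::-1], axis=2)
    k = np.arange(nz)[None, None, :]
    out = (k >= first[:, :, None]) & (k <= last[:, :, None]) & any_col[:, :, None]
    return out
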