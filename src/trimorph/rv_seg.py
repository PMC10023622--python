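"""Semi-automatic right-ventricle volumetry.

Four steps: ROI crop, threshold-based speed image in [-1, 1], seeded region
growing restricted to positive speed, scripted manual refinement, and voxel
volume quantification.  The front propagation is monotone growth over
6-connected neighbours with positive speed; on binary speed images this is
exactly thresholded connected-component labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import BoundsError, InvalidParameterError
from .synth_valve import VoxelVolume

__all__ = [
    "SpeedImage",
    "SegmentationMask",
    "ThresholdSpec",
    "EditList",
    "crop_roi",
    "compute_speed_image",
    "region_grow",
    "refine_mask",
    "quantify_volume",
    "segment_rv",
]


@dataclass
class SpeedImage:
    data: np.ndarray  # in [-1, 1]
    spacing: float
    origin: np.ndarray

    def __post_init__(self):
        if self.data.min() < -1.0 - 1e-12 or self.data.max() > 1.0 + 1e-12:
            raise InvalidParameterError("speed values must lie in [-1, 1]")


@dataclass
class SegmentationMask:
    data: np.ndarray  # bool
    spacing: float
    origin: np.ndarray
    converged: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)


@dataclass(frozen=True)
class ThresholdSpec:
    lower: float
    upper: float
    ramp_width: float = 0.0

    def __post_init__(self):
        if self.lower > self.upper:
            raise InvalidParameterError("lower threshold must be <= upper")
        if self.ramp_width < 0:
            raise InvalidParameterError("ramp_width must be >= 0")


@dataclass(frozen=True)
class SphereEdit:
    op: str  # add | remove
    center: tuple[float, float, float]  # mm, world coordinates
    radius: float  # mm


@dataclass(frozen=True)
class BoxEdit:
    op: str  # add | remove
    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]


@dataclass
class EditList:
    edits: list = field(default_factory=list)


def crop_roi(vol: VoxelVolume, box_min: Iterable[float], box_max: Iterable[float]) -> VoxelVolume:
    """Crop to the world-space box; retained voxels keep their world coordinates."""
    lo = np.asarray(tuple(box_min), dtype=float)
    hi = np.asarray(tuple(box_max), dtype=float)
    i_lo = np.maximum(np.ceil((lo - vol.origin) / vol.spacing - 1e-9), 0).astype(int)
    i_hi = np.minimum(
        np.floor((hi - vol.origin) / vol.spacing + 1e-9), np.asarray(vol.shape) - 1
    ).astype(int)
    if (i_hi < i_lo).any():
        raise BoundsError("ROI box does not intersect the volume")
    data = vol.data[
        i_lo[0] : i_hi[0] + 1, i_lo[1] : i_hi[1] + 1, i_lo[2] : i_hi[2] + 1
    ]
    return VoxelVolume(
        data=data.copy(),
        spacing=vol.spacing,
        origin=vol.origin + i_lo * vol.spacing,
    )


def compute_speed_image(vol: VoxelVolume, thr: ThresholdSpec) -> SpeedImage:
    """Map intensities to speed: +1 inside [lower, upper], -1 beyond the
    ramps, linear in between (hard +-1 map when ramp_width is 0)."""
    i = vol.data.astype(float)
    s = np.full(i.shape, -1.0)
    inside = (i >= thr.lower) & (i <= thr.upper)
    s[inside] = 1.0
    if thr.ramp_width > 0:
        lo_ramp = (i >= thr.lower - thr.ramp_width) & (i < thr.lower)
        s[lo_ramp] = -1.0 + 2.0 * (i[lo_ramp] - (thr.lower - thr.ramp_width)) / thr.ramp_width
        hi_ramp = (i > thr.upper) & (i <= thr.upper + thr.ramp_width)
        s[hi_ramp] = 1.0 - 2.0 * (i[hi_ramp] - thr.upper) / thr.ramp_width
    return SpeedImage(data=s, spacing=vol.spacing, origin=vol.origin.copy())


def region_grow(
    speed: SpeedImage,
    seeds: Sequence[tuple[int, int, int]],
    max_iter: int = 10_000,
) -> SegmentationMask:
    """Monotone front propagation from the seeds over 6-connected voxels with
    positive speed.  Terminates when the front stops (the boundary of the
    positive region is reached) or after ``max_iter`` dilations (flagged)."""
    if not seeds:
        raise InvalidParameterError("at least one seed is required")
    allowed = speed.data > 0.0
    mask = np.zeros(speed.data.shape, dtype=bool)
    for seed in seeds:
        idx = tuple(int(v) for v in seed)
        if any(i < 0 or i >= n for i, n in zip(idx, speed.data.shape)):
            raise InvalidParameterError(f"seed {idx} outside the volume")
        if not allowed[idx]:
            raise InvalidParameterError(f"seed {idx} has non-positive speed")
        mask[idx] = True

    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    converged = False
    for _ in range(max_iter):
        grown = ndimage.binary_dilation(mask, structure=structure, mask=allowed)
        if (grown == mask).all():
            converged = True
            break
        mask = grown
    return SegmentationMask(
        data=mask, spacing=speed.spacing, origin=speed.origin.copy(), converged=converged
    )


def _shape_voxels(mask: SegmentationMask, edit) -> np.ndarray:
    shape = mask.data.shape
    coords = [
        mask.origin[d] + np.arange(shape[d]) * mask.spacing for d in range(3)
    ]
    if isinstance(edit, SphereEdit):
        c = np.asarray(edit.center, dtype=float)
        lo, hi = c - edit.radius, c + edit.radius
        _check_bounds(mask, lo, hi)
        dx = (coords[0] - c[0]) ** 2
        dy = (coords[1] - c[1]) ** 2
        dz = (coords[2] - c[2]) ** 2
        return (
            dx[:, None, None] + dy[None, :, None] + dz[None, None, :]
        ) <= edit.radius**2
    if isinstance(edit, BoxEdit):
        lo = np.asarray(edit.min_corner, dtype=float)
        hi = np.asarray(edit.max_corner, dtype=float)
        _check_bounds(mask, lo, hi)
        sel = [(coords[d] >= lo[d]) & (coords[d] <= hi[d]) for d in range(3)]
        return sel[0][:, None, None] & sel[1][None, :, None] & sel[2][None, None, :]
    raise InvalidParameterError(f"unknown edit shape {type(edit).__name__}")


def _check_bounds(mask: SegmentationMask, lo: np.ndarray, hi: np.ndarray) -> None:
    vol_lo = mask.origin
    vol_hi = mask.origin + (np.asarray(mask.data.shape) - 1) * mask.spacing
    if (hi < vol_lo).any() or (lo > vol_hi).any():
        raise BoundsError("edit shape lies entirely outside the volume")


def refine_mask(mask: SegmentationMask, edits: EditList) -> SegmentationMask:
    """Apply scripted add/remove edits in order as voxel-set union/difference."""
    data = mask.data.copy()
    for edit in edits.edits:
        if edit.op not in ("add", "remove"):
            raise InvalidParameterError(f"unknown edit op {edit.op!r}")
        voxels = _shape_voxels(mask, edit)
        if edit.op == "add":
            data |= voxels
        else:
            data &= ~voxels
    return SegmentationMask(
        data=data, spacing=mask.spacing, origin=mask.origin.copy(), converged=mask.converged
    )


def quantify_volume(mask: SegmentationMask) -> float:
    """Mask volume in mL: voxel count x spacing^3 / 1000."""
    return float(mask.data.sum() * mask.spacing**3 / 1000.0)


def segment_rv(
    vol: VoxelVolume,
    thr: ThresholdSpec,
    seeds: Sequence[tuple[int, int, int]],
    roi_min: Iterable[float] | None = None,
    roi_max: Iterable[float] | None = None,
    edits: EditList | None = None,
    max_iter: int = 10_000,
) -> tuple[SegmentationMask, float]:
    """Full four-step volumetry; seeds are voxel indices of the (cropped) volume."""
    if roi_min is not None and roi_max is not None:
        vol = crop_roi(vol, roi_min, roi_max)
    speed = compute_speed_image(vol, thr)
    mask = region_grow(speed, seeds, max_iter=max_iter)
    if edits is not None:
        mask = refine_mask(mask, edits)
    return mask, quantify_volume(mask)
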