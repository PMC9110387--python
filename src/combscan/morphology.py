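"""Morphological and Boolean operators on signed distance volumes.

Dilation and erosion by a Euclidean ball of radius ``r`` are level-set
offsets of the SDF: a voxel belongs to the dilation when its signed
distance is at most ``r`` and to the erosion when its interior depth
exceeds ``r``.  Compositions give morphological closing (dilate then
erode, fills gaps narrower than ``2r``) and opening (erode then dilate,
removes features thinner than ``2r``).  Boolean combinations are
pointwise min/max of distances.  Every public operation redistances its
result so the output is again a valid SDF; internally compositions run on
binary masks with one distance transform per offset, which is equivalent
and cheaper.

Discrete tie rule: dilation keeps voxels within distance ``<= r`` of the
solid and erosion keeps voxels with interior depth strictly ``> r``,
which makes erosion the exact complement-dual of dilation on the voxel
grid and matches discrete Minkowski sum/erosion with the Euclidean ball
footprint voxel-for-voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import SignedDistanceVolume, signed_distance_from_mask

__all__ = [
    "StructuringBall",
    "dilate",
    "erode",
    "close",
    "open_",
    "boolean",
    "dilate_mask",
    "erode_mask",
    "close_mask",
    "open_mask",
]


@dataclass(frozen=True)
class StructuringBall:
    """Euclidean ball structuring element of radius ``radius_mm``."""

    radius_mm: float

    def validate(self, spacing: float) -> float:
        if self.radius_mm < spacing:
            raise ValueError(
                f"ball radius {self.radius_mm} mm is below the voxel spacing {spacing} mm"
            )
        return self.radius_mm


def _pad_amount(radius_mm: float, spacing: float) -> int:
    return int(math.ceil(radius_mm / spacing)) + 2


def dilate_mask(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    """Voxels within Euclidean distance ``<= radius`` of the solid."""
    if not mask.any():
        return mask.copy()
    dist_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist_out <= radius_mm


def erode_mask(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    """Voxels whose interior depth strictly exceeds ``radius``."""
    if not mask.any():
        return mask.copy()
    dist_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    return dist_in > radius_mm


def close_mask(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    """Closing on a padded copy of the grid, cropped back to it."""
    n = _pad_amount(radius_mm, spacing)
    padded = np.pad(mask, n, constant_values=False)
    out = erode_mask(dilate_mask(padded, radius_mm, spacing), radius_mm, spacing)
    return out[n:-n, n:-n, n:-n]


def open_mask(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    n = _pad_amount(radius_mm, spacing)
    padded = np.pad(mask, n, constant_values=False)
    out = dilate_mask(erode_mask(padded, radius_mm, spacing), radius_mm, spacing)
    return out[n:-n, n:-n, n:-n]


def _wrap(sdf: SignedDistanceVolume, mask: np.ndarray, origin=None) -> SignedDistanceVolume:
    return signed_distance_from_mask(
        mask, sdf.spacing_mm, sdf.origin_mm if origin is None else origin, sdf.iso_threshold
    )


def dilate(
    sdf: SignedDistanceVolume, ball: StructuringBall, pad: bool = True
) -> SignedDistanceVolume:
    """Offset the solid outward by the ball radius.

    With ``pad`` (default) the grid is grown by ``ceil(r/spacing)+2``
    voxels per face so the dilation cannot clip at the bounds; otherwise
    an error is raised if dilated material would touch the grid boundary.
    """
    spacing = sdf.require_isotropic("dilate")
    r = ball.validate(spacing)
    mask = sdf.solid_mask
    origin = sdf.origin_mm
    if pad:
        n = _pad_amount(r, spacing)
        mask = np.pad(mask, n, constant_values=False)
        origin = tuple(o - n * s for o, s in zip(sdf.origin_mm, sdf.spacing_mm))
    out = dilate_mask(mask, r, spacing)
    if not pad:
        shell = np.ones(out.shape, dtype=bool)
        shell[1:-1, 1:-1, 1:-1] = False
        if (out & shell).any():
            raise ValueError("dilation overflows grid bounds (enable padding)")
    return _wrap(sdf, out, origin)


def erode(sdf: SignedDistanceVolume, ball: StructuringBall) -> SignedDistanceVolume:
    """Offset the solid inward by the ball radius (may annihilate it)."""
    spacing = sdf.require_isotropic("erode")
    r = ball.validate(spacing)
    return _wrap(sdf, erode_mask(sdf.solid_mask, r, spacing))


def close(
    sdf: SignedDistanceVolume, ball: StructuringBall, keep_grid: bool = True
) -> SignedDistanceVolume:
    """Morphological closing (dilate then erode): bridges gaps < 2r.

    The intermediate dilation runs on a padded grid; with ``keep_grid``
    (default) the result is cropped back to the input grid so it can be
    Boolean-combined with the input.
    """
    spacing = sdf.require_isotropic("close")
    r = ball.validate(spacing)
    out = close_mask(sdf.solid_mask, r, spacing)
    if not keep_grid:
        n = _pad_amount(r, spacing)
        mask = np.pad(out, n, constant_values=False)
        origin = tuple(o - n * s for o, s in zip(sdf.origin_mm, sdf.spacing_mm))
        return _wrap(sdf, mask, origin)
    return _wrap(sdf, out)


def open_(sdf: SignedDistanceVolume, ball: StructuringBall) -> SignedDistanceVolume:
    """Morphological opening (erode then dilate): removes features thinner than 2r."""
    spacing = sdf.require_isotropic("open")
    r = ball.validate(spacing)
    return _wrap(sdf, open_mask(sdf.solid_mask, r, spacing))


def boolean(
    a: SignedDistanceVolume, b: SignedDistanceVolume, op: str
) -> SignedDistanceVolume:
    """Combine two solids on the same grid: ``union``, ``intersect`` or ``subtract``.

    Pointwise min / max / max(d_a, -d_b) of the distance fields, followed
    by redistancing of the resulting solid.
    """
    if not a.same_grid(b):
        raise ValueError("boolean operands must share dims, spacing and origin")
    if op == "union":
        d = np.minimum(a.distances, b.distances)
    elif op == "intersect":
        d = np.maximum(a.distances, b.distances)
    elif op == "subtract":
        d = np.maximum(a.distances, -b.distances)
    else:
        raise ValueError(f"unknown boolean op {op!r}")
    return _wrap(a, d < 0)
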