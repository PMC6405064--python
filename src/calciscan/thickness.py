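"""Local wall-thickness maps on binary shell masks.

Thickness at a voxel is the diameter of the largest inscribed sphere
(disk in 2D) that contains the voxel and fits entirely inside the mask —
the Hildebrand definition, computed here as a Euclidean distance
transform followed by sphere propagation.  With the distance transform
measured between voxel centers, a maximal ball of EDT radius ``r``
covers voxels out to ``r`` and has geometric diameter ``2r - 1`` voxels:
a slab of 5 voxels (EDT ridge 3) maps to thickness 5 voxels, as it
should.  Masks are zero-padded; there is no periodic wrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from calciscan.errors import ValidationError


@dataclass
class ThicknessMap:
    """Per-voxel local thickness (um) defined on shell-mask voxels."""

    values: np.ndarray
    voxel_size: float

    @property
    def mask(self) -> np.ndarray:
        return self.values > 0

    @property
    def mean_thickness(self) -> float:
        return mean_wall_thickness(self, self.mask)


def _ball_offsets(radius: float, ndim: int) -> np.ndarray:
    """Boolean structuring element: voxel-center offsets within ``radius``."""
    r = int(np.floor(radius))
    grids = np.indices((2 * r + 1,) * ndim) - r
    return (grids ** 2).sum(axis=0) <= radius ** 2 + 1e-9


def local_thickness(mask: np.ndarray, voxel_size: float = 1.0) -> ThicknessMap:
    """Hildebrand local thickness of a binary mask, in um.

    Maximal-ball centers are taken from the distance transform and
    propagated largest-radius-first, so every covered voxel receives the
    diameter of the largest ball containing it.
    """
    mask = np.asarray(mask).astype(bool)
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be positive")
    if not mask.any():
        raise ValidationError("empty mask")
    dt = ndimage.distance_transform_edt(mask)
    thickness = np.zeros(mask.shape, dtype=np.float64)
    radii = np.unique(dt[mask])[::-1]  # descending
    for r in radii:
        if r <= 0:
            continue
        centers = dt == r
        covered = ndimage.binary_dilation(
            centers, structure=_ball_offsets(r, mask.ndim)) & mask
        diam = (2.0 * r - 1.0) * voxel_size
        np.maximum(thickness, np.where(covered, diam, 0.0), out=thickness)
    return ThicknessMap(values=thickness, voxel_size=voxel_size)


def mean_wall_thickness(tmap: ThicknessMap, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean of local thickness over shell voxels (um)."""
    mask = tmap.mask if mask is None else np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("empty mask")
    if np.any(tmap.values[mask] <= 0):
        raise ValidationError("thickness map undefined on part of the mask")
    return float(tmap.values[mask].mean())
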