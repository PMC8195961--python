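"""Tumor-centrality metric: distance from a reference point to the tumor border.

TVTB is the shortest Euclidean distance, in centimeters, from a reference
world-coordinate point (clinically, the center of the third ventricle) to
the contrast-enhancing tumor border. The border is the set of mask voxels
with at least one 6-connected neighbor outside the mask (voxels on the
volume boundary count as border); distances are measured to voxel centers
in world millimeters and divided by 10. A reference point inside the
tumor yields 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import TumorMask

__all__ = ["ReferencePoint", "tvtb_cm", "border_voxels"]

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ReferencePoint:
    """A fixed anatomical point in world coordinates (mm)."""

    world_mm: tuple[float, float, float]
    label: str = "center of third ventricle"

    def __post_init__(self) -> None:
        pt = tuple(float(v) for v in self.world_mm)
        if len(pt) != 3 or not all(np.isfinite(pt)):
            raise ValueError(f"world_mm must be 3 finite coordinates, got {self.world_mm}")
        object.__setattr__(self, "world_mm", pt)


def border_voxels(voxels: np.ndarray) -> np.ndarray:
    """Boolean array marking mask voxels with a 6-connected outside neighbor."""
    vox = np.asarray(voxels, dtype=bool)
    return vox & ~ndimage.binary_erosion(vox, structure=_STRUCT_6, border_value=0)


def tvtb_cm(mask: TumorMask, ref: ReferencePoint | tuple[float, float, float]) -> float:
    """Shortest distance (cm) from ``ref`` to the tumor border of ``mask``.

    Returns 0 when the reference point lies inside the mask (the voxel
    whose center is nearest the point is a tumor voxel).
    """
    if not isinstance(ref, ReferencePoint):
        ref = ReferencePoint(world_mm=tuple(ref))
    vox = mask.voxels
    if not vox.any():
        raise ValueError(f"mask {mask.patient_id!r} is empty")
    point = np.asarray(ref.world_mm, dtype=float)

    cont = mask.grid.world_to_voxel(point)[0]
    idx = np.rint(cont).astype(int)
    if np.all(idx >= 0) and np.all(idx < np.asarray(vox.shape)) and vox[tuple(idx)]:
        return 0.0

    border_idx = np.argwhere(border_voxels(vox))
    centers = mask.grid.voxel_to_world(border_idx)
    dists = np.linalg.norm(centers - point, axis=1)
    return float(dists.min() / 10.0)
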