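"""Volumetric IO for cohort tumor masks and statistical maps.

All masks of a cohort live on one shared grid (shape + affine); every map
produced downstream carries that same grid. NIfTI-1 is the on-disk format,
with a JSON sidecar holding provenance (groups compared, permutation count,
seed, ...).
"""

from __future__ import annotations

import json
import numbers
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "TumorMask",
    "MapLabel",
    "VoxelMap",
    "GridMismatchError",
    "load_mask",
    "save_mask",
    "write_map",
    "load_map",
]

#: absolute tolerance (mm) when comparing affines across files; covers
#: header round-off introduced by different NIfTI writers.
AFFINE_TOL_MM = 1e-4

#: threshold above which a voxel of a (possibly probabilistic) input volume
#: counts as tumor; robust to interpolation artifacts from registration.
BINARIZE_THRESHOLD = 0.5


class GridMismatchError(ValueError):
    """A volume does not live on the cohort's shared grid."""


@dataclass(frozen=True)
class GridSpec:
    """Shape and voxel-to-world affine of the common reference grid."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """Voxel spacing along each axis (column norms of the affine)."""
        return tuple(float(v) for v in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def matches(self, other: "GridSpec", tol_mm: float = AFFINE_TOL_MM) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol_mm, rtol=0.0)
        )

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers, indices of shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world_mm) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        pts = np.atleast_2d(np.asarray(world_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class TumorMask:
    """One patient's binary segmentation on the common grid."""

    patient_id: str
    grid: GridSpec
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.dtype != np.bool_:
            uniq = np.unique(vox)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(
                    f"mask {self.patient_id!r}: values must be binary, got {uniq[:5]}"
                )
            vox = vox.astype(bool)
        if vox.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask {self.patient_id!r}: shape {vox.shape} != grid {self.grid.shape}"
            )
        if not vox.any():
            raise ValueError(f"mask {self.patient_id!r} is empty")
        self.voxels = vox

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0


class MapLabel(str, Enum):
    COUNT = "count"
    ODDS = "odds"
    LOG_OR = "log_or"
    PVALUE = "pvalue"
    ADJ_PVALUE = "adj_pvalue"
    SIGNIFICANCE = "significance"


_MAP_DTYPES = {
    MapLabel.COUNT: np.int16,
    MapLabel.SIGNIFICANCE: np.int8,
}


@dataclass
class VoxelMap:
    """A labeled scalar field on the common grid with provenance metadata.

    Values are stored in the on-disk dtype (int16 for counts, int8 for
    significance masks, float32 otherwise) so that write/load round trips
    are bitwise.
    """

    label: MapLabel
    grid: GridSpec
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label = MapLabel(self.label)
        dtype = _MAP_DTYPES.get(self.label, np.float32)
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise GridMismatchError(
                f"{self.label.value} map: shape {values.shape} != grid {self.grid.shape}"
            )
        values = values.astype(dtype, copy=False)
        if self.label in (MapLabel.PVALUE, MapLabel.ADJ_PVALUE):
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{self.label.value} map has values outside [0, 1]")
        elif self.label is MapLabel.SIGNIFICANCE:
            if not np.isin(values, (0, 1)).all():
                raise ValueError("significance map must be 0/1")
        elif self.label is MapLabel.COUNT:
            if values.min() < 0:
                raise ValueError("count map must be non-negative")
        self.values = values


def _grid_from_img(img) -> GridSpec:
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        shape = shape[:3]
    if len(shape) != 3:
        raise ValueError(f"expected a single 3D volume, got shape {shape}")
    return GridSpec(shape=tuple(shape), affine=np.asarray(img.affine))


def load_mask(
    path,
    reference_grid: GridSpec | None = None,
    patient_id: str | None = None,
) -> TumorMask:
    """Load a binary tumor mask, binarizing any non-binary input at 0.5.

    When ``reference_grid`` is given, the file's grid must match it
    (shape equal, affine within :data:`AFFINE_TOL_MM`).
    """
    path = Path(path)
    if patient_id is None:
        patient_id = path.name.removesuffix(".gz").removesuffix(".nii")
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    if reference_grid is not None:
        if not grid.matches(reference_grid):
            raise GridMismatchError(
                f"patient {patient_id!r}: grid of {path.name} does not match the "
                f"cohort reference grid (shape {grid.shape} vs {reference_grid.shape})"
            )
        grid = reference_grid
    data = np.asanyarray(img.dataobj).reshape(grid.shape)
    voxels = data > BINARIZE_THRESHOLD
    if not voxels.any():
        raise ValueError(f"patient {patient_id!r}: mask {path.name} is empty")
    return TumorMask(patient_id=patient_id, grid=grid, voxels=voxels)


def save_mask(mask: TumorMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def _sidecar_path(path: Path) -> Path:
    name = path.name.removesuffix(".gz").removesuffix(".nii")
    return path.with_name(name + ".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, numbers.Integral):
        return int(obj)
    if isinstance(obj, numbers.Real):
        return float(obj)
    return obj


def write_map(vmap: VoxelMap, path) -> None:
    """Write a map as NIfTI plus a JSON provenance sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vmap.values, vmap.grid.affine)
    nib.save(img, str(path))
    sidecar = {"label": vmap.label.value, "metadata": _jsonable(vmap.metadata)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_map(path, label: MapLabel | None = None) -> VoxelMap:
    """Load a map written by :func:`write_map` (sidecar supplies the label)."""
    path = Path(path)
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    metadata: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        metadata = payload.get("metadata", {})
        if label is None:
            label = MapLabel(payload["label"])
    if label is None:
        raise ValueError(f"no sidecar found for {path.name}; pass label= explicitly")
    values = np.asanyarray(img.dataobj).reshape(grid.shape)
    return VoxelMap(label=label, grid=grid, values=values, metadata=metadata)
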