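"""Volumes, coordinate frames and tabular I/O.

Everything in :mod:`vimloc` lives in a single world coordinate convention:
millimetres, axis-aligned voxel grids, the anterior commissure (AC) at the
origin, ``x+`` pointing to the subject's right, ``y+`` anterior and ``z+``
superior.  All geometric predicates operate on voxel *centers*.  Rotated or
sheared grids are deliberately unsupported: inter-contrast registration is
assumed to have happened upstream, so every volume handled here shares one
rigid AC-PC frame.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "ROIMask",
    "IntensityVolume",
    "COHORT_COLUMNS",
    "read_volume",
    "write_volume",
    "load_cohort_table",
    "validate_cohort_table",
    "table1_path",
]


class VolumeIOError(ValueError):
    """Raised for malformed volumes, affines or cohort tables."""


@dataclass(frozen=True)
class VoxelGrid:
    """An axis-aligned voxel lattice in world millimetres.

    ``shape`` is the number of voxels per axis, ``spacing`` the voxel pitch
    in mm and ``origin`` the world coordinate of the *center* of voxel
    ``(0, 0, 0)``.  The world coordinate of voxel ``(i, j, k)`` is
    ``origin + (i, j, k) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise VolumeIOError(f"grid shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + ijk * np.asarray(self.spacing)

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Continuous (fractional) voxel index of a world point."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def nearest_voxel(self, xyz) -> np.ndarray:
        """Index of the voxel whose center is nearest to a world point."""
        return np.rint(self.world_to_voxel(xyz)).astype(int)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def contains_world(self, xyz) -> bool:
        frac = self.world_to_voxel(xyz)
        return bool(np.all(frac >= -0.5) and np.all(frac <= np.asarray(self.shape) - 0.5))


def _check_data_shape(grid: VoxelGrid, data: np.ndarray) -> None:
    if tuple(data.shape) != grid.shape:
        raise VolumeIOError(f"data shape {data.shape} does not match grid shape {grid.shape}")


@dataclass
class ROIMask:
    """A binary region of interest on a :class:`VoxelGrid` (values 0/1)."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_data_shape(self.grid, data)
        self.data = (data != 0).astype(np.uint8)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    def world_coords(self) -> np.ndarray:
        """(n, 3) world coordinates of the centers of all mask voxels."""
        return self.grid.voxel_to_world(np.argwhere(self.data))


@dataclass
class LabelVolume:
    """An integer label volume with a name -> value map (0 = background)."""

    grid: VoxelGrid
    data: np.ndarray
    label_map: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_data_shape(self.grid, data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.rint(data)):
                raise VolumeIOError("label volume contains non-integer values")
            data = np.rint(data).astype(np.int32)
        self.data = data
        present = set(np.unique(self.data)) - {0}
        known = set(int(v) for v in self.label_map.values())
        missing = present - known
        if missing:
            raise VolumeIOError(f"labels {sorted(missing)} present in data but absent from label_map")

    def mask(self, name: str) -> ROIMask:
        return ROIMask(self.grid, self.data == int(self.label_map[name]))


@dataclass
class IntensityVolume:
    """A scalar (e.g. SWI-like) volume."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        _check_data_shape(self.grid, data)
        self.data = data


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    lin = np.asarray(affine, dtype=float)[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    scale = max(np.abs(np.diag(lin)).max(), 1.0)
    if np.abs(off_diag).max() > 1e-4 * scale:
        raise VolumeIOError(
            "only orthogonal, axis-aligned affines are supported; "
            f"offending affine:\n{np.asarray(affine)}"
        )
    diag = np.diag(lin)
    if np.any(diag <= 0):
        raise VolumeIOError(
            "affine must have positive diagonal spacing (x-right, y-anterior, "
            f"z-superior convention); offending affine:\n{np.asarray(affine)}"
        )
    # NIfTI-1 stores the affine in float32; round away the representation
    # noise (origins are mm-scale, so float32 keeps ~1e-4 mm precision there)
    spacing = tuple(np.round(diag, 6))
    origin = tuple(np.round(np.asarray(affine, dtype=float)[:3, 3], 3))
    return VoxelGrid(tuple(shape[:3]), spacing, origin)


def read_volume(path, kind: str = "intensity"):
    """Read a NIfTI-1 volume as a label, mask or intensity volume.

    ``kind='mask'`` binarizes (any nonzero value becomes 1); ``kind='label'``
    requires (near-)integer data.  The grid is taken from the affine, which
    must be diagonal (no rotation or shear).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asanyarray(img.dataobj)
    if kind == "mask":
        return ROIMask(grid, data)
    if kind == "label":
        return LabelVolume(grid, data, label_map={f"label_{v}": int(v) for v in np.unique(data) if v != 0})
    if kind == "intensity":
        return IntensityVolume(grid, data)
    raise VolumeIOError(f"unknown volume kind {kind!r}")


def write_volume(vol, path) -> None:
    """Write a volume to NIfTI-1; labels and masks are stored as integers."""
    if isinstance(vol, (ROIMask, LabelVolume)):
        data = np.asarray(vol.data)
        dtype = np.uint8 if data.max(initial=0) < 256 and data.min(initial=0) >= 0 else np.int32
        data = data.astype(dtype)
    elif isinstance(vol, IntensityVolume):
        data = vol.data.astype(np.float32)
    else:
        raise VolumeIOError(f"cannot write object of type {type(vol).__name__}")
    img = nib.Nifti1Image(data, vol.grid.affine())
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id",
    "hemisphere",
    "vim_manual_mm3",
    "vim_manual_pct",
    "vim_multiatlas_mm3",
    "vim_multiatlas_pct",
    "vlv_cm3",
    "vlv_pct",
]

_VOLUME_COLUMNS = ["vim_manual_mm3", "vim_multiatlas_mm3", "vlv_cm3"]
_PCT_COLUMNS = ["vim_manual_pct", "vim_multiatlas_pct", "vlv_pct"]


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the cohort-table schema; returns the table with typed columns.

    Missing cells are NaN (encoded as empty strings in CSV, never 0).
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise VolumeIOError(f"cohort table is missing columns {missing}")
    table = table[COHORT_COLUMNS].copy()
    bad_hemi = set(table["hemisphere"]) - {"left", "right"}
    if bad_hemi:
        raise VolumeIOError(f"invalid hemisphere values {sorted(bad_hemi)}")
    dup = table.duplicated(subset=["subject_id", "hemisphere"])
    if dup.any():
        dups = table.loc[dup, ["subject_id", "hemisphere"]].values.tolist()
        raise VolumeIOError(f"duplicate (subject, hemisphere) rows: {dups}")
    for col in _VOLUME_COLUMNS + _PCT_COLUMNS:
        table[col] = pd.to_numeric(table[col], errors="raise")
        vals = table[col].dropna()
        if (vals < 0).any():
            raise VolumeIOError(f"negative values in column {col}")
    for col in _PCT_COLUMNS:
        vals = table[col].dropna()
        if (vals > 100).any():
            raise VolumeIOError(f"percent column {col} exceeds 100")
    return table


def load_cohort_table(path) -> pd.DataFrame:
    """Load a per-hemisphere cohort volume table from CSV."""
    table = pd.read_csv(path, dtype={"subject_id": str, "hemisphere": str})
    return validate_cohort_table(table)


def table1_path() -> Path:
    """Path of the packaged cohort volume table (nine subjects, two hemispheres)."""
    return Path(importlib.resources.files("vimloc.data") / "table1.csv")
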