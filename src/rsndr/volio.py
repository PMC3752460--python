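"""Volume, mask and design-table I/O plus the common-grid data model.

Every stage of the pipeline operates on volumes sharing one voxel grid
(shape + affine). Nothing here resamples: grids must match exactly, and
mismatches raise instead of being silently interpolated, since spatial
registration is a preprocessing concern outside this package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "BrainMask",
    "DesignTable",
    "GridMismatchError",
    "read_volume4d",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_design",
    "write_design",
    "mask_to_matrix",
    "unmask",
]

GROUP_LABELS = ("patient", "control")

#: absolute tolerance for declaring two affines equal
AFFINE_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Raised when volumes that must share a voxel grid do not."""


@dataclasses.dataclass
class Volume4D:
    """One subject's 4D image: X*Y*Z voxels over T timepoints.

    ``data`` is float, shape (X, Y, Z, T); 3D images are carried with T=1.
    ``affine`` maps voxel indices to mm (RAS+), ``tr_seconds`` is the
    repetition time.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclasses.dataclass
class BrainMask:
    """Boolean voxel mask on the analysis grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if not self.data.any():
            raise ValueError("mask has no true voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat (C-order) indices of the in-mask voxels."""
        return np.flatnonzero(self.data.ravel())


@dataclasses.dataclass
class DesignTable:
    """Two-group subject table: id, group (patient/control) and file paths."""

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "group", "bold_path")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if "gm_path" not in df.columns:
            df = df.assign(gm_path=None)
        self.frame = df.reset_index(drop=True)
        ids = self.frame["subject_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad = set(self.frame["group"]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}")
        for g in GROUP_LABELS:
            if not (self.frame["group"] == g).any():
                raise ValueError(f"group '{g}' has no subjects")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame["subject_id"]]

    @property
    def is_patient(self) -> np.ndarray:
        """Boolean vector, True for patient rows (design order)."""
        return (self.frame["group"] == "patient").to_numpy()

    def subset(self, group: str) -> "DesignTable":
        if group not in GROUP_LABELS:
            raise ValueError(f"unknown group {group!r}")
        # bypass the two-group validation: a subset is single-group by intent
        out = object.__new__(DesignTable)
        out.frame = self.frame[self.frame["group"] == group].reset_index(drop=True)
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume4d(path: str | Path) -> Volume4D:
    """Load a NIfTI-1 volume; 3D files come back with a singleton time axis."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else 1.0
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel values")
    return Volume4D(data=data, affine=img.affine, tr_seconds=tr)


def write_volume(path: str | Path, vol: Volume4D, dtype=np.float64) -> Path:
    """Write a Volume4D as NIfTI-1, recording TR in the 4th pixdim."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data.astype(dtype)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_data_dtype(dtype)
    zooms = list(img.header.get_zooms())
    if len(zooms) >= 4:
        zooms[3] = vol.tr_seconds
        img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(Path(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return BrainMask(data=data != 0, affine=img.affine)


def write_mask(path: str | Path, mask: BrainMask) -> Path:
    """Masks go to disk as 8-bit 0/1 integers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Design table I/O (tab-separated with header)


def read_design(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return DesignTable(frame=df)


def write_design(path: str | Path, design: DesignTable) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design.frame.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Masking


def _check_grid(shape3d, affine, mask: BrainMask, what: str) -> None:
    if tuple(shape3d) != mask.data.shape:
        raise GridMismatchError(
            f"{what}: shape {tuple(shape3d)} != mask shape {mask.data.shape}"
        )
    if not np.allclose(affine, mask.affine, atol=AFFINE_ATOL):
        raise GridMismatchError(f"{what}: affine differs from mask affine")


def mask_to_matrix(
    vols: Sequence[Volume4D], mask: BrainMask
) -> tuple[np.ndarray, np.ndarray]:
    """Stack subjects into a (subjects, time, voxel) array over the mask.

    All volumes must share the mask's grid and a common T. Column ``v`` of
    every subject's matrix is the voxel at ``index_map[v]`` (flat C-order
    index into the 3D grid), so ``unmask`` inverts exactly.
    """
    if not vols:
        raise ValueError("no volumes given")
    t0 = vols[0].n_timepoints
    for i, v in enumerate(vols):
        _check_grid(v.shape3d, v.affine, mask, f"volume {i}")
        if v.n_timepoints != t0:
            raise ValueError(f"volume {i}: T={v.n_timepoints} != {t0}")
    index_map = mask.indices
    flat = mask.data.ravel()
    out = np.empty((len(vols), t0, index_map.size), dtype=np.float64)
    for i, v in enumerate(vols):
        # (X,Y,Z,T) -> (T, V)
        out[i] = v.data.reshape(-1, t0)[flat].T
    return out, index_map


def unmask(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Scatter masked values back onto the 3D grid.

    ``values`` is (V,) or (rows, V); the result is 3D or (X,Y,Z,rows).
    """
    values = np.asarray(values)
    flat_idx = mask.indices
    if values.shape[-1] != flat_idx.size:
        raise ValueError(
            f"last axis {values.shape[-1]} != mask voxel count {flat_idx.size}"
        )
    if values.ndim == 1:
        out = np.full(mask.data.size, fill, dtype=values.dtype)
        out[flat_idx] = values
        return out.reshape(mask.data.shape)
    if values.ndim == 2:
        rows = values.shape[0]
        out = np.full((mask.data.size, rows), fill, dtype=values.dtype)
        out[flat_idx] = values.T
        return out.reshape(*mask.data.shape, rows)
    raise ValueError("values must be 1D or 2D")
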