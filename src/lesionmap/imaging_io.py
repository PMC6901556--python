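"""Volumetric I/O and the shared-grid contract.

Every multi-volume operation in the package assumes its inputs live on one
voxel grid. Nothing here resamples: volumes either share a grid (shape equal,
affines elementwise-close) or the caller gets a :class:`GridMismatchError`.
Registration belongs upstream.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    EmptyMaskError,
    FormatError,
    GridMismatchError,
    MissingLabelError,
)

#: Absolute tolerance for elementwise affine agreement between two grids.
AFFINE_ATOL = 1e-4

#: Statistic kinds a StatMap may carry.
STAT_KINDS = ("r", "z", "t", "binary", "sum", "vor")

PathLike = Union[str, os.PathLike]


@dataclass(frozen=True)
class VolumeGrid:
    """Shape + affine contract shared by every volume in an analysis."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        self.affine.setflags(write=False)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(n) for n in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def compatible(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, rtol=0.0, atol=atol)
        )

    def __eq__(self, other):
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.array_equal(self.affine, other.affine)

    def __hash__(self):
        return hash((self.shape, self.affine.tobytes()))


def check_grid_compatible(a: VolumeGrid, b: VolumeGrid) -> bool:
    """True iff shapes match and affines agree within ``AFFINE_ATOL``."""
    return a.compatible(b)


def require_compatible(a: VolumeGrid, b: VolumeGrid, context: str = "") -> None:
    if not check_grid_compatible(a, b):
        where = f" ({context})" if context else ""
        raise GridMismatchError(
            f"grids are incompatible{where}: shapes {a.shape} vs {b.shape}; "
            "volumes must share one grid — this package never resamples"
        )


@dataclass(frozen=True)
class LesionMask:
    """Binary 3-D mask plus its outcome label ('P' or 'C')."""

    grid: VolumeGrid
    voxels: np.ndarray
    subject_id: str
    outcome: str

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {vox.shape} does not match grid {self.grid.shape}"
            )
        uniq = np.unique(vox)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("lesion mask voxels must be 0/1")
        vox = vox.astype(np.uint8)
        if vox.sum() == 0:
            raise EmptyMaskError(f"lesion mask '{self.subject_id}' is empty")
        if self.outcome not in ("P", "C"):
            raise ValueError(f"outcome must be 'P' or 'C', got {self.outcome!r}")
        object.__setattr__(self, "voxels", vox)
        self.voxels.setflags(write=False)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3


@dataclass(frozen=True)
class ParcellationAtlas:
    """Labelled parcellation volume plus an id -> name table."""

    grid: VolumeGrid
    labels: np.ndarray
    label_table: Mapping[int, str]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise GridMismatchError("atlas label volume does not match its grid")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise FormatError("atlas label volume is not integer-valued")
            labels = np.round(labels).astype(np.int32)
        if labels.min() < 0:
            raise ValueError("atlas label ids must be non-negative")
        table = {int(k): str(v) for k, v in self.label_table.items()}
        present = set(int(v) for v in np.unique(labels)) - {0}
        missing = present - set(table)
        if missing:
            raise MissingLabelError(missing)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_table", table)
        self.labels.setflags(write=False)

    @property
    def region_ids(self) -> list[int]:
        """Ids present in the volume, sorted, background excluded."""
        return sorted(set(int(v) for v in np.unique(self.labels)) - {0})


@dataclass(frozen=True)
class StatMap:
    """Voxelwise real-valued volume tagged with its statistic kind.

    ``values`` carries NaN wherever ``valid`` is 0; statistics downstream
    only ever aggregate over the valid support.
    """

    grid: VolumeGrid
    values: np.ndarray
    kind: str
    valid: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown stat kind {self.kind!r}")
        values = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid).astype(bool)
        if values.shape != self.grid.shape or valid.shape != self.grid.shape:
            raise GridMismatchError("StatMap arrays do not match the grid")
        values = values.copy()
        values[~valid] = np.nan
        v = values[valid]
        if self.kind == "binary" and v.size and not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("binary StatMap must hold only 0/1 at valid voxels")
        if self.kind == "r" and v.size and (np.nanmax(np.abs(v)) > 1.0 + 1e-12):
            raise ValueError("r StatMap values must lie in [-1, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)
        object.__setattr__(self, "provenance", tuple(self.provenance))
        self.values.setflags(write=False)
        self.valid.setflags(write=False)

    def with_provenance(self, *steps: str) -> "StatMap":
        return replace(self, provenance=self.provenance + steps)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def read_volume(path: PathLike, expect_ndim: int = 3):
    """Read a NIfTI volume; return ``(data, VolumeGrid)``.

    No resampling or reorientation is performed: the grid is taken verbatim
    from the header affine.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    # tolerate trailing singleton dims (common in exported 3-D maps)
    while data.ndim > expect_ndim and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != expect_ndim:
        raise DimensionalityError(
            f"{path}: expected {expect_ndim}-D volume, got {data.ndim}-D"
        )
    grid = VolumeGrid(shape=tuple(data.shape[:3]), affine=affine)
    return data, grid


def write_volume(path: PathLike, data: np.ndarray, grid: VolumeGrid, dtype=None) -> Path:
    """Write ``data`` on ``grid`` as NIfTI-1. Returns the path written."""
    path = Path(path)
    data = np.asarray(data)
    if data.shape[:3] != grid.shape:
        raise GridMismatchError("data shape does not match grid for writing")
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_data_dtype(data.dtype)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_mask(path: PathLike, subject_id: str, outcome: str,
              threshold: float = 0.5) -> LesionMask:
    """Read a lesion mask volume, binarizing at ``> threshold``."""
    data, grid = read_volume(path, expect_ndim=3)
    vox = binarize_mask(data, threshold=threshold)
    return LesionMask(grid=grid, voxels=vox, subject_id=subject_id, outcome=outcome)


def binarize_mask(volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where ``volume > threshold``, else 0 (uint8).

    The strict ``>`` at 0.5 tolerates interpolation dust left by upstream
    nearest-neighbour registration while keeping already-binary input fixed.
    """
    volume = np.asarray(volume)
    if not np.isfinite(volume).all():
        raise ValueError("cannot binarize a volume with non-finite values")
    return (volume > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Label tables


def read_label_table(path: PathLike) -> dict[int, str]:
    """Two-column (id, name) delimited text; tab or comma; optional header."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such label table: {path}")
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    table: dict[int, str] = {}
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    for i, row in enumerate(rows):
        if not row or not "".join(row).strip():
            continue
        row = [c.strip() for c in row]
        try:
            label_id = int(row[0])
        except ValueError:
            if i == 0:
                continue  # header row
            raise FormatError(f"{path}:{i + 1}: non-integer label id {row[0]!r}")
        if len(row) < 2 or not row[1]:
            raise FormatError(f"{path}:{i + 1}: missing region name")
        table[label_id] = row[1]
    if not table:
        raise FormatError(f"{path}: empty label table")
    return table


def write_label_table(path: PathLike, table: Mapping[int, str]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for label_id in sorted(table):
            writer.writerow([int(label_id), table[label_id]])
    return path


def read_atlas(volume_path: PathLike, table_path: PathLike) -> ParcellationAtlas:
    """Read a parcellation volume plus its label table.

    Raises :class:`MissingLabelError` naming any in-volume label absent from
    the table.
    """
    data, grid = read_volume(volume_path, expect_ndim=3)
    table = read_label_table(table_path)
    return ParcellationAtlas(grid=grid, labels=data, label_table=table)
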