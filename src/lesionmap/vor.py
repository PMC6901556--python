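"""Voxelwise odds-ratio (VOR) maps contrasting the two outcome groups.

At each voxel the 2x2 table is (V_P, N_P - V_P) vs (V_C, N_C - V_C), where
V_* counts group lesions with thresholded connectivity there and N_* is the
group size. The odds ratio

    VOR = V_P * (N_C - V_C) / (V_C * (N_P - V_P))

is undefined when V_C = 0 or V_P = N_P; the ``exclude`` policy (default)
flags such voxels invalid, the ``haldane`` policy adds 0.5 to all four
cells first (Haldane-Anscombe continuity correction). Direction ``C_vs_P``
swaps the group roles wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError
from .imaging_io import StatMap, VolumeGrid, require_compatible
from .maps import GroupSumMap

DIRECTIONS = ("P_vs_C", "C_vs_P")
ZERO_CELL_POLICIES = ("exclude", "haldane")

#: "At least twice as likely" cutoff for likelihood maps.
DEFAULT_VOR_CUTOFF = 2.0


@dataclass(frozen=True)
class VORCell:
    """One voxel's 2x2 counts."""

    v_p: int
    v_c: int
    n_p: int
    n_c: int

    def __post_init__(self):
        if self.n_p < 1 or self.n_c < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 <= self.v_p <= self.n_p):
            raise ValueError(f"V_P={self.v_p} outside [0, N_P={self.n_p}]")
        if not (0 <= self.v_c <= self.n_c):
            raise ValueError(f"V_C={self.v_c} outside [0, N_C={self.n_c}]")


@dataclass(frozen=True)
class VORMap:
    grid: VolumeGrid
    values: np.ndarray
    valid: np.ndarray
    direction: str
    zero_cell_policy: str
    n_p: int
    n_c: int
    provenance: tuple = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid).astype(bool)
        if values.shape != self.grid.shape or valid.shape != self.grid.shape:
            raise GridMismatchError("VOR map arrays off-grid")
        values = values.copy()
        values[~valid] = np.nan
        if valid.any() and np.nanmin(values[valid]) < 0:
            raise ValueError("VOR values must be >= 0 wherever valid")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.zero_cell_policy not in ZERO_CELL_POLICIES:
            raise ValueError(f"policy must be one of {ZERO_CELL_POLICIES}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)
        object.__setattr__(self, "provenance", tuple(self.provenance))
        self.values.setflags(write=False)
        self.valid.setflags(write=False)


def vor_cell(cell: VORCell, policy: str = "exclude"):
    """Odds ratio for one voxel; ``None`` when invalid under ``exclude``."""
    if policy not in ZERO_CELL_POLICIES:
        raise ValueError(f"policy must be one of {ZERO_CELL_POLICIES}")
    v_p, v_c, n_p, n_c = cell.v_p, cell.v_c, cell.n_p, cell.n_c
    if policy == "haldane":
        return ((v_p + 0.5) * (n_c - v_c + 0.5)) / ((v_c + 0.5) * (n_p - v_p + 0.5))
    if v_c == 0 or v_p == n_p:
        return None
    return (v_p * (n_c - v_c)) / (v_c * (n_p - v_p))


def vor_map(sum_p: GroupSumMap, sum_c: GroupSumMap,
            direction: str = "P_vs_C", policy: str = "exclude") -> VORMap:
    """Vectorized per-voxel odds ratio from the two group sum maps.

    Group sizes are read from the GroupSumMap fields, never from config;
    ``direction="C_vs_P"`` swaps the roles of the two groups exactly.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if sum_p.group_label != "P" or sum_c.group_label != "C":
        raise ValueError("vor_map expects (P sum map, C sum map) in that order")
    require_compatible(sum_p.grid, sum_c.grid, "vor_map inputs")
    grid = sum_p.grid

    if direction == "P_vs_C":
        v_num, n_num = sum_p.values.astype(float), float(sum_p.group_size)
        v_den, n_den = sum_c.values.astype(float), float(sum_c.group_size)
    else:
        v_num, n_num = sum_c.values.astype(float), float(sum_c.group_size)
        v_den, n_den = sum_p.values.astype(float), float(sum_p.group_size)

    if policy == "haldane":
        values = ((v_num + 0.5) * (n_den - v_den + 0.5)) / (
            (v_den + 0.5) * (n_num - v_num + 0.5))
        valid = np.ones(grid.shape, dtype=bool)
    elif policy == "exclude":
        denom = v_den * (n_num - v_num)
        valid = denom > 0
        values = np.full(grid.shape, np.nan)
        values[valid] = (v_num[valid] * (n_den - v_den[valid])) / denom[valid]
    else:
        raise ValueError(f"policy must be one of {ZERO_CELL_POLICIES}")

    return VORMap(
        grid=grid, values=values, valid=valid, direction=direction,
        zero_cell_policy=policy,
        n_p=sum_p.group_size, n_c=sum_c.group_size,
        provenance=(f"vor_map(direction={direction}, policy={policy}, "
                    f"N_P={sum_p.group_size}, N_C={sum_c.group_size})",),
    )


def likelihood_map(vor: VORMap, cutoff: float = DEFAULT_VOR_CUTOFF) -> StatMap:
    """Binary map of voxels "at least ``cutoff`` times as likely": VOR >= cutoff."""
    with np.errstate(invalid="ignore"):
        hit = vor.values >= cutoff
    out = np.where(vor.valid & hit, 1.0, 0.0)
    return StatMap(
        grid=vor.grid, values=out, kind="binary",
        valid=np.ones(vor.grid.shape, dtype=bool),
        provenance=vor.provenance + (f"likelihood_map(cutoff={cutoff})",),
    )
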