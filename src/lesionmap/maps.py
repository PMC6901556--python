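"""Map algebra on binarized connectivity masks: thresholding, group
summation, and Dice overlap with a label-permutation group comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectivity import TAILS
from .errors import (
    GridMismatchError,
    KindError,
    UndefinedDiceError,
)
from .imaging_io import LesionMask, StatMap, VolumeGrid, require_compatible


def threshold_binarize(t_map: StatMap, t_threshold: float,
                       tail: str = "two") -> StatMap:
    """1 where the (inclusive) tail condition holds at a valid voxel, else 0.

    tail: "two" -> |t| >= thr; "positive" -> t >= thr; "negative" -> t <= -thr.
    Invalid voxels always map to 0 but stay flagged invalid.
    """
    if t_map.kind != "t":
        raise KindError(f"threshold_binarize expects a t map, got {t_map.kind!r}")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    t = t_map.values
    with np.errstate(invalid="ignore"):
        if tail == "two":
            hit = np.abs(t) >= t_threshold
        elif tail == "positive":
            hit = t >= t_threshold
        else:
            hit = t <= -t_threshold
    out = np.where(t_map.valid & hit, 1.0, 0.0)
    return StatMap(
        grid=t_map.grid, values=out, kind="binary",
        valid=np.ones(t_map.grid.shape, dtype=bool),
        provenance=t_map.provenance + (f"threshold_binarize(t={t_threshold}, tail={tail})",),
    )


@dataclass(frozen=True)
class GroupSumMap:
    """Voxelwise count of binarized maps from one outcome group."""

    grid: VolumeGrid
    values: np.ndarray
    group_label: str
    group_size: int

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise GridMismatchError("sum map off-grid")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("sum map must be integer-valued")
            values = np.round(values).astype(np.int32)
        if self.group_label not in ("P", "C"):
            raise ValueError("group_label must be 'P' or 'C'")
        if values.min() < 0 or values.max() > self.group_size:
            raise ValueError(
                f"sum values must lie in [0, group_size={self.group_size}]"
            )
        object.__setattr__(self, "values", values)
        self.values.setflags(write=False)


def sum_maps(binary_maps: Sequence[StatMap], group_label: str) -> GroupSumMap:
    """Voxelwise count of maps equal to 1; group_size = number of maps."""
    if not binary_maps:
        raise ValueError("sum_maps needs at least one map")
    grid = binary_maps[0].grid
    total = np.zeros(grid.shape, dtype=np.int32)
    for m in binary_maps:
        if m.kind != "binary":
            raise KindError(f"sum_maps expects binary maps, got {m.kind!r}")
        require_compatible(grid, m.grid, "sum_maps inputs")
        total += np.nan_to_num(m.values, nan=0.0).astype(np.int32)
    return GroupSumMap(grid=grid, values=total, group_label=group_label,
                       group_size=len(binary_maps))


# ---------------------------------------------------------------------------
# Dice overlap


def dice_index(a: np.ndarray, b: np.ndarray) -> float:
    """2*|A∩B| / (|A| + |B|) on voxel counts."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise GridMismatchError("dice_index inputs have different shapes")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedDiceError("Dice of two empty masks is undefined")
    overlap = int((a & b).sum())
    return 2.0 * overlap / (na + nb)


def pairwise_dice(masks: Sequence[LesionMask]):
    """All unordered pair Dice values within one group.

    Returns ``(matrix, mean, sd, ids)``; the matrix has 1.0 on the diagonal.
    With a single pair the sample SD is reported as 0.
    """
    if len(masks) < 2:
        raise ValueError("pairwise_dice needs at least 2 masks")
    grid = masks[0].grid
    for m in masks[1:]:
        require_compatible(grid, m.grid, "pairwise_dice inputs")
    n = len(masks)
    matrix = np.eye(n)
    values = []
    for i in range(n):
        for j in range(i + 1, n):
            d = dice_index(masks[i].voxels, masks[j].voxels)
            matrix[i, j] = matrix[j, i] = d
            values.append(d)
    values = np.asarray(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    ids = [m.subject_id for m in masks]
    return matrix, mean, sd, ids


def _mean_pairwise_dice(voxel_arrays: Sequence[np.ndarray]) -> float:
    vals = [
        dice_index(voxel_arrays[i], voxel_arrays[j])
        for i in range(len(voxel_arrays))
        for j in range(i + 1, len(voxel_arrays))
    ]
    return float(np.mean(vals))


def compare_group_dice(masks_p: Sequence[LesionMask],
                       masks_c: Sequence[LesionMask],
                       n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for the difference in mean within-group Dice.

    Pairwise Dice values within a group are not independent, so a two-sample
    t-test over them would be invalid; instead group labels are shuffled over
    the pooled masks (group sizes preserved) and the absolute difference of
    within-group mean pairwise Dice is recomputed per shuffle.
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if len(masks_p) < 2 or len(masks_c) < 2:
        raise ValueError("each group needs >= 2 masks")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pooled = [m.voxels for m in masks_p] + [m.voxels for m in masks_c]
    n_p = len(masks_p)
    observed = abs(_mean_pairwise_dice(pooled[:n_p]) - _mean_pairwise_dice(pooled[n_p:]))
    rng = np.random.default_rng(seed)
    n_total = len(pooled)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        g1 = [pooled[i] for i in perm[:n_p]]
        g2 = [pooled[i] for i in perm[n_p:]]
        stat = abs(_mean_pairwise_dice(g1) - _mean_pairwise_dice(g2))
        if stat >= observed - 1e-15:
            hits += 1
    return (1 + hits) / (1 + n_perm)
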