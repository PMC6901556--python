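"""Seed-based connectivity of one lesion mask in a normative cohort.

The pipeline per lesion is: mean time course over the mask (per subject) ->
Pearson r against every brain voxel -> Fisher z -> one-sample t across
subjects -> threshold/binarize. The across-subject one-sample t-test is the
default r-to-t construction; a per-map parametric conversion
``t = r*sqrt(n-2)/sqrt(1-r^2)`` is available as ``mode="single_map"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSeedError,
    EmptyMaskError,
    GridMismatchError,
    InsufficientSubjectsError,
)
from .imaging_io import LesionMask, StatMap, VolumeGrid, require_compatible

#: Whole-brain Bonferroni-corrected threshold adopted for binarization.
DEFAULT_T_THRESHOLD = 5.1

#: r values are clipped to +/- (1 - R_CLIP_EPS) before atanh.
R_CLIP_EPS = 1e-7

TAILS = ("two", "positive", "negative")


@dataclass(frozen=True)
class ConnectomeCohort:
    """Per-subject 4-D time-series volumes plus a shared brain mask."""

    grid: VolumeGrid
    subjects: Sequence[np.ndarray]
    brain_mask: np.ndarray

    def __post_init__(self):
        subjects = tuple(np.asarray(s) for s in self.subjects)
        if not subjects:
            raise ValueError("cohort needs at least one subject")
        n_t = subjects[0].shape[-1]
        for s in subjects:
            if s.ndim != 4 or s.shape[:3] != self.grid.shape:
                raise GridMismatchError("subject volume off-grid or not 4-D")
            if s.shape[-1] != n_t:
                raise ValueError("subjects disagree on n_timepoints")
        if n_t < 4:
            raise ValueError("n_timepoints must be >= 4")
        mask = np.asarray(self.brain_mask).astype(bool)
        if mask.shape != self.grid.shape:
            raise GridMismatchError("brain mask off-grid")
        if not mask.any():
            raise EmptyMaskError("brain mask is empty")
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "brain_mask", mask)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_timepoints(self) -> int:
        return int(self.subjects[0].shape[-1])


@dataclass(frozen=True)
class SeedTimecourse:
    values: np.ndarray
    source_n_voxels: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or not np.isfinite(values).all():
            raise ValueError("seed time course must be a finite 1-D series")
        object.__setattr__(self, "values", values)
        self.values.setflags(write=False)

    @property
    def variance(self) -> float:
        return float(np.var(self.values, ddof=1))


def extract_seed_timecourse(subject: np.ndarray, mask: LesionMask,
                            brain_mask: np.ndarray) -> SeedTimecourse:
    """Unweighted mean signal over mask ∩ brain_mask at each timepoint."""
    subject = np.asarray(subject)
    if subject.shape[:3] != mask.grid.shape:
        raise GridMismatchError("subject and mask are on different grids")
    support = mask.voxels.astype(bool) & np.asarray(brain_mask).astype(bool)
    n = int(support.sum())
    if n == 0:
        raise EmptyMaskError(
            f"mask '{mask.subject_id}' does not intersect the brain mask"
        )
    series = subject[support].mean(axis=0)
    tc = SeedTimecourse(values=series, source_n_voxels=n)
    if tc.variance == 0.0:
        raise DegenerateSeedError(
            f"seed for '{mask.subject_id}' has zero variance"
        )
    return tc


def subject_r_map(subject: np.ndarray, seed: SeedTimecourse,
                  brain_mask: np.ndarray, grid: VolumeGrid) -> StatMap:
    """Pearson r between the seed series and every brain-mask voxel series.

    Voxels with zero temporal variance are marked invalid; voxels outside
    the brain mask are invalid by construction.
    """
    if seed.variance == 0.0:
        raise DegenerateSeedError("seed has zero variance")
    mask = np.asarray(brain_mask).astype(bool)
    X = np.asarray(subject, dtype=float)[mask]          # (n_vox, n_t)
    s = seed.values - seed.values.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc ** 2).sum(axis=1))
    s_norm = np.sqrt((s ** 2).sum())
    ok = x_norm > 0
    r_flat = np.full(X.shape[0], np.nan)
    r_flat[ok] = (Xc[ok] @ s) / (x_norm[ok] * s_norm)
    r_flat = np.clip(r_flat, -1.0, 1.0)  # guard float dust past +/-1

    values = np.full(grid.shape, np.nan)
    valid = np.zeros(grid.shape, dtype=bool)
    values[mask] = r_flat
    valid[mask] = ok
    return StatMap(grid=grid, values=values, kind="r", valid=valid,
                   provenance=(f"subject_r_map(seed_voxels={seed.source_n_voxels})",))


def fisher_z(r_map: StatMap) -> StatMap:
    """Elementwise atanh; |r| = 1 clipped to 1 - 1e-7 first. Validity propagates."""
    if r_map.kind != "r":
        raise ValueError(f"fisher_z expects an r map, got kind={r_map.kind!r}")
    r = np.clip(r_map.values, -(1.0 - R_CLIP_EPS), 1.0 - R_CLIP_EPS)
    with np.errstate(invalid="ignore"):
        z = np.arctanh(r)
    return StatMap(grid=r_map.grid, values=z, kind="z", valid=r_map.valid,
                   provenance=r_map.provenance + ("fisher_z",))


def group_t_map(z_maps: Sequence[StatMap]) -> StatMap:
    """One-sample t across subjects of z values against 0, per voxel.

    t = mean(z) * sqrt(n) / sd(z), sample sd (n-1). Voxels valid only where
    every subject is valid. sd = 0 with mean = 0 gives t = 0; sd = 0 with
    mean != 0 is flagged invalid (kept out of downstream sums rather than
    set to +/- infinity).
    """
    if len(z_maps) < 3:
        raise InsufficientSubjectsError(
            f"group t-test needs >= 3 subjects, got {len(z_maps)}"
        )
    grid = z_maps[0].grid
    for m in z_maps[1:]:
        require_compatible(grid, m.grid, "group_t_map inputs")
    n = len(z_maps)
    z = np.stack([m.values for m in z_maps])
    valid = np.logical_and.reduce([m.valid for m in z_maps])

    mean = np.zeros(grid.shape)
    sd = np.zeros(grid.shape)
    mean[valid] = z[:, valid].mean(axis=0)
    sd[valid] = z[:, valid].std(axis=0, ddof=1)

    # sd of n identical values is not exactly 0 in floats (mean rounding),
    # so "zero spread" is judged relative to the mean's magnitude
    sd_zero = sd <= 1e-12 * np.maximum(np.abs(mean), np.finfo(float).tiny)
    t = np.full(grid.shape, np.nan)
    regular = valid & ~sd_zero
    t[regular] = mean[regular] * np.sqrt(n) / sd[regular]
    null = valid & sd_zero & (mean == 0)
    t[null] = 0.0
    degenerate = valid & sd_zero & (mean != 0)
    out_valid = (regular | null) & ~degenerate
    prov = z_maps[0].provenance + (
        f"group_t_map(n={n}, degenerate_voxels={int(degenerate.sum())})",)
    return StatMap(grid=grid, values=t, kind="t", valid=out_valid, provenance=prov)


def single_map_t(r_map: StatMap, n_timepoints: int) -> StatMap:
    """Per-map parametric conversion t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if r_map.kind != "r":
        raise ValueError("single_map_t expects an r map")
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3")
    r = np.clip(r_map.values, -(1.0 - R_CLIP_EPS), 1.0 - R_CLIP_EPS)
    with np.errstate(invalid="ignore"):
        t = r * np.sqrt(n_timepoints - 2) / np.sqrt(1.0 - r ** 2)
    return StatMap(grid=r_map.grid, values=t, kind="t", valid=r_map.valid,
                   provenance=r_map.provenance + (f"single_map_t(n={n_timepoints})",))


def lesion_t_map(cohort: ConnectomeCohort, mask: LesionMask,
                 mode: str = "group_ttest") -> StatMap:
    """t-map of seed connectivity for one lesion over the whole cohort."""
    require_compatible(cohort.grid, mask.grid, f"lesion '{mask.subject_id}'")
    if mode == "group_ttest":
        z_maps = []
        for subject in cohort.subjects:
            seed = extract_seed_timecourse(subject, mask, cohort.brain_mask)
            r = subject_r_map(subject, seed, cohort.brain_mask, cohort.grid)
            z_maps.append(fisher_z(r))
        return group_t_map(z_maps)
    if mode == "single_map":
        # mean z across subjects, converted once with the temporal df
        z_sum = None
        valid = None
        for subject in cohort.subjects:
            seed = extract_seed_timecourse(subject, mask, cohort.brain_mask)
            r = subject_r_map(subject, seed, cohort.brain_mask, cohort.grid)
            z = fisher_z(r)
            z_sum = z.values if z_sum is None else np.nansum([z_sum, z.values], axis=0)
            valid = z.valid if valid is None else (valid & z.valid)
        z_mean = np.where(valid, z_sum / cohort.n_subjects, np.nan)
        r_mean = np.tanh(z_mean)
        r_back = StatMap(grid=cohort.grid, values=r_mean, kind="r", valid=valid,
                         provenance=(f"mean_z_r_map(n={cohort.n_subjects})",))
        return single_map_t(r_back, cohort.n_timepoints)
    raise ValueError(f"unknown r_to_t mode {mode!r}")


def lesion_network_map(cohort: ConnectomeCohort, mask: LesionMask,
                       t_threshold: float = DEFAULT_T_THRESHOLD,
                       tail: str = "two", mode: str = "group_ttest") -> StatMap:
    """Thresholded, binarized connectivity map for one lesion."""
    from .maps import threshold_binarize  # local import: maps also imports us

    t_map = lesion_t_map(cohort, mask, mode=mode)
    out = threshold_binarize(t_map, t_threshold=t_threshold, tail=tail)
    return out.with_provenance(f"lesion={mask.subject_id}")


def bonferroni_critical_t(n_voxels: int, df: int, alpha: float = 0.05,
                          tail: str = "two") -> float:
    """Critical t for family-wise ``alpha`` over ``n_voxels`` comparisons."""
    if n_voxels < 1 or df < 1:
        raise ValueError("n_voxels and df must be positive")
    per_voxel = alpha / n_voxels
    if tail == "two":
        per_voxel /= 2.0
    return float(stats.t.isf(per_voxel, df))
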