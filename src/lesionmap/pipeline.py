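"""Config-driven end-to-end orchestration.

masks + cohort + atlases in; per-lesion binary maps, group sum maps, VOR
maps (both directions), likelihood maps, a Dice report, and one region
table per atlas out. A run manifest records every parameter and input
checksum; any stage failure aborts with the stage name and the offending
input id, and the manifest marks the run incomplete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import atlas_summary, maps, vor
from .connectivity import (
    DEFAULT_T_THRESHOLD,
    ConnectomeCohort,
    TAILS,
    lesion_network_map,
)
from .errors import (
    ConfigError,
    EmptyMaskError,
    GridMismatchError,
    LesionMapError,
    PipelineStageError,
)
from .imaging_io import (
    LesionMask,
    check_grid_compatible,
    read_atlas,
    read_mask,
    read_volume,
    write_volume,
)
from .vor import DEFAULT_VOR_CUTOFF

log = logging.getLogger("lesionmap")

_OUTCOME_ALIASES = {"P": "P", "C": "C", "SF": "P", "NSF": "C"}


@dataclass(frozen=True)
class AtlasSpec:
    name: str
    volume: Path
    table: Path


@dataclass(frozen=True)
class PipelineConfig:
    cohort_dir: Path
    mask_manifest: Path
    output_dir: Path
    atlases: tuple[AtlasSpec, ...] = ()
    t_threshold: float = DEFAULT_T_THRESHOLD
    tail: str = "two"
    zero_cell_policy: str = "exclude"
    vor_cutoff: float = DEFAULT_VOR_CUTOFF
    r_to_t_mode: str = "group_ttest"
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self):
        if self.tail not in TAILS:
            raise ConfigError(f"tail must be one of {TAILS}")
        if self.zero_cell_policy not in vor.ZERO_CELL_POLICIES:
            raise ConfigError(
                f"zero_cell_policy must be one of {vor.ZERO_CELL_POLICIES}")
        if self.r_to_t_mode not in ("group_ttest", "single_map"):
            raise ConfigError("r_to_t_mode must be 'group_ttest' or 'single_map'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except Exception as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            atlases = tuple(
                AtlasSpec(name=str(a["name"]), volume=resolve(a["volume"]),
                          table=resolve(a["table"]))
                for a in raw.get("atlases", []) or []
            )
            return cls(
                cohort_dir=resolve(raw["cohort_dir"]),
                mask_manifest=resolve(raw["mask_manifest"]),
                output_dir=resolve(raw["output_dir"]),
                atlases=atlases,
                t_threshold=float(raw.get("t_threshold", DEFAULT_T_THRESHOLD)),
                tail=str(raw.get("tail", "two")),
                zero_cell_policy=str(raw.get("zero_cell_policy", "exclude")),
                vor_cutoff=float(raw.get("vor_cutoff", DEFAULT_VOR_CUTOFF)),
                r_to_t_mode=str(raw.get("r_to_t_mode", "group_ttest")),
                n_perm=int(raw.get("n_perm", 999)),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"config {path} missing required key {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "cohort_dir": str(self.cohort_dir),
            "mask_manifest": str(self.mask_manifest),
            "output_dir": str(self.output_dir),
            "atlases": [{"name": a.name, "volume": str(a.volume),
                         "table": str(a.table)} for a in self.atlases],
            "t_threshold": self.t_threshold,
            "tail": self.tail,
            "zero_cell_policy": self.zero_cell_policy,
            "vor_cutoff": self.vor_cutoff,
            "r_to_t_mode": self.r_to_t_mode,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Input loading


def read_mask_manifest(path) -> list[tuple[Path, str, str]]:
    """TSV of (path, outcome); returns (resolved path, lesion id, P/C label)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"mask manifest not found: {path}")
    entries = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ConfigError(f"{path}:{i + 1}: expected 'path<TAB>outcome'")
        if i == 0 and parts[0].lower() in ("path", "file", "mask"):
            continue
        outcome = _OUTCOME_ALIASES.get(parts[1].strip().upper())
        if outcome is None:
            raise ConfigError(
                f"{path}:{i + 1}: outcome must be P/C (or SF/NSF), got {parts[1]!r}")
        mask_path = Path(parts[0])
        if not mask_path.is_absolute():
            mask_path = path.parent / mask_path
        entries.append((mask_path, mask_path.name.split(".nii")[0], outcome))
    if not entries:
        raise ConfigError(f"mask manifest {path} lists no masks")
    return entries


def load_cohort(cohort_dir) -> ConnectomeCohort:
    """Directory of ``subj_*.nii[.gz]`` 4-D volumes plus ``brain_mask.nii[.gz]``."""
    cohort_dir = Path(cohort_dir)
    subj_paths = sorted(p for p in cohort_dir.glob("subj_*.nii*"))
    if not subj_paths:
        raise ConfigError(f"no subj_*.nii volumes under {cohort_dir}")
    subjects = []
    grid = None
    for p in subj_paths:
        data, g = read_volume(p, expect_ndim=4)
        if grid is None:
            grid = g
        elif not check_grid_compatible(grid, g):
            raise GridMismatchError(f"cohort subject off-grid: {p}")
        subjects.append(data)
    mask_candidates = sorted(cohort_dir.glob("brain_mask.nii*"))
    if mask_candidates:
        mask_data, g = read_volume(mask_candidates[0], expect_ndim=3)
        if not check_grid_compatible(grid, g):
            raise GridMismatchError("brain mask off-grid")
        brain_mask = mask_data > 0
    else:
        brain_mask = np.ones(grid.shape, dtype=bool)
    return ConnectomeCohort(grid=grid, subjects=subjects, brain_mask=brain_mask)


def load_masks(config: PipelineConfig) -> list[LesionMask]:
    entries = read_mask_manifest(config.mask_manifest)
    return [read_mask(p, subject_id=lesion_id, outcome=outcome)
            for p, lesion_id, outcome in entries]


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)
    n_masks_p: int = 0
    n_masks_c: int = 0
    n_subjects: int = 0

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Grid compatibility across every input, plus group-size sanity.

    Report contract: never raises for data problems — callers inspect
    ``report.ok``; ``run_pipeline`` refuses on a failing report.
    """
    report = ValidationReport()
    try:
        cohort = load_cohort(config.cohort_dir)
        report.n_subjects = cohort.n_subjects
    except LesionMapError as exc:
        report.problems.append(f"cohort: {exc}")
        cohort = None

    try:
        entries = read_mask_manifest(config.mask_manifest)
    except LesionMapError as exc:
        report.problems.append(f"mask manifest: {exc}")
        entries = []

    for p, lesion_id, outcome in entries:
        try:
            mask = read_mask(p, subject_id=lesion_id, outcome=outcome)
        except EmptyMaskError:
            report.problems.append(f"mask '{lesion_id}' is empty: {p}")
            continue
        except LesionMapError as exc:
            report.problems.append(f"mask '{lesion_id}': {exc}")
            continue
        if cohort is not None and not check_grid_compatible(cohort.grid, mask.grid):
            report.problems.append(f"mask '{lesion_id}' off-grid: {p}")
            continue
        if outcome == "P":
            report.n_masks_p += 1
        else:
            report.n_masks_c += 1

    if entries and report.n_masks_p == 0:
        report.problems.append("no masks in outcome group P")
    if entries and report.n_masks_c == 0:
        report.problems.append("no masks in outcome group C")

    for spec in config.atlases:
        try:
            atlas = read_atlas(spec.volume, spec.table)
        except LesionMapError as exc:
            report.problems.append(f"atlas '{spec.name}': {exc}")
            continue
        if cohort is not None and not check_grid_compatible(cohort.grid, atlas.grid):
            report.problems.append(f"atlas '{spec.name}' off-grid: {spec.volume}")
    return report


# ---------------------------------------------------------------------------
# Run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_sidecar(path: Path, record: dict) -> None:
    with open(path, "w") as fh:
        for key in sorted(record):
            fh.write(f"{key}\t{record[key]}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths.

    Deterministic given config + seed: rerunning over the same output
    directory reproduces bit-identical artifacts.
    """
    report = validate_inputs(config)
    if not report.ok:
        raise ConfigError("input validation failed:\n  " + "\n  ".join(report.problems))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "status": "incomplete",
                      "inputs": {}, "outputs": []}
    manifest_path = out / "run_manifest.json"

    def checkpoint():
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    checkpoint()
    outputs: dict = {"manifest": manifest_path}
    try:
        cohort = load_cohort(config.cohort_dir)
        masks = load_masks(config)
        for p, lesion_id, _ in read_mask_manifest(config.mask_manifest):
            manifest["inputs"][lesion_id] = _sha256(p)

        # stage 1: per-lesion binary connectivity maps
        binary_maps: dict[str, list] = {"P": [], "C": []}
        lesion_dir = out / "lesion_maps"
        per_lesion_paths = []
        for mask in masks:
            try:
                bmap = lesion_network_map(cohort, mask,
                                          t_threshold=config.t_threshold,
                                          tail=config.tail,
                                          mode=config.r_to_t_mode)
            except LesionMapError as exc:
                raise PipelineStageError("lesion_network_map", mask.subject_id, exc)
            n_on = int(np.nansum(bmap.values))
            log.info("lesion %s: %d suprathreshold voxels (t=%.2f, %s tail)",
                     mask.subject_id, n_on, config.t_threshold, config.tail)
            if n_on == 0:
                log.warning("lesion %s produced an EMPTY thresholded map",
                            mask.subject_id)
            p = write_volume(lesion_dir / f"{mask.subject_id}_binary.nii",
                             np.nan_to_num(bmap.values), bmap.grid, dtype=np.uint8)
            _write_sidecar(lesion_dir / f"{mask.subject_id}_binary.provenance.tsv",
                           {"t_threshold": config.t_threshold, "tail": config.tail,
                            "r_to_t_mode": config.r_to_t_mode,
                            "n_cohort_subjects": cohort.n_subjects,
                            "suprathreshold_voxels": n_on})
            binary_maps[mask.outcome].append(bmap)
            per_lesion_paths.append(p)
        outputs["lesion_maps"] = per_lesion_paths

        # stage 2: group sums
        sum_p = maps.sum_maps(binary_maps["P"], "P")
        sum_c = maps.sum_maps(binary_maps["C"], "C")
        outputs["sum_P"] = write_volume(out / "sum_P.nii", sum_p.values,
                                        sum_p.grid, dtype=np.int16)
        outputs["sum_C"] = write_volume(out / "sum_C.nii", sum_c.values,
                                        sum_c.grid, dtype=np.int16)
        log.info("sum maps: max_P=%d/%d max_C=%d/%d", sum_p.values.max(),
                 sum_p.group_size, sum_c.values.max(), sum_c.group_size)

        # stage 3: VOR maps, both directions, plus likelihood maps
        vor_maps = {}
        for direction in vor.DIRECTIONS:
            vmap = vor.vor_map(sum_p, sum_c, direction=direction,
                               policy=config.zero_cell_policy)
            vor_maps[direction] = vmap
            stem = f"vor_{direction}"
            outputs[stem] = write_volume(out / f"{stem}.nii",
                                         np.nan_to_num(vmap.values), vmap.grid,
                                         dtype=np.float32)
            outputs[stem + "_valid"] = write_volume(
                out / f"{stem}_valid.nii", vmap.valid.astype(np.uint8),
                vmap.grid, dtype=np.uint8)
            _write_sidecar(out / f"{stem}.provenance.tsv",
                           {"direction": direction,
                            "zero_cell_policy": config.zero_cell_policy,
                            "vor_cutoff": config.vor_cutoff,
                            "N_P": vmap.n_p, "N_C": vmap.n_c})
            lmap = vor.likelihood_map(vmap, cutoff=config.vor_cutoff)
            outputs[f"likelihood_{direction}"] = write_volume(
                out / f"likelihood_{direction}.nii",
                np.nan_to_num(lmap.values), lmap.grid, dtype=np.uint8)

        # stage 4: Dice report
        dice_path = out / "dice_report.tsv"
        masks_p = [m for m in masks if m.outcome == "P"]
        masks_c = [m for m in masks if m.outcome == "C"]
        _, mean_p, sd_p, _ = maps.pairwise_dice(masks_p)
        _, mean_c, sd_c, _ = maps.pairwise_dice(masks_c)
        p_value = maps.compare_group_dice(masks_p, masks_c,
                                          n_perm=config.n_perm, seed=config.seed)
        with open(dice_path, "w") as fh:
            fh.write("group\tn_masks\tmean_pairwise_dice\tsd_pairwise_dice\n")
            fh.write(f"P\t{len(masks_p)}\t{mean_p:.6g}\t{sd_p:.6g}\n")
            fh.write(f"C\t{len(masks_c)}\t{mean_c:.6g}\t{sd_c:.6g}\n")
            fh.write(f"# permutation p (n_perm={config.n_perm}, "
                     f"seed={config.seed}): {p_value:.6g}\n")
        outputs["dice_report"] = dice_path

        # stage 5: region tables
        for spec in config.atlases:
            atlas = read_atlas(spec.volume, spec.table)
            table = atlas_summary.dual_direction_table(
                vor_maps["P_vs_C"], vor_maps["C_vs_P"], atlas)
            table_path = out / f"regions_{spec.name}.tsv"
            atlas_summary.write_region_table(table_path, table)
            outputs[f"regions_{spec.name}"] = table_path

        manifest["outputs"] = sorted(
            str(Path(p).relative_to(out))
            for v in outputs.values()
            for p in (v if isinstance(v, list) else [v]))
        manifest["status"] = "complete"
        checkpoint()
    except Exception:
        manifest["status"] = "incomplete"
        checkpoint()
        raise
    return outputs
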