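"""Desk-scale synthetic normative cohort with planted ground truth.

Generative model: each latent network k has a compact binary spatial support
and, per subject s, an independent standard-normal time course c_{k,s}(t).
A subject's voxel series is

    Y_s(v, t) = sum_k loading_k * support_k(v) * c_{k,s}(t) + eps,
    eps ~ N(0, noise_sd^2), i.i.d.

so the population correlation between two voxels sharing exactly one network
with loading a is a^2 / (a^2 + noise_sd^2) — a closed form every downstream
stage can be tested against. One master seed drives everything; per-subject
streams are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .connectivity import ConnectomeCohort
from .errors import GeometryError
from .imaging_io import (
    LesionMask,
    ParcellationAtlas,
    VolumeGrid,
    write_label_table,
    write_volume,
)


def _default_affine(voxel_size: float = 2.0) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


@dataclass(frozen=True)
class NetworkSpec:
    """A latent network: binary spatial support + signal loading."""

    support: np.ndarray
    loading: float = 1.0
    center: Optional[tuple[int, int, int]] = None
    radius: Optional[float] = None

    def __post_init__(self):
        support = np.asarray(self.support).astype(bool)
        if support.ndim != 3 or not support.any():
            raise GeometryError("network support must be a nonempty 3-D mask")
        if self.loading <= 0:
            raise ValueError("loading must be > 0")
        object.__setattr__(self, "support", support)
        self.support.setflags(write=False)

    @property
    def n_voxels(self) -> int:
        return int(self.support.sum())


@dataclass(frozen=True)
class CohortConfig:
    grid_shape: tuple[int, int, int]
    n_subjects: int
    n_timepoints: int
    networks: tuple[NetworkSpec, ...]
    noise_sd: float = 0.5
    seed: int = 0
    voxel_size: float = 2.0

    def __post_init__(self):
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "networks", tuple(self.networks))
        for net in self.networks:
            if net.support.shape != self.grid_shape:
                raise GeometryError("network support shape != cohort grid shape")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.grid_shape, _default_affine(self.voxel_size))


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for a batch of planted lesions."""

    network_index: tuple[int, ...]            # per lesion
    expected_maps: tuple[np.ndarray, ...]     # per lesion: assigned support
    lesion_ids: tuple[str, ...]
    lesion_n_voxels: tuple[int, ...]

    def expected_map_for(self, lesion_id: str) -> np.ndarray:
        return self.expected_maps[self.lesion_ids.index(lesion_id)]


def sphere_mask(grid_shape: Sequence[int], center: Sequence[int],
                radius: float) -> np.ndarray:
    """Axis-aligned voxel-lattice sphere: ||idx - center||_2 <= radius."""
    grid_shape = tuple(int(s) for s in grid_shape)
    idx = np.indices(grid_shape)
    d2 = sum((idx[i] - int(center[i])) ** 2 for i in range(3))
    mask = d2 <= float(radius) ** 2
    if not mask.any():
        raise GeometryError(f"sphere at {tuple(center)} r={radius} is empty on grid")
    return mask


def make_network_supports(grid_shape, k: int, geometry="random",
                          radius: float = 4.0, loading: float = 1.0,
                          seed: int = 0) -> list[NetworkSpec]:
    """Build k spherical network supports.

    ``geometry`` is either "random" (non-overlapping spheres of ``radius``
    placed by rejection sampling) or an explicit list of ``(center, radius)``
    pairs. Deterministic given ``seed``.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    specs: list[NetworkSpec] = []
    if geometry == "random":
        rng = np.random.default_rng(seed)
        lo = int(np.ceil(radius))
        his = [s - 1 - lo for s in grid_shape]
        if any(h < lo for h in his):
            raise GeometryError(f"radius {radius} does not fit inside grid {grid_shape}")
        centers: list[np.ndarray] = []
        for _ in range(k):
            for _attempt in range(10_000):
                c = np.array([rng.integers(lo, h + 1) for h in his])
                if all(np.linalg.norm(c - p) > 2 * radius + 1 for p in centers):
                    centers.append(c)
                    break
            else:
                raise GeometryError(
                    f"could not place {k} disjoint spheres of radius {radius} "
                    f"on grid {grid_shape}"
                )
        geometry = [(tuple(int(x) for x in c), radius) for c in centers]
    for center, r in geometry:
        support = sphere_mask(grid_shape, center, r)
        specs.append(NetworkSpec(support=support, loading=loading,
                                 center=tuple(int(x) for x in center), radius=float(r)))
    return specs


def simulate_cohort(config: CohortConfig, return_latents: bool = False):
    """Simulate the cohort under the latent-network model.

    Returns a :class:`ConnectomeCohort` (brain mask = whole grid), or
    ``(cohort, latents)`` with ``latents[k, s, t]`` when ``return_latents``.
    """
    grid = config.grid
    n_net = len(config.networks)
    supports = np.stack([n.support for n in config.networks]) if n_net else None
    loadings = np.array([n.loading for n in config.networks])

    # one spawned stream per subject: adding subjects never perturbs earlier ones
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    subjects = []
    latents = np.zeros((n_net, config.n_subjects, config.n_timepoints))
    for s, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        courses = rng.standard_normal((n_net, config.n_timepoints))
        latents[:, s, :] = courses
        noise = rng.normal(0.0, config.noise_sd,
                           size=(*config.grid_shape, config.n_timepoints))
        signal = np.zeros_like(noise)
        if n_net:
            # support_k(v) * loading_k * c_k(t), summed over k
            signal = np.tensordot(
                supports.astype(float) * loadings[:, None, None, None],
                courses, axes=([0], [0]))
        subjects.append((signal + noise).astype(np.float32))

    brain_mask = np.ones(config.grid_shape, dtype=np.uint8)
    cohort = ConnectomeCohort(grid=grid, subjects=subjects, brain_mask=brain_mask)
    if return_latents:
        return cohort, latents
    return cohort


def plant_lesion_masks(networks: Sequence[NetworkSpec],
                       assignments: Sequence[tuple[int, str]],
                       lesion_radius: float = 1.0,
                       grid: Optional[VolumeGrid] = None,
                       seed: int = 0) -> tuple[list[LesionMask], PlantedTruth]:
    """Place one spherical lesion per (network index, outcome) assignment.

    Each lesion is centred on its network's centre (spheres from
    :func:`make_network_supports` record their geometry), guaranteeing
    containment; a lesion that does not fit raises :class:`GeometryError`.
    """
    if grid is None:
        shape = networks[0].support.shape
        grid = VolumeGrid(shape, _default_affine())
    masks: list[LesionMask] = []
    net_idx: list[int] = []
    expected: list[np.ndarray] = []
    ids: list[str] = []
    nvox: list[int] = []
    for i, (k, outcome) in enumerate(assignments):
        net = networks[k]
        if net.center is None:
            center = [int(round(c)) for c in
                      np.array(np.nonzero(net.support)).mean(axis=1)]
        else:
            center = list(net.center)
        vox = sphere_mask(grid.shape, center, lesion_radius)
        if not (vox <= net.support).all():
            raise GeometryError(
                f"lesion radius {lesion_radius} does not fit inside network {k}"
            )
        lesion_id = f"lesion{i:02d}_{outcome}"
        masks.append(LesionMask(grid=grid, voxels=vox.astype(np.uint8),
                                subject_id=lesion_id, outcome=outcome))
        net_idx.append(k)
        expected.append(net.support.copy())
        ids.append(lesion_id)
        nvox.append(int(vox.sum()))
    truth = PlantedTruth(network_index=tuple(net_idx),
                         expected_maps=tuple(expected),
                         lesion_ids=tuple(ids),
                         lesion_n_voxels=tuple(nvox))
    return masks, truth


def networks_atlas(networks: Sequence[NetworkSpec],
                   grid: VolumeGrid) -> ParcellationAtlas:
    """One atlas region per network support (label k+1); later networks win ties."""
    labels = np.zeros(grid.shape, dtype=np.int32)
    table = {}
    for k, net in enumerate(networks):
        labels[net.support] = k + 1
        table[k + 1] = f"network_{k + 1}"
    return ParcellationAtlas(grid=grid, labels=labels, label_table=table)


# ---------------------------------------------------------------------------
# Bundled default fixture


@dataclass(frozen=True)
class FixtureSpec:
    """Default desk-scale fixture: two disjoint networks, mixed assignments.

    Group C lesions preferentially occupy network 2 (3 of 4), group P
    network 1 (2 of 3), so the C-direction VOR map discriminates network 2
    with all four 2x2 cells nonzero there.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_subjects: int = 50
    n_timepoints: int = 60
    noise_sd: float = 0.5
    loading: float = 1.0
    network_geometry: tuple = (((6, 6, 6), 3.0), ((13, 13, 13), 3.0))
    assignments: tuple = ((0, "P"), (0, "P"), (1, "P"),
                          (1, "C"), (1, "C"), (1, "C"), (0, "C"))
    lesion_radius: float = 1.0
    seed: int = 0


def build_fixture(spec: FixtureSpec = FixtureSpec()):
    """Materialize the fixture in memory.

    Returns ``(cohort, masks, truth, atlas, networks, config)``.
    """
    networks = make_network_supports(spec.grid_shape, k=len(spec.network_geometry),
                                     geometry=list(spec.network_geometry),
                                     loading=spec.loading, seed=spec.seed)
    config = CohortConfig(grid_shape=spec.grid_shape, n_subjects=spec.n_subjects,
                          n_timepoints=spec.n_timepoints, networks=tuple(networks),
                          noise_sd=spec.noise_sd, seed=spec.seed)
    cohort = simulate_cohort(config)
    masks, truth = plant_lesion_masks(networks, spec.assignments,
                                      lesion_radius=spec.lesion_radius,
                                      grid=config.grid, seed=spec.seed)
    atlas = networks_atlas(networks, config.grid)
    return cohort, masks, truth, atlas, networks, config


def write_fixture(directory, spec: FixtureSpec = FixtureSpec()) -> dict:
    """Write the fixture as a file tree imaging_io can read back.

    Layout::

        cohort/subj_<s>.nii      4-D time series, float32
        cohort/brain_mask.nii
        masks/<lesion_id>.nii    binary
        masks/manifest.tsv       path <tab> outcome
        atlas/networks.nii + networks_labels.tsv
        truth.tsv                flat key-value ground-truth manifest

    Returns a dict of the paths written plus the in-memory objects.
    """
    directory = Path(directory)
    cohort, masks, truth, atlas, networks, config = build_fixture(spec)
    grid = config.grid

    cohort_dir = directory / "cohort"
    subj_paths = []
    for s, vol in enumerate(cohort.subjects):
        subj_paths.append(write_volume(cohort_dir / f"subj_{s:03d}.nii", vol, grid,
                                       dtype=np.float32))
    write_volume(cohort_dir / "brain_mask.nii", cohort.brain_mask, grid,
                 dtype=np.uint8)

    mask_dir = directory / "masks"
    mask_rows = []
    for mask in masks:
        p = write_volume(mask_dir / f"{mask.subject_id}.nii", mask.voxels, grid,
                         dtype=np.uint8)
        mask_rows.append((p, mask.outcome))
    manifest = mask_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("path\toutcome\n")
        for p, outcome in mask_rows:
            fh.write(f"{p.name}\t{outcome}\n")

    atlas_dir = directory / "atlas"
    write_volume(atlas_dir / "networks.nii", atlas.labels, grid, dtype=np.int32)
    write_label_table(atlas_dir / "networks_labels.tsv", atlas.label_table)

    truth_path = directory / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(f"seed\t{spec.seed}\n")
        fh.write(f"n_subjects\t{spec.n_subjects}\n")
        fh.write(f"n_timepoints\t{spec.n_timepoints}\n")
        fh.write(f"noise_sd\t{spec.noise_sd}\n")
        fh.write(f"loading\t{spec.loading}\n")
        for k, net in enumerate(networks):
            fh.write(f"network_{k}_n_voxels\t{net.n_voxels}\n")
        for lesion_id, k, n in zip(truth.lesion_ids, truth.network_index,
                                   truth.lesion_n_voxels):
            fh.write(f"{lesion_id}_network\t{k}\n")
            fh.write(f"{lesion_id}_n_voxels\t{n}\n")

    return {
        "directory": directory,
        "cohort_dir": cohort_dir,
        "mask_manifest": manifest,
        "atlas_volume": atlas_dir / "networks.nii",
        "atlas_table": atlas_dir / "networks_labels.tsv",
        "truth_path": truth_path,
        "cohort": cohort,
        "masks": masks,
        "truth": truth,
        "atlas": atlas,
        "networks": networks,
        "config": config,
    }
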