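# lesionmap

Lesion network mapping on a shared volumetric grid: seed binary lesion
masks in a normative resting-state fMRI cohort, derive thresholded and
binarized connectivity maps, sum them per outcome group, contrast the
groups with voxelwise odds-ratio (VOR) maps, and summarize VORs over
anatomical / resting-state-network parcellations. A synthetic-connectome
generator with planted ground truth makes every stage testable offline.

## Method

For each lesion mask (outcome label `P` or `C`, e.g. seizure-free vs.
not-seizure-free):

1. **Seed** — the mask's mean time course is extracted per cohort subject.
2. **r-map** — Pearson correlation of the seed against every brain voxel.
3. **t-map** — Fisher-z per subject, then a one-sample t-test across
   subjects (default; a per-map `t = r·√(n−2)/√(1−r²)` conversion is
   available as `r_to_t_mode: single_map`).
4. **Threshold + binarize** — inclusive comparison at `t = 5.1` by default
   (the whole-brain Bonferroni-corrected threshold; two-tailed by default).
5. **Group sums** — binarized maps are summed per outcome group, giving
   per-voxel counts `V_P`, `V_C` with group sizes `N_P`, `N_C`.
6. **VOR maps** — per voxel, `VOR = V_P(N_C − V_C) / (V_C(N_P − V_P))`,
   computed in both directions; voxels with a zero denominator cell are
   excluded (marked invalid) by default, or Haldane–Anscombe-corrected
   with `zero_cell_policy: haldane`. "At least twice as likely" maps use
   an inclusive `VOR ≥ 2` cutoff.
7. **Atlas tables** — mean / sample-SD / max VOR per parcel, over each
   parcel's valid voxels, for both directions side by side.

Dice overlap of the raw lesion masks is reported per group (mean and SD
over within-group pairs) with a label-permutation test for the group
difference.

All volumes must share one grid (shape + affine within 1e-4); the package
refuses with a grid-mismatch error rather than resampling. Registration
to template space is out of scope and assumed done upstream.

## CLI

```sh
# write a self-contained synthetic fixture (cohort, masks, atlas, truth)
lesionmap simulate --out demo --seed 0

# check grid compatibility, group coverage, label tables
lesionmap validate -c demo/config.yaml

# run the full pipeline
lesionmap run -c demo/config.yaml

# region table from existing group sum maps only
lesionmap summarize --sum-p demo/results/sum_P.nii --sum-c demo/results/sum_C.nii \
    --n-p 3 --n-c 4 --atlas-volume demo/atlas/networks.nii \
    --atlas-table demo/atlas/networks_labels.tsv --out regions.tsv
```

The config file is flat YAML; every analysis parameter (`t_threshold: 5.1`,
`vor_cutoff: 2.0`, `tail`, `zero_cell_policy`, `r_to_t_mode`, `seed`)
surfaces there. Outputs: per-lesion binary maps with provenance sidecars,
`sum_P/sum_C` integer maps, both VOR maps with paired validity volumes,
both likelihood maps, `dice_report.tsv`, one `regions_<atlas>.tsv` per
atlas, and a `run_manifest.json` recording every parameter and input
checksum. Reruns with identical config + seed are bit-identical.

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 computation error.

## Input formats

- Volumes: NIfTI-1 (`.nii`/`.nii.gz`), 3-D masks/maps/atlases, 4-D cohort
  subjects (`cohort_dir/subj_*.nii` plus optional `brain_mask.nii`).
- Mask manifest: TSV `path<TAB>outcome` with outcome `P`/`C` (aliases
  `SF`/`NSF`).
- Label tables: two-column delimited text (integer id, name), tab or
  comma, optional header.

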