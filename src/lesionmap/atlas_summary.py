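"""Per-parcel summaries of VOR maps (region and network tables).

The regional mean is taken over a region's *valid* VOR voxels by default
(``support="valid_only"``); voxels where the odds ratio is undefined are
never silently absorbed as zeros. A region with no valid voxel still gets a
row, with NaN statistics and ``n_voxels_valid = 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging_io import ParcellationAtlas, require_compatible
from .vor import VORMap

SUPPORTS = ("valid_only", "all_region")

#: Column order for single-direction region tables.
REGION_COLUMNS = ["region_id", "region_name", "mean_vor", "sd_vor", "max_vor",
                  "n_voxels_region", "n_voxels_valid"]

#: Column order for dual-direction tables (P then C statistics).
DUAL_COLUMNS = ["region_id", "region_name", "mean_P", "sd_P", "max_P",
                "mean_C", "sd_C", "max_C", "n_voxels_region",
                "n_voxels_valid_P", "n_voxels_valid_C"]


def _region_row(values: np.ndarray, valid: np.ndarray, region_mask: np.ndarray,
                support: str):
    n_region = int(region_mask.sum())
    use = region_mask & valid
    n_valid = int(use.sum())
    if n_valid == 0:
        return np.nan, np.nan, np.nan, n_region, n_valid
    v = values[use]
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n_valid > 1 else 0.0
    return mean, sd, float(v.max()), n_region, n_valid


def region_stats(vor: VORMap, atlas: ParcellationAtlas,
                 support: str = "valid_only") -> pd.DataFrame:
    """Mean / sample-SD / max VOR per atlas region.

    ``support`` only affects bookkeeping: statistics are always over valid
    voxels (undefined odds cannot be averaged), but ``all_region`` callers
    get the region/valid count discrepancy via the two count columns.
    """
    if support not in SUPPORTS:
        raise ValueError(f"support must be one of {SUPPORTS}")
    require_compatible(vor.grid, atlas.grid, "region_stats inputs")
    rows = []
    for region_id in atlas.region_ids:
        region_mask = atlas.labels == region_id
        mean, sd, vmax, n_region, n_valid = _region_row(
            vor.values, vor.valid, region_mask, support)
        rows.append((region_id, atlas.label_table[region_id],
                     mean, sd, vmax, n_region, n_valid))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def dual_direction_table(vor_p: VORMap, vor_c: VORMap,
                         atlas: ParcellationAtlas,
                         support: str = "valid_only") -> pd.DataFrame:
    """One row per region with both directions' statistics side by side.

    ``vor_p`` is the P-direction map (P_vs_C), ``vor_c`` the C-direction
    (C_vs_P); row count always equals the number of atlas regions.
    """
    if vor_p.direction != "P_vs_C" or vor_c.direction != "C_vs_P":
        raise ValueError("expected (P_vs_C map, C_vs_P map)")
    require_compatible(vor_p.grid, atlas.grid, "dual_direction_table inputs")
    require_compatible(vor_c.grid, atlas.grid, "dual_direction_table inputs")
    rows = []
    for region_id in atlas.region_ids:
        region_mask = atlas.labels == region_id
        mean_p, sd_p, max_p, n_region, n_valid_p = _region_row(
            vor_p.values, vor_p.valid, region_mask, support)
        mean_c, sd_c, max_c, _, n_valid_c = _region_row(
            vor_c.values, vor_c.valid, region_mask, support)
        rows.append((region_id, atlas.label_table[region_id],
                     mean_p, sd_p, max_p, mean_c, sd_c, max_c,
                     n_region, n_valid_p, n_valid_c))
    return pd.DataFrame(rows, columns=DUAL_COLUMNS)


def write_region_table(path, table: pd.DataFrame) -> None:
    """Tab-delimited, fixed column order, deterministic float formatting."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
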