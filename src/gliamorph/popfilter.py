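"""Population filtering: outlier, edge and duplicate elimination.

Three rules clean the raw per-cell table before analysis:

* size/roundness outliers — bodies smaller than 10 um^2 or larger than
  500 um^2, or rounder than noise allows (< 0.7), are artefacts of tissue
  noise; the inequalities are strict, so boundary values are kept;
* edge cells — a cell whose territory touches the mosaic border may be
  truncated and is removed;
* sub-volume duplicates — the same cell captured on two adjacent axial
  sub-volumes would be counted twice; matched pairs are merged keeping the
  member with the larger body area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_outliers",
    "remove_edge_cells",
    "deduplicate_across_subvolumes",
    "apply_all",
]


@dataclass
class FilterConfig:
    min_body_area_um2: float = 10.0
    max_body_area_um2: float = 500.0
    min_roundness: float = 0.7
    edge_margin_um: float = 0.0
    dedup_max_centroid_dist_um: float = 5.0

    def __post_init__(self) -> None:
        if self.min_body_area_um2 >= self.max_body_area_um2:
            raise DataError("min body area must be below max body area")
        if self.edge_margin_um < 0 or self.dedup_max_centroid_dist_um < 0:
            raise DataError("margins must be >= 0")


def filter_outliers(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, rejected-with-reason) by size and roundness.

    Strict inequalities: a body of exactly 10 or 500 um^2, or roundness of
    exactly 0.7, is kept.
    """
    config = config or FilterConfig()
    too_small = records["body_area_um2"] < config.min_body_area_um2
    too_large = records["body_area_um2"] > config.max_body_area_um2
    not_round = records["roundness"] < config.min_roundness
    reason = np.select(
        [too_small, too_large, not_round],
        ["body_too_small", "body_too_large", "roundness"],
        default="",
    )
    rejected = records[reason != ""].copy()
    rejected["reject_reason"] = reason[reason != ""]
    kept = records[reason == ""].copy()
    return kept, rejected


def remove_edge_cells(
    records: pd.DataFrame,
    mosaic_bounds_um: tuple[float, float, float, float],
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells whose territory (hull or body) touches the border band.

    ``mosaic_bounds_um`` is (xmin, ymin, xmax, ymax).  A cell is removed
    iff the bounding extent of its convex hull united with its body enters
    the band of width ``edge_margin_um`` along the border (for an
    axis-aligned band, hull-bbox intersection is exact).
    """
    config = config or FilterConfig()
    xmin, ymin, xmax, ymax = mosaic_bounds_um
    m = config.edge_margin_um
    hit = (
        (records["hull_min_x_um"] <= xmin + m)
        | (records["hull_max_x_um"] >= xmax - m)
        | (records["hull_min_y_um"] <= ymin + m)
        | (records["hull_max_y_um"] >= ymax - m)
    )
    removed = records[hit].copy()
    removed["reject_reason"] = "edge"
    return records[~hit].copy(), removed


def deduplicate_across_subvolumes(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge duplicate captures on adjacent sub-volumes.

    Records on sub-volumes whose indices differ by exactly 1 and whose
    centroids lie within ``dedup_max_centroid_dist_um`` are considered one
    cell; within each matched group the record with the largest body area
    survives (ties keep the lowest sub-volume index).  Non-adjacent pairs
    are never merged.
    """
    config = config or FilterConfig()
    if records.empty:
        return records.copy(), records.iloc[0:0].copy()
    idx = records.index.to_numpy()
    sv = records["subvolume_index"].to_numpy()
    xy = records[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=float)

    parent = {i: i for i in range(len(idx))}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    svs = np.unique(sv)
    for s in svs:
        a = np.flatnonzero(sv == s)
        b = np.flatnonzero(sv == s + 1)
        if len(a) == 0 or len(b) == 0:
            continue
        tree = cKDTree(xy[b])
        for ia in a:
            for jb in tree.query_ball_point(xy[ia], config.dedup_max_centroid_dist_um):
                union(ia, b[jb])

    groups: dict[int, list[int]] = {}
    for i in range(len(idx)):
        groups.setdefault(find(i), []).append(i)
    keep_pos, drop_pos = [], []
    areas = records["body_area_um2"].to_numpy(dtype=float)
    for members in groups.values():
        if len(members) == 1:
            keep_pos.append(members[0])
            continue
        best = min(members, key=lambda i: (-areas[i], sv[i]))
        keep_pos.append(best)
        drop_pos.extend(m for m in members if m != best)
    kept = records.iloc[sorted(keep_pos)].copy()
    dropped = records.iloc[sorted(drop_pos)].copy()
    if not dropped.empty:
        dropped["reject_reason"] = "duplicate"
    return kept, dropped


@dataclass
class FilterReport:
    kept: pd.DataFrame
    rejected: pd.DataFrame
    counts: dict[str, int]


def apply_all(
    records: pd.DataFrame,
    mosaic_bounds_um: tuple[float, float, float, float] | None = None,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Outlier filter, optional edge removal, then sub-volume dedup."""
    config = config or FilterConfig()
    kept, rej1 = filter_outliers(records, config)
    n0 = len(records)
    if mosaic_bounds_um is not None:
        kept, rej2 = remove_edge_cells(kept, mosaic_bounds_um, config)
    else:
        rej2 = kept.iloc[0:0].copy()
    kept, rej3 = deduplicate_across_subvolumes(kept, config)
    rejected = pd.concat([rej1, rej2, rej3], axis=0)
    counts = {
        "input": n0,
        "outliers": len(rej1),
        "edge": len(rej2),
        "duplicates": len(rej3),
        "kept": len(kept),
    }
    return FilterReport(kept, rejected, counts)
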