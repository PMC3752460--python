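"""Difference-map summary statistics and atrophy-adjacency reports.

``difference_map_stats`` reproduces the usual results-table columns for a
thresholded group-difference map: number of significant voxels, location of
the peak t value, and min/max/mean/std of t within the significant mask.
``atrophy_adjacency`` quantifies how significant voxels sit relative to an
atrophy mask (overlap plus distance-ring fractions), the geometry behind
"increased connectivity surrounds the atrophied area" claims.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RegionStats",
    "AdjacencyReport",
    "difference_map_stats",
    "region_stats_table",
    "atrophy_adjacency",
    "write_adjacency_report",
]


@dataclasses.dataclass
class RegionStats:
    ic_label: int
    n_voxels: int
    max_location: Optional[tuple[int, int, int]]  # 0-based voxel indices
    t_min: Optional[float]
    t_max: Optional[float]
    t_mean: Optional[float]
    t_std: Optional[float]  # population std (divide by n)


@dataclasses.dataclass
class AdjacencyReport:
    overlap_fraction: float
    d_list: list[float]
    near_fraction: list[float]
    n_significant: int
    n_atrophy: int


def difference_map_stats(
    tmap: np.ndarray, sigmask: np.ndarray, ic_label: int
) -> RegionStats:
    """Summary statistics of t over the significant mask of one component.

    An empty mask yields n_voxels=0 with absent statistics. The std is the
    population standard deviation, so a single-voxel region reports 0.
    """
    tmap = np.asarray(tmap, dtype=np.float64)
    sigmask = np.asarray(sigmask).astype(bool)
    if tmap.shape != sigmask.shape:
        raise ValueError(f"tmap shape {tmap.shape} != mask shape {sigmask.shape}")
    n = int(sigmask.sum())
    if n == 0:
        return RegionStats(int(ic_label), 0, None, None, None, None, None)
    vals = tmap[sigmask]
    masked = np.where(sigmask, tmap, -np.inf)
    loc = np.unravel_index(int(np.argmax(masked)), tmap.shape)
    return RegionStats(
        ic_label=int(ic_label),
        n_voxels=n,
        max_location=tuple(int(i) for i in loc),
        t_min=float(vals.min()),
        t_max=float(vals.max()),
        t_mean=float(vals.mean()),
        t_std=float(vals.std(ddof=0)),
    )


def region_stats_table(stats: Sequence[RegionStats]) -> pd.DataFrame:
    """Tabulate per-IC region statistics; one row per component."""
    rows = []
    for s in stats:
        loc = s.max_location or (None, None, None)
        rows.append(
            {
                "ic": s.ic_label,
                "voxels": s.n_voxels,
                "max_x": loc[0],
                "max_y": loc[1],
                "max_z": loc[2],
                "min_t": s.t_min,
                "max_t": s.t_max,
                "mean_t": s.t_mean,
                "std_t": s.t_std,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ic", "voxels", "max_x", "max_y", "max_z",
            "min_t", "max_t", "mean_t", "std_t",
        ],
    )


def atrophy_adjacency(
    sigmask: np.ndarray,
    atrophy_mask: np.ndarray,
    d_list: Sequence[float],
) -> AdjacencyReport:
    """Overlap and distance-ring fractions of significant voxels around atrophy.

    Distances are Euclidean in voxel units, from a discrete distance
    transform of the atrophy mask. ``near_fraction[i]`` is the fraction of
    significant voxels within ``d_list[i]`` voxels of atrophy (0 distance =
    inside), hence monotone non-decreasing in d. With no significant voxels
    all fractions are 0.
    """
    sigmask = np.asarray(sigmask).astype(bool)
    atrophy_mask = np.asarray(atrophy_mask).astype(bool)
    if sigmask.shape != atrophy_mask.shape:
        raise ValueError("mask shapes differ")
    if not atrophy_mask.any():
        raise ValueError("atrophy mask is empty")
    d_list = [float(d) for d in d_list]
    if any(d < 0 for d in d_list):
        raise ValueError("distances must be >= 0")
    n_sig = int(sigmask.sum())
    if n_sig == 0:
        return AdjacencyReport(0.0, d_list, [0.0] * len(d_list), 0, int(atrophy_mask.sum()))
    dist = ndimage.distance_transform_edt(~atrophy_mask)
    dvals = dist[sigmask]
    return AdjacencyReport(
        overlap_fraction=float((dvals == 0).mean()),
        d_list=d_list,
        near_fraction=[float((dvals <= d).mean()) for d in d_list],
        n_significant=n_sig,
        n_atrophy=int(atrophy_mask.sum()),
    )


def write_adjacency_report(path: str | Path, report: AdjacencyReport) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dataclasses.asdict(report), indent=2))
    return path
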