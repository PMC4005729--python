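"""Range metrics derived from binary presence/absence maps.

Area in km^2 from presence-cell counts; directional percentage overlap
between two ranges; the cell-wise union of several ranges; Levins'
standardized niche breadth; and minimum distances from points to a range,
binned for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grids import BinaryRangeMap, OccurrenceSet, check_same_geometry

DEFAULT_BIN_EDGES = (50.0, 200.0, 500.0, 1000.0, 1500.0)


def range_area(rmap: BinaryRangeMap) -> float:
    """Predicted range area in km^2: presence cells x cell area."""
    return rmap.n_presence_cells * rmap.geometry.cell_area_km2


@dataclass
class OverlapReport:
    pct_a_in_b: float | None  # % of A's range overlapped by B (None if A empty)
    pct_b_in_a: float | None
    overlap_area_km2: float


def overlap(a: BinaryRangeMap, b: BinaryRangeMap) -> OverlapReport:
    """Directional percentage overlap of two ranges sharing one grid."""
    geom = check_same_geometry(a, b)
    inter = int((a.presence & b.presence).sum())
    na, nb = a.n_presence_cells, b.n_presence_cells
    return OverlapReport(
        pct_a_in_b=100.0 * inter / na if na else None,
        pct_b_in_a=100.0 * inter / nb if nb else None,
        overlap_area_km2=inter * geom.cell_area_km2,
    )


def union_range(maps: list[BinaryRangeMap]) -> BinaryRangeMap:
    """Cell-wise logical OR of several ranges (combined predicted range)."""
    if not maps:
        raise ValueError("need at least one map")
    geom = check_same_geometry(*maps)
    presence = np.zeros_like(maps[0].presence)
    mask = np.zeros_like(maps[0].mask)
    for m in maps:
        presence |= m.presence
        mask |= m.mask
    return BinaryRangeMap(geometry=geom, presence=presence, mask=mask)


def levins_breadth(suitability: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Levins' standardized niche breadth over grid cells.

    With p_i the suitability share of cell i, B_raw = 1 / sum(p_i^2) and the
    standardized breadth is (B_raw - 1) / (n - 1): 0 when a single cell is
    suitable, 1 when all n cells are equally suitable. Accepts continuous
    non-negative suitabilities or a binary map.
    """
    s = np.asarray(suitability, dtype=float).ravel()
    if mask is not None:
        s = s[np.asarray(mask, dtype=bool).ravel()]
    s = s[~np.isnan(s)]
    n = len(s)
    if n < 2:
        raise ValueError("need at least two valid cells")
    if np.any(s < 0):
        raise ValueError("suitability must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero suitability has undefined breadth")
    p = s / total
    b_raw = 1.0 / np.sum(p ** 2)
    return float((b_raw - 1.0) / (n - 1.0))


@dataclass
class DistanceReport:
    distances: np.ndarray        # meters per point, 0 if inside the range
    bin_edges: tuple
    bin_counts: dict[str, int]   # within-range, then (prev, edge] bins, then beyond


def distance_to_range(points: OccurrenceSet, rmap: BinaryRangeMap,
                      bin_edges: tuple = DEFAULT_BIN_EDGES) -> DistanceReport:
    """Minimum distance from each point to the range (0 if its cell is presence).

    Distances outside the range are point-to-nearest-presence-cell-center,
    Euclidean. Bins are closed on the right: within, (0, e1], (e1, e2], ...,
    > last edge; counts sum to the number of points.
    """
    if rmap.n_presence_cells == 0:
        raise ValueError("range is empty")
    geom = rmap.geometry
    rows, cols = np.nonzero(rmap.presence)
    cx, cy = geom.cell_centers(rows, cols)
    tree = cKDTree(np.column_stack([cx, cy]))
    d, _ = tree.query(points.points)
    prow, pcol = geom.cell_of(points.points[:, 0], points.points[:, 1])
    inside_grid = geom.inside(prow, pcol)
    in_range = np.zeros(len(points), dtype=bool)
    ok = np.nonzero(inside_grid)[0]
    in_range[ok] = rmap.presence[prow[ok], pcol[ok]]
    d = np.where(in_range, 0.0, d)

    edges = tuple(sorted(bin_edges))
    counts = {"within": int(in_range.sum())}
    prev = 0.0
    outside = d[~in_range]
    for e in edges:
        counts[f"<={e:g}m"] = int(np.sum((outside > prev) & (outside <= e)))
        prev = e
    counts[f">{edges[-1]:g}m"] = int(np.sum(outside > edges[-1]))
    return DistanceReport(distances=d, bin_edges=edges, bin_counts=counts)
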