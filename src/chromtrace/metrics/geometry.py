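"""Geometric single-cell metrics: radial scores, convex-hull nuclear volume,
and the A/B compartment polarization index.

The polarization index of one chromosome copy is

    PI = sqrt((1 - Vs/Va) * (1 - Vs/Vb))

where Va and Vb are the convex-hull volumes of its A- and B-labeled loci and
Vs is the volume of the hulls' intersection; PI is 1 for disjoint hulls and 0
for identical ones.  The intersection volume is computed exactly by
half-space intersection of the two polytopes.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from ..types import CellRecord, ChromatinTrace

__all__ = [
    "radial_scores",
    "nuclear_volume",
    "polarization_index",
    "convex_hull_intersection_volume",
]


def radial_scores(cell: CellRecord) -> tuple[np.ndarray, dict[int, float]]:
    """Normalized distance of each locus to the cell's locus centroid.

    Per-locus score = distance-to-centroid divided by the mean
    distance-to-centroid over all detected loci, so scores average to 1 per
    cell; the per-region score averages over chromosome copies.

    Returns ``(per_locus_scores, per_region_scores)`` where the locus order
    matches :meth:`CellRecord.loci_arrays`.
    """
    regs, xyz, _ = cell.loci_arrays()
    if len(regs) < 2:
        raise ValueError("radial scores need at least 2 detected loci")
    centroid = xyz.mean(axis=0)
    dist = np.linalg.norm(xyz - centroid, axis=1)
    scores = dist / dist.mean()
    per_region: dict[int, float] = {}
    for ri in np.unique(regs):
        per_region[int(ri)] = float(scores[regs == ri].mean())
    return scores, per_region


def nuclear_volume(cell: CellRecord, min_traces: int = 10) -> float:
    """Convex-hull volume of all detected loci, in µm³.

    NaN when the cell has fewer than ``min_traces`` non-empty traces or its
    loci are degenerate (coplanar / too few).
    """
    if cell.n_traces() < min_traces:
        return float("nan")
    _, xyz, _ = cell.loci_arrays()
    if len(xyz) < 4:
        return float("nan")
    try:
        hull = ConvexHull(xyz)
    except QhullError:
        return float("nan")
    return float(hull.volume) / 1e9


def _interior_point(halfspaces: np.ndarray) -> np.ndarray | None:
    """Chebyshev center of the polytope {x : Ax + b <= 0}; None if empty."""
    norms = np.linalg.norm(halfspaces[:, :3], axis=1, keepdims=True)
    c = np.zeros(4)
    c[3] = -1.0
    a_ub = np.hstack([halfspaces[:, :3], norms])
    b_ub = -halfspaces[:, 3]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=[(None, None)] * 3 + [(0, None)],
                  method="highs")
    if not res.success or res.x[3] < 1e-9:
        return None
    return res.x[:3]


def convex_hull_intersection_volume(points_a: np.ndarray,
                                    points_b: np.ndarray) -> float:
    """Volume of the intersection of the convex hulls of two 3D point sets."""
    try:
        ha = ConvexHull(points_a)
        hb = ConvexHull(points_b)
    except QhullError:
        return 0.0
    halfspaces = np.vstack([ha.equations, hb.equations])
    center = _interior_point(halfspaces)
    if center is None:
        return 0.0
    try:
        hs = HalfspaceIntersection(halfspaces, center)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0


def polarization_index(trace: ChromatinTrace, is_a: np.ndarray) -> float:
    """A/B polarization index of one chromosome copy.

    ``is_a`` is a boolean array over global region indices.  NaN when the
    trace has fewer than 4 A or 4 B loci (3D hulls need 4 points) or a hull
    is degenerate.
    """
    regs = trace.region_indices
    xyz = trace.xyz
    a_pts = xyz[is_a[regs]]
    b_pts = xyz[~is_a[regs]]
    if len(a_pts) < 4 or len(b_pts) < 4:
        return float("nan")
    try:
        va = ConvexHull(a_pts).volume
        vb = ConvexHull(b_pts).volume
    except QhullError:
        return float("nan")
    if va <= 0 or vb <= 0:
        return float("nan")
    vs = convex_hull_intersection_volume(a_pts, b_pts)
    term = (1.0 - vs / va) * (1.0 - vs / vb)
    return float(np.sqrt(max(term, 0.0)))
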