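"""Containment, adjacency and centroid localization between binary ROIs.

These operations turn qualitative anatomical statements — "the Vim lies
inside the motor cluster, against its inferior lateral border" — into
reproducible numbers: a containment fraction, a minimum boundary-to-
boundary distance, the set of subregions of the outer ROI whose border the
inner ROI approaches, and the subregion in which a centroid falls.

Boundary voxels are mask voxels with at least one face neighbor (6-
connectivity) outside the mask; distances are Euclidean between boundary
voxel centers, so they are exact multiples of the grid geometry and can be
checked against brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .roi_geometry import SUBREGION_LABELS, bounding_cuboid, classify_point, subdivide_roi
from .volume_io import ROIMask

__all__ = [
    "SpatialRelationRecord",
    "boundary_voxels",
    "containment_fraction",
    "min_surface_distance",
    "adjacency_report",
    "centroid_localization",
    "cohort_localization_summary",
    "relation_record",
]


def _check_same_grid(a: ROIMask, b: ROIMask) -> None:
    if a.grid != b.grid:
        raise ValueError("masks live on different grids")


def boundary_voxels(mask: ROIMask) -> np.ndarray:
    """(n, 3) indices of mask voxels with a face neighbor outside the mask."""
    m = mask.data > 0
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(m, struct, border_value=0)
    return np.argwhere(m & ~interior)


def containment_fraction(inner: ROIMask, outer: ROIMask) -> float:
    """|inner ∩ outer| / |inner|."""
    _check_same_grid(inner, outer)
    n_inner = inner.voxel_count
    if n_inner == 0:
        raise ValueError("inner mask is empty")
    return float(np.logical_and(inner.data, outer.data).sum() / n_inner)


def min_surface_distance(a: ROIMask, b: ROIMask) -> float:
    """Minimum distance (mm) between boundary voxel centers of two masks."""
    _check_same_grid(a, b)
    if a.voxel_count == 0 or b.voxel_count == 0:
        raise ValueError("surface distance is undefined for empty masks")
    ba = a.grid.voxel_to_world(boundary_voxels(a))
    bb = b.grid.voxel_to_world(boundary_voxels(b))
    dists, _ = cKDTree(bb).query(ba, k=1)
    return float(np.min(dists))


def adjacency_report(
    inner: ROIMask, outer: ROIMask, hemisphere: str, threshold_mm: float = 1.0
) -> set:
    """Subregions of ``outer`` whose share of the outer border the inner ROI approaches.

    ``outer`` is subdivided into its eight geometric subregions; a
    subregion is reported when the minimum distance from the inner ROI's
    boundary to the outer-boundary voxels belonging to that subregion is at
    most ``threshold_mm``.  Monotone non-decreasing in the threshold.
    """
    _check_same_grid(inner, outer)
    if inner.voxel_count == 0:
        raise ValueError("inner mask is empty")
    submap = subdivide_roi(outer, hemisphere).data
    border_idx = boundary_voxels(outer)
    border_codes = submap[tuple(border_idx.T)]
    inner_pts = inner.grid.voxel_to_world(boundary_voxels(inner))
    tree = cKDTree(inner_pts)
    adjacent = set()
    for code, name in SUBREGION_LABELS.items():
        sel = border_idx[border_codes == code]
        if len(sel) == 0:
            continue
        pts = outer.grid.voxel_to_world(sel)
        d, _ = tree.query(pts, k=1)
        if np.min(d) <= threshold_mm:
            adjacent.add(name)
    return adjacent


def centroid_localization(mask: ROIMask, reference: ROIMask, hemisphere: str) -> dict:
    """Classify the centroid of ``mask`` within ``reference``'s bounding cuboid.

    The centroid is the unweighted mean of mask voxel centers.  A centroid
    falling outside the reference cuboid is reported as
    ``{'subregion': 'outside', 'on_boundary': None}`` rather than raising.
    """
    _check_same_grid(mask, reference)
    if mask.voxel_count == 0 or reference.voxel_count == 0:
        raise ValueError("centroid localization requires nonempty masks")
    centroid = mask.world_coords().mean(axis=0)
    cuboid = bounding_cuboid(reference, hemisphere)
    if not cuboid.contains(centroid):
        return {"subregion": "outside", "on_boundary": None, "centroid": tuple(centroid)}
    label, on_boundary = classify_point(cuboid, centroid)
    return {"subregion": label, "on_boundary": on_boundary, "centroid": tuple(centroid)}


@dataclass
class SpatialRelationRecord:
    """Per-case spatial relations between an inner and an outer ROI."""

    subject_id: str
    hemisphere: str
    containment_fraction: float
    min_surface_distance_mm: float
    inner_centroid_subregion: str
    inner_centroid_on_boundary: bool | None
    adjacent_to: set


def relation_record(
    inner: ROIMask,
    outer: ROIMask,
    subject_id: str,
    hemisphere: str,
    threshold_mm: float = 1.0,
) -> SpatialRelationRecord:
    """Compute the full set of spatial relations for one case."""
    loc = centroid_localization(inner, outer, hemisphere)
    return SpatialRelationRecord(
        subject_id=subject_id,
        hemisphere=hemisphere,
        containment_fraction=containment_fraction(inner, outer),
        min_surface_distance_mm=min_surface_distance(inner, outer),
        inner_centroid_subregion=loc["subregion"],
        inner_centroid_on_boundary=loc["on_boundary"],
        adjacent_to=adjacency_report(inner, outer, hemisphere, threshold_mm),
    )


def cohort_localization_summary(records: list, predicate) -> dict:
    """Count records satisfying a predicate; fraction as percent (1 decimal)."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record list")
    count = sum(1 for r in records if predicate(r))
    total = len(records)
    return {
        "count": count,
        "total": total,
        "fraction_pct": round(100.0 * count / total, 1),
    }
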