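"""Bounding cuboids and the eight-way geometric subdivision of an ROI.

The subdivision splits the smallest axis-aligned cuboid enclosing all mask
voxel centers by its axial mid-plane (superior vs inferior half) and by the
two diagonals of its axial rectangle, giving four in-plane quadrants:
anterior, lateral, posterior and ventral (the medial-facing quadrant keeps
the traditional name "ventral").  Because the diagonals connect cuboid
corners, the quadrant test is performed in coordinates normalized by the
cuboid half-extents: with ``u`` the normalized lateral offset (sign chosen
per hemisphere so +u is lateral) and ``v`` the normalized anterior offset,

* anterior  iff ``v >  |u|``
* posterior iff ``v < -|u|``
* lateral   iff ``u >= |v|`` otherwise
* ventral   iff ``u <= -|v|``

Tie-breaks are deterministic: a z-tie is superior, a point on a diagonal
falls to the lateral/ventral side by the sign of ``u``, and the exact
center is lateral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import ROIMask, LabelVolume

__all__ = [
    "QUADRANTS",
    "SUBREGION_LABELS",
    "BoundingCuboid",
    "DegenerateGeometryError",
    "bounding_cuboid",
    "subdivide_roi",
    "classify_point",
]

QUADRANTS = ("anterior", "lateral", "posterior", "ventral")

#: label code -> name for the eight subregions (1..8; 0 = outside the ROI)
SUBREGION_LABELS = {
    i + 1 + 4 * j: f"{half}-{quad}"
    for j, half in enumerate(("superior", "inferior"))
    for i, quad in enumerate(QUADRANTS)
}
_LABEL_CODES = {name: code for code, name in SUBREGION_LABELS.items()}


class DegenerateGeometryError(ValueError):
    """The cuboid is flat in x or y, so the in-plane diagonals are undefined."""


@dataclass(frozen=True)
class BoundingCuboid:
    """Tight axis-aligned bounds over the voxel centers of a mask."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    hemisphere: str

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if any(h < l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"cuboid has hi < lo: lo={self.lo}, hi={self.hi}")

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.lo) + np.asarray(self.hi)) / 2.0

    @property
    def extents(self) -> np.ndarray:
        return np.asarray(self.hi) - np.asarray(self.lo)

    @property
    def half_extents(self) -> np.ndarray:
        return self.extents / 2.0

    @property
    def lateral_sign(self) -> float:
        return 1.0 if self.hemisphere == "right" else -1.0

    def contains(self, point, atol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= np.asarray(self.lo) - atol) and np.all(p <= np.asarray(self.hi) + atol))


def bounding_cuboid(mask: ROIMask, hemisphere: str) -> BoundingCuboid:
    """Smallest axis-aligned cuboid containing all nonzero voxel centers."""
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise ValueError("cannot compute the bounding cuboid of an empty mask")
    lo = mask.grid.voxel_to_world(idx.min(axis=0))
    hi = mask.grid.voxel_to_world(idx.max(axis=0))
    return BoundingCuboid(tuple(lo), tuple(hi), hemisphere)


def _normalized_coords(cuboid: BoundingCuboid, points: np.ndarray):
    """(u, v, w) normalized coordinates; raises on flat x/y extents."""
    half = cuboid.half_extents
    if half[0] <= 0 or half[1] <= 0:
        raise DegenerateGeometryError(
            "ROI is flat in x or y (zero cuboid extent); the in-plane diagonal "
            "subdivision is undefined — supply an ROI with nonzero axial area"
        )
    center = cuboid.center
    u = cuboid.lateral_sign * (points[..., 0] - center[0]) / half[0]
    v = (points[..., 1] - center[1]) / half[1]
    if half[2] > 0:
        w = (points[..., 2] - center[2]) / half[2]
    else:
        w = np.zeros_like(u)
    return u, v, w


def _classify_normalized(u, v, w) -> np.ndarray:
    """Vectorized subregion codes from normalized coordinates."""
    u, v, w = np.broadcast_arrays(u, v, w)
    # quadrant index within QUADRANTS: anterior=0, lateral=1, posterior=2, ventral=3
    quad = np.where(u <= -np.abs(v), 3, 1)
    quad = np.where(v > np.abs(u), 0, quad)
    quad = np.where(v < -np.abs(u), 2, quad)
    quad = np.where((u == 0) & (v == 0), 1, quad)  # exact center -> lateral
    superior = w >= 0  # z tie -> superior
    return np.where(superior, quad + 1, quad + 5).astype(np.int32)


def subdivide_roi(mask: ROIMask, hemisphere: str) -> LabelVolume:
    """Partition an ROI into its eight geometric subregions.

    Returns a :class:`LabelVolume` on the mask's grid whose nonzero values
    are the codes of :data:`SUBREGION_LABELS`; voxels outside the ROI are 0.
    """
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise ValueError("cannot subdivide an empty mask")
    # normalized coordinates are computed in voxel-index space: the map from
    # index to world is affine per axis, so the normalization is identical,
    # but index arithmetic keeps half-integer centers exact and makes the
    # diagonal tie-breaks (and mirror equivariance) deterministic
    lo_i, hi_i = idx.min(axis=0), idx.max(axis=0)
    center_i = (lo_i + hi_i) / 2.0
    half_i = (hi_i - lo_i) / 2.0
    if half_i[0] <= 0 or half_i[1] <= 0:
        raise DegenerateGeometryError(
            "ROI is flat in x or y (zero cuboid extent); the in-plane diagonal "
            "subdivision is undefined — supply an ROI with nonzero axial area"
        )
    if hemisphere not in ("left", "right"):
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    sign = 1.0 if hemisphere == "right" else -1.0
    u = sign * (idx[:, 0] - center_i[0]) / half_i[0]
    v = (idx[:, 1] - center_i[1]) / half_i[1]
    w = (idx[:, 2] - center_i[2]) / half_i[2] if half_i[2] > 0 else np.zeros_like(u)
    codes = _classify_normalized(u, v, w)
    out = np.zeros(mask.grid.shape, dtype=np.int32)
    out[tuple(idx.T)] = codes
    return LabelVolume(mask.grid, out, label_map={v: k for k, v in SUBREGION_LABELS.items()})


def classify_point(cuboid: BoundingCuboid, point, boundary_tolerance: float = 0.05):
    """Classify a world point against a cuboid's eight subregions.

    Returns ``(label, on_boundary)``.  ``on_boundary`` is True when the
    point lies within ``boundary_tolerance`` (in normalized cuboid units) of
    the axial mid-plane or of either in-plane diagonal; it is reported for
    interpretation only and never alters the label.
    """
    p = np.asarray(point, dtype=float)
    if not cuboid.contains(p):
        raise ValueError(f"point {tuple(p)} lies outside the cuboid [{cuboid.lo}, {cuboid.hi}]")
    u, v, w = _normalized_coords(cuboid, p[np.newaxis, :])
    code = int(_classify_normalized(u, v, w)[0])
    on_boundary = bool(
        np.abs(w[0]) <= boundary_tolerance or np.abs(np.abs(u[0]) - np.abs(v[0])) <= boundary_tolerance
    )
    return SUBREGION_LABELS[code], on_boundary
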