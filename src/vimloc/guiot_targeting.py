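"""Indirect stereotactic Vim targeting via the quadrilatere of Guiot.

The construction places the target from midline landmarks alone: laterally
at a fixed offset (default 11 mm) from the third-ventricle lateral wall,
anteriorly at a configurable fraction of the PC->AC distance measured from
PC, and vertically on (or at an offset from) the AC-PC plane.  Only the
11 mm laterality is a firmly established constant of the construction; the
anterior-posterior fraction and vertical offset vary between descriptions,
so they are exposed as parameters rather than hard-coded.

Repeated blind targeting is emulated by perturbing every landmark
coordinate uniformly within a half-range and snapping each reconstructed
point to the nearest voxel center, which reproduces the whole-voxel
granularity of manual targeting on an image grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import ROIMask, VoxelGrid

__all__ = [
    "LandmarkSet",
    "GuiotParams",
    "GuiotTarget",
    "TargetingSession",
    "construct_guiot_target",
    "simulate_repeated_targeting",
    "targeting_reproducibility",
    "session_within_one_voxel",
    "sphere_roi",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Stereotactic landmarks: AC, PC, thalamus height, ventricle walls.

    ``third_ventricle_wall_x_mm`` maps hemisphere -> |x| of the lateral wall
    of the third ventricle on that side.  ``hemisphere`` optionally pins the
    set to one side; targeting a different side then raises.
    """

    ac: tuple[float, float, float]
    pc: tuple[float, float, float]
    thalamus_height_mm: float
    third_ventricle_wall_x_mm: dict
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if not self.ac[1] > self.pc[1]:
            raise ValueError(f"AC must be anterior to PC (AC.y={self.ac[1]}, PC.y={self.pc[1]})")
        if self.thalamus_height_mm <= 0:
            raise ValueError("thalamus height must be positive")
        for side, wall in self.third_ventricle_wall_x_mm.items():
            if side not in ("left", "right"):
                raise ValueError(f"unknown hemisphere key {side!r}")
            if wall < 0:
                raise ValueError("third-ventricle wall |x| must be non-negative")
        if self.hemisphere not in (None, "left", "right"):
            raise ValueError(f"invalid hemisphere {self.hemisphere!r}")

    def translated(self, t) -> "LandmarkSet":
        t = np.asarray(t, dtype=float)
        return LandmarkSet(
            ac=tuple(np.asarray(self.ac) + t),
            pc=tuple(np.asarray(self.pc) + t),
            thalamus_height_mm=self.thalamus_height_mm + t[2],
            third_ventricle_wall_x_mm=dict(self.third_ventricle_wall_x_mm),
            hemisphere=self.hemisphere,
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        obj = json.loads(Path(path).read_text())
        return cls(
            ac=tuple(obj["AC"]),
            pc=tuple(obj["PC"]),
            thalamus_height_mm=float(obj["thalamus_height_mm"]),
            third_ventricle_wall_x_mm={k: float(v) for k, v in obj["wall_x_mm"].items()},
            hemisphere=obj.get("hemisphere"),
        )

    def to_json(self, path) -> None:
        obj = {
            "AC": list(self.ac),
            "PC": list(self.pc),
            "thalamus_height_mm": self.thalamus_height_mm,
            "wall_x_mm": dict(self.third_ventricle_wall_x_mm),
        }
        if self.hemisphere is not None:
            obj["hemisphere"] = self.hemisphere
        Path(path).write_text(json.dumps(obj, indent=2))


@dataclass(frozen=True)
class GuiotParams:
    """Tunable constants of the Guiot construction.

    ``lateral_offset_mm`` is the distance from the third-ventricle lateral
    wall; ``ap_fraction`` the anterior fraction of the PC->AC distance
    measured from PC; ``z_offset_mm`` the height relative to the AC-PC
    plane; ``sphere_radius_mm`` the radius of the emulated isodose sphere.
    """

    lateral_offset_mm: float = 11.0
    ap_fraction: float = 0.25
    z_offset_mm: float = 0.0
    sphere_radius_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.lateral_offset_mm <= 0:
            raise ValueError("lateral_offset_mm must be positive")
        if not 0 < self.ap_fraction < 1:
            raise ValueError("ap_fraction must lie strictly between 0 and 1")
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere_radius_mm must be positive")


@dataclass(frozen=True)
class GuiotTarget:
    point: tuple[float, float, float]
    hemisphere: str
    params: GuiotParams
    landmarks: LandmarkSet
    quantized_point: tuple[float, float, float] | None = None

    def quantized(self, grid: VoxelGrid) -> "GuiotTarget":
        q = grid.voxel_to_world(grid.nearest_voxel(self.point))
        return GuiotTarget(self.point, self.hemisphere, self.params, self.landmarks, tuple(q))


def construct_guiot_target(
    landmarks: LandmarkSet, hemisphere: str | None = None, params: GuiotParams | None = None
) -> GuiotTarget:
    """Deterministically construct the Guiot target point for one side."""
    params = params or GuiotParams()
    side = hemisphere or landmarks.hemisphere
    if side not in ("left", "right"):
        raise ValueError("a hemisphere must be given (argument or landmarks.hemisphere)")
    if landmarks.hemisphere is not None and side != landmarks.hemisphere:
        raise ValueError(
            f"landmarks are pinned to the {landmarks.hemisphere} hemisphere, requested {side}"
        )
    if side not in landmarks.third_ventricle_wall_x_mm:
        raise ValueError(f"no third-ventricle wall coordinate for side {side!r}")
    sign = 1.0 if side == "right" else -1.0
    wall = landmarks.third_ventricle_wall_x_mm[side]
    ac, pc = np.asarray(landmarks.ac), np.asarray(landmarks.pc)
    x = sign * (wall + params.lateral_offset_mm)
    y = pc[1] + params.ap_fraction * (ac[1] - pc[1])
    z = (ac[2] + pc[2]) / 2.0 + params.z_offset_mm
    return GuiotTarget((float(x), float(y), float(z)), side, params, landmarks)


@dataclass
class TargetingSession:
    """An ordered series of independently re-constructed Guiot targets."""

    targets: list
    grid: VoxelGrid
    jitter_mm: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.targets) < 2:
            raise ValueError("a targeting session needs at least 2 repetitions")

    def quantized_points(self) -> np.ndarray:
        return np.asarray([t.quantized_point for t in self.targets], dtype=float)


def simulate_repeated_targeting(
    landmarks: LandmarkSet,
    hemisphere: str,
    grid: VoxelGrid,
    n_rep: int = 6,
    jitter_mm: float = 0.2,
    params: GuiotParams | None = None,
    seed: int | None = None,
) -> TargetingSession:
    """Simulate blind re-targeting with per-landmark uniform jitter.

    Each repetition perturbs every landmark coordinate independently and
    uniformly within ``±jitter_mm``, reconstructs the target and snaps it to
    the nearest voxel center of ``grid``.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be at least 2")
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be non-negative")
    params = params or GuiotParams()
    rng = np.random.default_rng(seed)
    targets = []
    for _ in range(n_rep):
        d_ac = rng.uniform(-jitter_mm, jitter_mm, 3)
        d_pc = rng.uniform(-jitter_mm, jitter_mm, 3)
        d_wall = rng.uniform(-jitter_mm, jitter_mm)
        d_height = rng.uniform(-jitter_mm, jitter_mm)
        walls = {
            k: max(0.0, v + (d_wall if k == hemisphere else 0.0))
            for k, v in landmarks.third_ventricle_wall_x_mm.items()
        }
        jittered = LandmarkSet(
            ac=tuple(np.asarray(landmarks.ac) + d_ac),
            pc=tuple(np.asarray(landmarks.pc) + d_pc),
            thalamus_height_mm=landmarks.thalamus_height_mm + d_height,
            third_ventricle_wall_x_mm=walls,
            hemisphere=landmarks.hemisphere,
        )
        targets.append(construct_guiot_target(jittered, hemisphere, params).quantized(grid))
    return TargetingSession(targets, grid, jitter_mm, seed)


def targeting_reproducibility(session: TargetingSession) -> dict:
    """Euclidean distances of each repetition to the first targeted point.

    Distances are computed between quantized (voxel-center) points, the
    first repetition serving as the reference; the reference's zero distance
    is included in the list and the mean.
    """
    pts = session.quantized_points()
    ref = pts[0]
    dists = np.linalg.norm(pts - ref, axis=1)
    return {
        "distances_to_first": [float(d) for d in dists],
        "max_mm": float(dists.max()),
        "mean_mm": float(dists.mean()),
    }


def session_within_one_voxel(session: TargetingSession) -> bool:
    """True when all repetitions overlap or differ by at most one voxel per axis."""
    pts = session.quantized_points()
    idx = np.rint(session.grid.world_to_voxel(pts)).astype(int)
    span = idx.max(axis=0) - idx.min(axis=0)
    return bool(np.all(span <= 1))


def sphere_roi(center, radius_mm: float, grid: VoxelGrid) -> ROIMask:
    """Spherical ROI: voxels whose center lies within ``radius_mm`` of ``center``.

    Emulates the 2 mm-radius isodose sphere drawn around a target point.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    center = np.asarray(center, dtype=float)
    data = np.zeros(grid.shape, dtype=np.uint8)
    lo = np.maximum(grid.world_to_voxel(center - radius_mm), 0).astype(int)
    hi = np.minimum(np.ceil(grid.world_to_voxel(center + radius_mm)).astype(int) + 1, grid.shape)
    if np.any(lo >= hi):
        import warnings

        warnings.warn("sphere lies entirely outside the grid; returning an empty mask")
        return ROIMask(grid, data)
    axes = [grid.axis_coords(a)[lo[a] : hi[a]] - center[a] for a in range(3)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    # small relative tolerance so lattice points mathematically on the sphere
    # (e.g. Pythagorean offsets) are included despite float rounding
    inside = dx * dx + dy * dy + dz * dz <= radius_mm * radius_mm * (1.0 + 1e-9)
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return ROIMask(grid, data)
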