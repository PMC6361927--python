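"""Synthetic thalamic-anatomy phantoms with known ground truth.

Real 7T SWI with a manually delineated Vim is scarce, so every downstream
stage of this package is exercised on phantoms that emulate the reported
statistical structure of such data: per hemisphere, an ovoid thalamus
(default 7600 mm³), a motor-nuclei (VLV) cluster occupying ~15% of it, and
a small Vim occupying ~1% of it, placed in the inferior anterior-lateral
part of the VLV flush against its lateral border.  The SWI-like intensity
volume renders the Vim hyperintense between two darker slabs (Vc posterior,
Vo anterior-superior), gives the pulvinar a medial-bright gradient, and can
draw dark vessel-like cylinders near the Vim.

Shapes are ellipsoids clipped to their parent structure.  Absolute sizes
are controlled by the volume/fraction targets: the ellipsoid radius is
scaled so the clipped voxel count matches the target exactly (to one
voxel), which makes the realized volume fractions recover the requested
ones by construction.  The extent parameters therefore set *shape* (aspect
ratio), not size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .guiot_targeting import LandmarkSet
from .roi_geometry import bounding_cuboid
from .volume_io import IntensityVolume, LabelVolume, ROIMask, VoxelGrid

__all__ = [
    "SwiParams",
    "VesselParams",
    "JitterParams",
    "VimPlacement",
    "PhantomSpec",
    "SyntheticSubject",
    "ellipsoid_mask",
    "generate_subject",
    "generate_cohort",
    "vim_contrast_sd",
]

HEMISPHERES = ("left", "right")
STRUCTURES = ("thalamus", "vlv", "vim", "vc", "vo", "pulvinar")

# Nominal right-hemisphere geometry (mm, AC at origin).  Mirrored for the
# left side.  Aspect triples are ellipsoid semi-axes at unit scale; the
# exact-count fit rescales them to hit the volume targets.
_THAL_CENTER = np.array([9.8, -17.5, 2.5])
_THAL_ASPECT = np.array([9.2, 16.5, 11.6])
_VLV_OFFSET = np.array([2.3, -1.0, -2.5])  # relative to the thalamus center
_VLV_ASPECT = np.array([5.4, 7.9, 6.4])
_PULVINAR_POSTERIOR_FRACTION = 0.28  # posterior slice of the thalamus cuboid


@dataclass(frozen=True)
class SwiParams:
    """Mean intensity levels (arbitrary units) and noise of the SWI phantom."""

    background: float = 40.0
    thalamus: float = 45.0
    vim: float = 62.0
    vc_vo: float = 30.0
    pulvinar_lateral: float = 32.0
    pulvinar_medial: float = 50.0
    noise_sd: float = 3.0


@dataclass(frozen=True)
class VesselParams:
    """Dark cylindrical vessel artifacts near the Vim."""

    count: int = 2
    radius_mm: float = 0.4
    length_mm: float = 18.0
    intensity: float = 15.0
    enabled: bool = True


@dataclass(frozen=True)
class JitterParams:
    """Per-subject anatomical variability for cohort generation."""

    translation_mm: float = 0.5
    scale: float = 0.05


@dataclass(frozen=True)
class VimPlacement:
    """Vim position inside the VLV bounding cuboid.

    ``ap_frac``/``dv_frac`` are offsets of the Vim center from the cuboid
    center in units of the cuboid half-extents (positive = anterior /
    superior).  ``lateral_overlap_mm`` is how far the unclipped Vim
    ellipsoid pokes past the lateral VLV surface; after clipping the Vim
    sits flush against that border.
    """

    ap_frac: float = 0.0
    dv_frac: float = -0.35
    lateral_overlap_mm: float = 0.3


def _default_grid() -> VoxelGrid:
    return VoxelGrid((96, 96, 96), (0.4, 0.4, 0.4), (-19.0, -34.6, -14.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Full configuration of one phantom subject (both hemispheres)."""

    grid: VoxelGrid = field(default_factory=_default_grid)
    thalamus_volume_mm3: float = 7600.0
    vlv_fraction: float = 0.15
    vim_fraction: float = 0.010
    #: full Vim extents in mm: anterio-posterior, dorso-ventral, medio-lateral
    vim_extent_mm: tuple[float, float, float] = (3.0, 8.0, 5.0)
    vim_placement: VimPlacement = field(default_factory=VimPlacement)
    swi_params: SwiParams = field(default_factory=SwiParams)
    vessel_params: VesselParams = field(default_factory=VesselParams)
    subject_jitter: JitterParams = field(default_factory=JitterParams)

    def __post_init__(self) -> None:
        if not 0 < self.vim_fraction < self.vlv_fraction < 1:
            raise ValueError(
                "fractions must satisfy 0 < vim_fraction < vlv_fraction < 1, got "
                f"vim={self.vim_fraction}, vlv={self.vlv_fraction}"
            )
        if any(e <= 0 for e in self.vim_extent_mm):
            raise ValueError("vim extents must be positive")
        if self.thalamus_volume_mm3 <= 0:
            raise ValueError("thalamus volume must be positive")

    @property
    def vim_aspect_semi(self) -> np.ndarray:
        """Vim semi-axes in grid (x, y, z) = (medio-lateral, AP, dorso-ventral) order."""
        ap, dv, ml = self.vim_extent_mm
        return np.array([ml, ap, dv]) / 2.0


@dataclass
class SyntheticSubject:
    subject_id: str
    spec: PhantomSpec
    structures: dict
    intensity: IntensityVolume
    landmarks: LandmarkSet
    vessel_mask: ROIMask
    realized: dict

    def mask(self, structure: str, hemisphere: str) -> ROIMask:
        return self.structures[(structure, hemisphere)]

    def labels(self) -> LabelVolume:
        """Flattened label volume; nested structures keep the finest label."""
        grid = self.spec.grid
        data = np.zeros(grid.shape, dtype=np.int32)
        label_map = {}
        code = 0
        # paint coarse-to-fine so the finest structure wins
        for structure in ("thalamus", "vlv", "pulvinar", "vo", "vc", "vim"):
            for hemi in HEMISPHERES:
                code += 1
                label_map[f"{structure}_{hemi}"] = code
                data[self.structures[(structure, hemi)].data > 0] = code
        return LabelVolume(grid, data, label_map)


# ---------------------------------------------------------------------------
# Ellipsoid primitives
# ---------------------------------------------------------------------------


def _box_slices(grid: VoxelGrid, center, radii) -> tuple[slice, slice, slice] | None:
    lo = np.floor(grid.world_to_voxel(np.asarray(center) - np.asarray(radii))).astype(int)
    hi = np.ceil(grid.world_to_voxel(np.asarray(center) + np.asarray(radii))).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, grid.shape)
    if np.any(lo >= hi):
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _r2_in_box(grid: VoxelGrid, center, semi_axes, box) -> np.ndarray:
    """Squared normalized ellipsoid radius at voxel centers of a sub-box."""
    axes = [
        (grid.axis_coords(a)[box[a]] - center[a]) / semi_axes[a] for a in range(3)
    ]
    nx, ny, nz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return nx * nx + ny * ny + nz * nz


def ellipsoid_mask(center, semi_axes, grid: VoxelGrid) -> ROIMask:
    """Voxels whose center satisfies sum(((c - center)/a)^2) <= 1."""
    semi_axes = np.asarray(semi_axes, dtype=float)
    if np.any(semi_axes <= 0):
        raise ValueError("semi-axes must be positive")
    data = np.zeros(grid.shape, dtype=np.uint8)
    box = _box_slices(grid, center, semi_axes)
    if box is None:
        warnings.warn("ellipsoid lies entirely outside the grid; returning an empty mask")
        return ROIMask(grid, data)
    data[box] = _r2_in_box(grid, center, semi_axes, box) <= 1.0
    mask = ROIMask(grid, data)
    if mask.voxel_count == 0:
        warnings.warn("ellipsoid contains no voxel centers; returning an empty mask")
    return mask


def _fit_ellipsoid(
    grid: VoxelGrid, center, aspect_semi, target_mm3: float, clip: np.ndarray, max_scale: float = 1.8
):
    """Ellipsoid of given aspect, clipped to ``clip``, scaled to a volume target.

    Chooses the scale so that the clipped mask holds exactly
    ``round(target / voxel_volume)`` voxels (up to ties in the radius
    field).  Returns ``(mask_data, scale)``.
    """
    aspect_semi = np.asarray(aspect_semi, dtype=float)
    box = _box_slices(grid, center, aspect_semi * max_scale)
    if box is None:
        raise ValueError("structure lies entirely outside the grid")
    r2 = _r2_in_box(grid, center, aspect_semi, box)
    vals = r2[clip[box]]
    n_target = max(1, int(round(target_mm3 / grid.voxel_volume_mm3)))
    if vals.size < n_target:
        warnings.warn(
            f"volume target {target_mm3:.0f} mm3 exceeds the available clipped region; "
            "using every available voxel"
        )
        n_target = vals.size
    vals = np.sort(vals)
    k2 = vals[n_target - 1]
    data = np.zeros(grid.shape, dtype=np.uint8)
    data[box] = (r2 <= k2) & clip[box]
    return data, float(np.sqrt(k2))


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------


def _lateral_surface_x(grid: VoxelGrid, mask_data: np.ndarray, sign: float, y0: float, z0: float):
    """|x| of the lateral-most mask voxel near the axial position (y0, z0)."""
    idx = np.argwhere(mask_data)
    pts = grid.voxel_to_world(idx)
    sy, sz = grid.spacing[1], grid.spacing[2]
    near = (np.abs(pts[:, 1] - y0) <= 1.5 * sy) & (np.abs(pts[:, 2] - z0) <= 1.5 * sz)
    if not near.any():
        near = np.ones(len(pts), dtype=bool)  # fall back to the whole structure
    return float(np.max(sign * pts[near, 0]))


def _hemisphere_structures(spec: PhantomSpec, hemisphere: str, t_th, t_vlv, t_vim, s_vol):
    """Build the clipped, volume-fitted masks of one hemisphere."""
    grid = spec.grid
    sign = 1.0 if hemisphere == "right" else -1.0
    mirror = np.array([sign, 1.0, 1.0])

    # thalamus: ellipsoid clipped to its own half-space (never crosses x=0)
    th_center = _THAL_CENTER * mirror + t_th
    xw = grid.axis_coords(0)
    halfspace = np.zeros(grid.shape, dtype=bool)
    halfspace[sign * xw > 0, :, :] = True
    th_data, _ = _fit_ellipsoid(
        grid, th_center, _THAL_ASPECT, spec.thalamus_volume_mm3 * s_vol, halfspace
    )
    th_vol = th_data.sum() * grid.voxel_volume_mm3

    # VLV: anterior-ventral-lateral sub-ellipsoid clipped to the thalamus
    vlv_center = th_center + _VLV_OFFSET * mirror + t_vlv
    vlv_data, _ = _fit_ellipsoid(
        grid, vlv_center, _VLV_ASPECT, spec.vlv_fraction * th_vol, th_data.astype(bool)
    )
    vlv_mask = ROIMask(grid, vlv_data)

    # Vim: small ellipsoid in the inferior anterior-lateral VLV, flush
    # against the lateral VLV surface, clipped to the VLV
    cub = bounding_cuboid(vlv_mask, hemisphere)
    half = cub.half_extents
    place = spec.vim_placement
    y0 = cub.center[1] + place.ap_frac * half[1] + t_vim[1]
    z0 = cub.center[2] + place.dv_frac * half[2] + t_vim[2]
    x_lat = _lateral_surface_x(grid, vlv_data, sign, y0, z0)
    aspect = spec.vim_aspect_semi
    vim_target = spec.vim_fraction * th_vol
    k = (vim_target / (4.0 / 3.0 * np.pi * np.prod(aspect))) ** (1.0 / 3.0)
    vim_data = None
    for _ in range(3):  # fixed-point iteration: center depends on the fitted scale
        cx = sign * (x_lat + place.lateral_overlap_mm - k * aspect[0]) + t_vim[0]
        vim_data, k_new = _fit_ellipsoid(
            grid, (cx, y0, z0), aspect, vim_target, vlv_data.astype(bool)
        )
        if abs(k_new - k) < 1e-3:
            k = k_new
            break
        k = k_new

    # Vc (posterior dark slab) and Vo (anterior-superior dark slab) flank the Vim
    vim_semi = k * aspect
    vc_center = np.array([cx, y0 - (vim_semi[1] + 1.6), z0])
    vo_center = np.array([cx, y0 + (vim_semi[1] + 1.4), z0 + 2.2])
    flank_semi = np.array([vim_semi[0], 1.6, vim_semi[2]])
    th_bool = th_data.astype(bool)
    not_vim = ~vim_data.astype(bool)
    vc_data = (ellipsoid_mask(vc_center, flank_semi, grid).data.astype(bool) & th_bool & not_vim)
    vo_data = (ellipsoid_mask(vo_center, flank_semi, grid).data.astype(bool) & th_bool & not_vim)

    # pulvinar: posterior slice of the thalamus cuboid
    th_cub = bounding_cuboid(ROIMask(grid, th_data), hemisphere)
    y_cut = th_cub.lo[1] + _PULVINAR_POSTERIOR_FRACTION * th_cub.extents[1]
    yw = grid.axis_coords(1)
    posterior = np.zeros(grid.shape, dtype=bool)
    posterior[:, yw < y_cut, :] = True
    pul_data = th_bool & posterior & ~vlv_data.astype(bool) & ~vc_data & ~vo_data

    return {
        "thalamus": ROIMask(grid, th_data),
        "vlv": vlv_mask,
        "vim": ROIMask(grid, vim_data),
        "vc": ROIMask(grid, vc_data.astype(np.uint8)),
        "vo": ROIMask(grid, vo_data.astype(np.uint8)),
        "pulvinar": ROIMask(grid, pul_data.astype(np.uint8)),
    }


def _paint_intensity(spec: PhantomSpec, structures: dict, rng: np.random.Generator):
    grid = spec.grid
    p = spec.swi_params
    img = np.full(grid.shape, p.background, dtype=float)
    for hemi in HEMISPHERES:
        th = structures[("thalamus", hemi)].data > 0
        img[th] = p.thalamus
        pul = structures[("pulvinar", hemi)].data > 0
        if pul.any():
            xw = np.abs(grid.voxel_to_world(np.argwhere(pul))[:, 0])
            lo, hi = xw.min(), xw.max()
            t = (xw - lo) / (hi - lo) if hi > lo else np.zeros_like(xw)
            img[pul] = p.pulvinar_medial - t * (p.pulvinar_medial - p.pulvinar_lateral)
        dark = (structures[("vc", hemi)].data > 0) | (structures[("vo", hemi)].data > 0)
        img[dark] = p.vc_vo
        img[structures[("vim", hemi)].data > 0] = p.vim

    vessel = np.zeros(grid.shape, dtype=np.uint8)
    vp = spec.vessel_params
    if vp.enabled and vp.count > 0:
        for hemi in HEMISPHERES:
            vim_idx = np.argwhere(structures[("vim", hemi)].data)
            anchor = grid.voxel_to_world(vim_idx.mean(axis=0))
            for _ in range(vp.count):
                point = anchor + rng.uniform(-4.0, 4.0, 3)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                _stamp_cylinder(grid, vessel, point, direction, vp.length_mm, vp.radius_mm)
        img[vessel > 0] = vp.intensity
    img += rng.normal(0.0, p.noise_sd, grid.shape)
    return IntensityVolume(grid, img), ROIMask(grid, vessel)


def _stamp_cylinder(grid: VoxelGrid, out: np.ndarray, point, direction, length_mm, radius_mm):
    """Mark voxels within ``radius_mm`` of a line segment through ``point``."""
    a = np.asarray(point) - 0.5 * length_mm * direction
    b = np.asarray(point) + 0.5 * length_mm * direction
    lo = np.minimum(a, b) - radius_mm
    hi = np.maximum(a, b) + radius_mm
    box = _box_slices(grid, (lo + hi) / 2, (hi - lo) / 2)
    if box is None:
        return
    axes = [grid.axis_coords(ax)[box[ax]] for ax in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) - a
    ab = b - a
    tpar = np.clip((pts @ ab) / (ab @ ab), 0.0, 1.0)
    dist = np.linalg.norm(pts - tpar[..., None] * ab, axis=-1)
    out[box] |= (dist <= radius_mm).astype(np.uint8)


def generate_subject(spec: PhantomSpec, seed: int | None, subject_id: str = "S1") -> SyntheticSubject:
    """Generate one phantom subject; deterministic for a fixed (spec, seed)."""
    rng = np.random.default_rng(seed)
    j = spec.subject_jitter
    s_lin = 1.0 + rng.uniform(-j.scale, j.scale)
    s_vol = s_lin**3
    structures = {}
    for hemi in HEMISPHERES:
        t_th = rng.uniform(-j.translation_mm, j.translation_mm, 3)
        t_vlv = rng.uniform(-j.translation_mm / 2, j.translation_mm / 2, 3)
        t_vim = rng.uniform(-j.translation_mm / 2, j.translation_mm / 2, 3)
        hemi_masks = _hemisphere_structures(spec, hemi, t_th, t_vlv, t_vim, s_vol)
        for name, mask in hemi_masks.items():
            structures[(name, hemi)] = mask

    intensity, vessel_mask = _paint_intensity(spec, structures, rng)

    grid = spec.grid
    z_top = max(
        grid.voxel_to_world(np.argwhere(structures[("thalamus", h)].data))[:, 2].max()
        for h in HEMISPHERES
    )
    landmarks = LandmarkSet(
        ac=(0.0, 0.0, 0.0),
        pc=(0.0, -25.0, 0.0),
        thalamus_height_mm=float(z_top),
        third_ventricle_wall_x_mm={"left": 2.0, "right": 2.0},
    )

    realized = {}
    for hemi in HEMISPHERES:
        th = structures[("thalamus", hemi)].volume_mm3
        realized[hemi] = {
            "thalamus_mm3": th,
            "vlv_mm3": structures[("vlv", hemi)].volume_mm3,
            "vim_mm3": structures[("vim", hemi)].volume_mm3,
            "vlv_pct": 100.0 * structures[("vlv", hemi)].volume_mm3 / th,
            "vim_pct": 100.0 * structures[("vim", hemi)].volume_mm3 / th,
        }
    return SyntheticSubject(subject_id, spec, structures, intensity, landmarks, vessel_mask, realized)


def generate_cohort(spec: PhantomSpec, n: int, seed: int | None) -> list[SyntheticSubject]:
    """Generate ``n`` subjects with per-subject seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [
        generate_subject(spec, int(child_seeds[i]) & 0x7FFFFFFF, subject_id=f"S{i + 1:02d}")
        for i in range(n)
    ]


def vim_contrast_sd(subject: SyntheticSubject, hemisphere: str, shell_voxels: int = 3) -> float:
    """Vim-to-surround intensity contrast in units of the noise sd.

    The surround is a ``shell_voxels``-voxel dilation shell around the Vim,
    restricted to the thalamus.
    """
    vim = subject.mask("vim", hemisphere).data > 0
    th = subject.mask("thalamus", hemisphere).data > 0
    struct = ndimage.generate_binary_structure(3, 1)
    shell = ndimage.binary_dilation(vim, struct, iterations=shell_voxels) & ~vim & th
    img = subject.intensity.data
    return float((img[vim].mean() - img[shell].mean()) / subject.spec.swi_params.noise_sd)
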