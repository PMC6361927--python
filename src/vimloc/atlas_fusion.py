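"""Multi-atlas Vim segmentation: VOI, intensity standardization, label fusion.

The pipeline mirrors a standard multi-atlas workflow on co-registered
images: crop a volume of interest (VOI) around the thalamus, standardize
SWI intensities across subjects with decile-landmark histogram matching
(piecewise-linear mapping of the percentiles p1, p10, ..., p90, p99 onto a
shared standard scale), then propagate the atlases' Vim labels onto the
target and fuse them.

Three fusion rules are provided:

* ``majority`` — unweighted vote;
* ``local_weighted`` — atlas weights proportional to
  ``exp(-beta * MSD_i(v))`` with ``MSD_i`` the mean squared intensity
  difference over a cubic patch around ``v``;
* ``joint`` — weights ``w = (M + eps I)^-1 1`` normalized to sum 1, where
  ``M_ij(v)`` is the patch mean of ``|I_i - T| * |I_j - T|``, so that
  atlases making correlated errors share (rather than accumulate) weight.
  Negative solutions are clipped to zero and renormalized so that fused
  probabilities stay in [0, 1].

Registration is out of scope: atlases are assumed to live on the target
grid already (phantom cohorts share one grid by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .overlap_metrics import dice
from .volume_io import IntensityVolume, ROIMask, VoxelGrid

__all__ = [
    "PERCENTILES",
    "StandardScale",
    "FusionParams",
    "AtlasCase",
    "VOI",
    "extract_voi",
    "crop_to_voi",
    "build_standard_scale",
    "intensity_landmarks",
    "standardize_intensities",
    "fuse_labels",
    "FusionResult",
    "loo_experiment",
]

#: histogram landmarks: robust extrema plus deciles
PERCENTILES = np.array([1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99], dtype=float)

_MIN_MASK_VOXELS = 100


@dataclass(frozen=True)
class StandardScale:
    """Percentile landmarks mapped onto a fixed standard intensity range."""

    landmarks: tuple
    s_min: float = 0.0
    s_max: float = 100.0

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.ndim != 1 or len(lm) != len(PERCENTILES):
            raise ValueError(f"expected {len(PERCENTILES)} landmarks, got {lm.shape}")
        if np.any(np.diff(lm) < 0):
            raise ValueError("standard-scale landmarks must be non-decreasing")
        if not self.s_min < self.s_max:
            raise ValueError("s_min must be smaller than s_max")
        object.__setattr__(self, "landmarks", tuple(float(v) for v in lm))


@dataclass(frozen=True)
class FusionParams:
    method: str = "joint"
    patch_radius_voxels: int = 2
    beta: float = 1.0
    epsilon: float = 1e-6
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("majority", "local_weighted", "joint"):
            raise ValueError(f"unknown fusion method {self.method!r}")
        if self.patch_radius_voxels < 0:
            raise ValueError("patch_radius_voxels must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must lie in (0, 1)")


@dataclass
class AtlasCase:
    """One co-registered atlas: standardized intensity plus its Vim label."""

    subject_id: str
    intensity: np.ndarray
    vim_label: np.ndarray
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.intensity.shape != self.vim_label.shape:
            raise ValueError("atlas intensity and label must share one grid")


@dataclass
class VOI:
    """A cropped sub-volume with bookkeeping back to the parent grid."""

    data: np.ndarray
    grid: VoxelGrid
    offset: tuple[int, int, int]
    parent_shape: tuple[int, int, int]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + n) for o, n in zip(self.offset, self.data.shape))

    def to_parent_index(self, ijk) -> np.ndarray:
        return np.asarray(ijk) + np.asarray(self.offset)

    def embed(self, fill=0) -> np.ndarray:
        out = np.full(self.parent_shape, fill, dtype=self.data.dtype)
        out[self.slices] = self.data
        return out


def extract_voi(volume: IntensityVolume, thalamus: ROIMask, margin_mm: float = 2.0) -> VOI:
    """Crop the volume to the thalamus bounding box dilated by ``margin_mm``."""
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    if volume.grid != thalamus.grid:
        raise ValueError("volume and thalamus live on different grids")
    if thalamus.voxel_count == 0:
        raise ValueError("thalamus mask is empty")
    grid = volume.grid
    idx = np.argwhere(thalamus.data)
    margin_vox = np.ceil(margin_mm / np.asarray(grid.spacing)).astype(int)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + margin_vox + 1, grid.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = volume.data[sl]
    sub_grid = VoxelGrid(sub.shape, grid.spacing, tuple(grid.voxel_to_world(lo)))
    return VOI(sub, sub_grid, tuple(int(v) for v in lo), grid.shape)


def crop_to_voi(data: np.ndarray, voi: VOI) -> np.ndarray:
    """Crop a parent-grid array with a VOI's bounding slices."""
    if tuple(data.shape) != voi.parent_shape:
        raise ValueError("array shape does not match the VOI's parent grid")
    return data[voi.slices]


def intensity_landmarks(values: np.ndarray) -> np.ndarray:
    """Percentile landmarks of a masked intensity sample."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < _MIN_MASK_VOXELS:
        raise ValueError(
            f"need at least {_MIN_MASK_VOXELS} masked voxels for stable percentiles, "
            f"got {values.size}"
        )
    lm = np.percentile(values, PERCENTILES)
    if lm[0] == lm[-1]:
        raise ValueError("degenerate (constant) intensity sample; landmarks collapse")
    return lm


def build_standard_scale(
    vois: list, masks: list | None = None, s_min: float = 0.0, s_max: float = 100.0
) -> StandardScale:
    """Average the per-subject landmark vectors and map them onto [s_min, s_max].

    ``vois`` is a list of arrays (or VOI objects); ``masks`` an optional
    matching list of binary arrays restricting the histogram sample.
    """
    if len(vois) == 0:
        raise ValueError("at least one VOI is required")
    all_lm = []
    for i, voi in enumerate(vois):
        data = voi.data if isinstance(voi, VOI) else np.asarray(voi, dtype=float)
        vals = data[np.asarray(masks[i]) > 0] if masks is not None else data
        all_lm.append(intensity_landmarks(vals))
    mean_lm = np.mean(all_lm, axis=0)
    span = mean_lm[-1] - mean_lm[0]
    scaled = s_min + (mean_lm - mean_lm[0]) / span * (s_max - s_min)
    return StandardScale(tuple(scaled), s_min, s_max)


def standardize_intensities(
    data: np.ndarray, scale: StandardScale, mask: np.ndarray | None = None
) -> np.ndarray:
    """Map a volume onto the standard scale by piecewise-linear interpolation.

    The volume's own landmarks (computed within ``mask`` if given) are sent
    onto the scale's landmarks; values beyond the terminal landmarks are
    extrapolated linearly along the terminal segments.  The map is monotone
    non-decreasing.
    """
    data = np.asarray(data, dtype=float)
    vals = data[np.asarray(mask) > 0] if mask is not None else data
    in_lm = intensity_landmarks(vals)
    if np.any(np.diff(in_lm) <= 0):
        raise ValueError("input landmarks are not strictly increasing; cannot invert the map")
    out_lm = np.asarray(scale.landmarks)
    out = np.interp(data, in_lm, out_lm)
    lo_slope = (out_lm[1] - out_lm[0]) / (in_lm[1] - in_lm[0])
    hi_slope = (out_lm[-1] - out_lm[-2]) / (in_lm[-1] - in_lm[-2])
    below = data < in_lm[0]
    above = data > in_lm[-1]
    out[below] = out_lm[0] + (data[below] - in_lm[0]) * lo_slope
    out[above] = out_lm[-1] + (data[above] - in_lm[-1]) * hi_slope
    return out


@dataclass
class FusionResult:
    mask: np.ndarray
    probability: np.ndarray
    weights: np.ndarray  # (n_atlases, *shape)
    params: FusionParams


def _patch_mean(arr: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return arr
    # zero-padded cubic patch mean
    size = 2 * radius + 1
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0)


def fuse_labels(target: np.ndarray, atlases: list, params: FusionParams | None = None) -> FusionResult:
    """Fuse the atlases' Vim labels onto a target intensity volume.

    ``target`` is the standardized target VOI; ``atlases`` a list of
    :class:`AtlasCase` on the same grid.  Returns the fused binary mask
    (probability >= decision threshold), the per-voxel fused probability
    and the per-atlas weight field (weights sum to 1 at every voxel).
    """
    params = params or FusionParams()
    if len(atlases) == 0:
        raise ValueError("at least one atlas is required")
    target = np.asarray(target, dtype=float)
    for a in atlases:
        if a.intensity.shape != target.shape:
            raise ValueError(f"atlas {a.subject_id} is not on the target grid")
    n = len(atlases)
    labels = np.stack([np.asarray(a.vim_label, dtype=float) for a in atlases])

    if params.method == "majority":
        weights = np.full((n,) + target.shape, 1.0 / n)
    elif params.method == "local_weighted":
        msd = np.stack(
            [
                _patch_mean((np.asarray(a.intensity, float) - target) ** 2, params.patch_radius_voxels)
                for a in atlases
            ]
        )
        # subtract the per-voxel minimum before exponentiating for stability
        logw = -params.beta * (msd - msd.min(axis=0, keepdims=True))
        weights = np.exp(logw)
        weights /= weights.sum(axis=0, keepdims=True)
    else:  # joint
        absdiff = [np.abs(np.asarray(a.intensity, float) - target) for a in atlases]
        m = np.empty(target.shape + (n, n))
        for i in range(n):
            for j in range(i, n):
                mij = _patch_mean(absdiff[i] * absdiff[j], params.patch_radius_voxels)
                m[..., i, j] = mij
                m[..., j, i] = mij
        m = m.reshape(-1, n, n)
        m[:, np.arange(n), np.arange(n)] += params.epsilon
        w = np.linalg.solve(m, np.ones((m.shape[0], n, 1)))[..., 0]
        w = np.clip(w, 0.0, None)
        norm = w.sum(axis=1, keepdims=True)
        degenerate = norm[:, 0] <= 0
        w[degenerate] = 1.0 / n
        norm[degenerate] = 1.0
        w /= norm
        weights = np.moveaxis(w.reshape(target.shape + (n,)), -1, 0)

    probability = np.einsum("a...,a...->...", weights, labels)
    mask = probability >= params.decision_threshold
    return FusionResult(mask.astype(np.uint8), probability, weights, params)


def loo_experiment(cohort: list, params: FusionParams | None = None, margin_mm: float = 2.0) -> dict:
    """Leave-one-out multi-atlas evaluation on a phantom cohort.

    For each target subject and hemisphere: crop a VOI around the target's
    thalamus, build the standard intensity scale from the *training*
    subjects' thalamic samples, standardize everyone, fuse the training
    subjects' Vim labels onto the target, and score Dice against the
    target's ground-truth Vim.  The target's own delineation is never used
    as an atlas.  Returns per-case records plus the cohort mean ± sample sd.
    """
    params = params or FusionParams()
    if len(cohort) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    grid = cohort[0].spec.grid
    for s in cohort:
        if s.spec.grid != grid:
            raise ValueError("all cohort subjects must share one grid")

    records = []
    for t_idx, target_subj in enumerate(cohort):
        training = [s for i, s in enumerate(cohort) if i != t_idx]
        for hemi in ("left", "right"):
            voi = extract_voi(target_subj.intensity, target_subj.mask("thalamus", hemi), margin_mm)
            train_int = [crop_to_voi(s.intensity.data, voi) for s in training]
            train_masks = [crop_to_voi(s.mask("thalamus", hemi).data, voi) for s in training]
            scale = build_standard_scale(train_int, train_masks)
            target_std = standardize_intensities(
                voi.data, scale, crop_to_voi(target_subj.mask("thalamus", hemi).data, voi)
            )
            atlases = [
                AtlasCase(
                    s.subject_id,
                    standardize_intensities(ti, scale, tm),
                    crop_to_voi(s.mask("vim", hemi).data, voi),
                    hemi,
                )
                for s, ti, tm in zip(training, train_int, train_masks)
            ]
            result = fuse_labels(target_std, atlases, params)
            fused = ROIMask(voi.grid, result.mask)
            truth = ROIMask(voi.grid, crop_to_voi(target_subj.mask("vim", hemi).data, voi))
            records.append(
                {
                    "subject_id": target_subj.subject_id,
                    "hemisphere": hemi,
                    "dice": dice(fused, truth),
                    "fused_mask": fused,
                    "voi": voi,
                }
            )
    dices = np.array([r["dice"] for r in records])
    return {
        "records": records,
        "mean_dice": float(dices.mean()),
        "sd_dice": float(dices.std(ddof=1)),
    }
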