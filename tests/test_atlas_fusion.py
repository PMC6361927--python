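import dataclasses

import numpy as np
import pytest

from vimloc.atlas_fusion import (
    PERCENTILES,
    AtlasCase,
    FusionParams,
    StandardScale,
    build_standard_scale,
    crop_to_voi,
    extract_voi,
    fuse_labels,
    intensity_landmarks,
    loo_experiment,
    standardize_intensities,
)
from vimloc.overlap_metrics import dice
from vimloc.synthetic_anatomy import JitterParams, PhantomSpec, generate_cohort
from vimloc.volume_io import IntensityVolume, ROIMask, VoxelGrid


@pytest.fixture
def grid():
    return VoxelGrid((20, 20, 20))


def thalamus_mask(grid):
    data = np.zeros(grid.shape)
    data[4:15, 5:16, 6:14] = 1
    return ROIMask(grid, data)


class TestExtractVoi:
    def test_zero_margin_equals_bounding_box(self, grid):
        vol = IntensityVolume(grid, np.random.default_rng(0).normal(size=grid.shape))
        voi = extract_voi(vol, thalamus_mask(grid), margin_mm=0.0)
        assert voi.offset == (4, 5, 6)
        assert voi.data.shape == (11, 11, 8)

    def test_margin_grows_by_ceil_voxels(self, grid):
        vol = IntensityVolume(grid, np.zeros(grid.shape))
        voi = extract_voi(vol, thalamus_mask(grid), margin_mm=2.0)  # 5 voxels at 0.4 mm
        assert voi.offset == (0, 0, 1)
        assert voi.data.shape == (20, 20, 18)  # clipped at the image edge

    def test_offset_bookkeeping_recovers_world_coordinates(self, grid):
        vol = IntensityVolume(grid, np.zeros(grid.shape))
        voi = extract_voi(vol, thalamus_mask(grid), margin_mm=0.8)
        ijk_voi = (3, 2, 1)
        world_from_voi = voi.grid.voxel_to_world(ijk_voi)
        world_from_parent = grid.voxel_to_world(voi.to_parent_index(ijk_voi))
        np.testing.assert_allclose(world_from_voi, world_from_parent)

    def test_negative_margin_rejected(self, grid):
        with pytest.raises(ValueError):
            extract_voi(IntensityVolume(grid, np.zeros(grid.shape)), thalamus_mask(grid), -1.0)


class TestStandardScale:
    def test_single_voi_scale_is_own_landmarks_affinely_mapped(self):
        rng = np.random.default_rng(1)
        data = rng.normal(50, 10, size=5000)
        scale = build_standard_scale([data])
        lm = intensity_landmarks(data)
        expected = (lm - lm[0]) / (lm[-1] - lm[0]) * 100.0
        np.testing.assert_allclose(scale.landmarks, expected, atol=1e-9)

    def test_shifted_pair_averages_to_midpoint(self):
        rng = np.random.default_rng(2)
        x = rng.normal(50, 10, size=5000)
        c = 7.5
        scale_pair = build_standard_scale([x, x + c])
        scale_mid = build_standard_scale([x + c / 2])
        np.testing.assert_allclose(scale_pair.landmarks, scale_mid.landmarks, atol=1e-9)

    def test_constant_intensities_rejected(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            build_standard_scale([np.full(500, 3.0)])

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="100"):
            build_standard_scale([np.arange(50, dtype=float)])

    def test_non_monotone_scale_rejected(self):
        bad = np.linspace(0, 100, len(PERCENTILES))
        bad[3] = bad[2] - 5
        with pytest.raises(ValueError):
            StandardScale(tuple(bad))


class TestStandardization:
    def test_identity_on_already_standard_input(self):
        data = np.linspace(0.0, 100.0, 4000)
        scale = StandardScale(tuple(intensity_landmarks(data)))
        out = standardize_intensities(data, scale)
        np.testing.assert_allclose(out, data, atol=1e-9)

    def test_affine_input_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(40, 8, size=(12, 12, 12))
        scale = build_standard_scale([rng.normal(40, 8, size=4000)])
        ref = standardize_intensities(x, scale)
        warped = standardize_intensities(2.3 * x + 11.0, scale)
        np.testing.assert_allclose(warped, ref, rtol=1e-6, atol=1e-8)

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.normal(0, 5, size=3000))
        scale = build_standard_scale([rng.normal(0, 5, size=3000)])
        out = standardize_intensities(x, scale)
        assert np.all(np.diff(out) >= 0)

    def test_tied_landmarks_rejected(self):
        # half the sample is one constant value, collapsing several deciles
        data = np.concatenate([np.full(2000, 5.0), np.linspace(0, 10, 2000)])
        scale = StandardScale(tuple(np.linspace(0, 100, len(PERCENTILES))))
        with pytest.raises(ValueError, match="strictly increasing"):
            standardize_intensities(data, scale)


def _make_atlases(rng, shape, labels, intensities=None):
    out = []
    for i, lab in enumerate(labels):
        intensity = intensities[i] if intensities is not None else rng.normal(size=shape)
        out.append(AtlasCase(f"A{i}", np.asarray(intensity, float), np.asarray(lab, float)))
    return out


class TestFuseLabels:
    @pytest.mark.parametrize("method", ["majority", "local_weighted", "joint"])
    def test_consensus_is_reproduced_exactly(self, method):
        rng = np.random.default_rng(5)
        shape = (9, 9, 9)
        label = (rng.random(shape) > 0.8).astype(float)
        atlases = _make_atlases(rng, shape, [label] * 4)
        result = fuse_labels(rng.normal(size=shape), atlases, FusionParams(method=method))
        np.testing.assert_array_equal(result.mask, label.astype(np.uint8))

    @pytest.mark.parametrize("method", ["majority", "local_weighted", "joint"])
    def test_weights_sum_to_one_and_probability_bounded(self, method):
        rng = np.random.default_rng(6)
        shape = (8, 8, 8)
        labels = [(rng.random(shape) > 0.7).astype(float) for _ in range(3)]
        atlases = _make_atlases(rng, shape, labels)
        result = fuse_labels(rng.normal(size=shape), atlases, FusionParams(method=method))
        np.testing.assert_allclose(result.weights.sum(axis=0), 1.0, atol=1e-9)
        assert result.probability.min() >= -1e-12
        assert result.probability.max() <= 1 + 1e-12

    def test_local_weighting_prefers_matching_atlas(self):
        shape = (9, 9, 9)
        rng = np.random.default_rng(7)
        target = rng.normal(size=shape)
        # atlas 0 matches the target exactly; atlas 1 is far off
        intensities = [target.copy(), target + 10.0]
        labels = [np.ones(shape), np.zeros(shape)]
        atlases = _make_atlases(rng, shape, labels, intensities)
        result = fuse_labels(target, atlases, FusionParams(method="local_weighted", beta=1.0))
        assert result.mask.all()

    def test_joint_downweights_mismatching_atlas(self):
        shape = (9, 9, 9)
        rng = np.random.default_rng(8)
        target = rng.normal(size=shape)
        intensities = [target + 5.0, target.copy()]
        labels = [np.ones(shape), np.zeros(shape)]
        atlases = _make_atlases(rng, shape, labels, intensities)
        result = fuse_labels(target, atlases, FusionParams(method="joint"))
        # the matching atlas (absdiff ~ 0) should dominate the vote
        assert not result.mask.any()

    def test_majority_two_of_three(self):
        shape = (5, 5, 5)
        rng = np.random.default_rng(9)
        labels = [np.ones(shape), np.ones(shape), np.zeros(shape)]
        atlases = _make_atlases(rng, shape, labels)
        result = fuse_labels(rng.normal(size=shape), atlases, FusionParams(method="majority"))
        np.testing.assert_allclose(result.probability, 2 / 3)
        assert result.mask.all()

    def test_small_beta_recovers_majority(self):
        shape = (7, 7, 7)
        rng = np.random.default_rng(10)
        labels = [(rng.random(shape) > 0.6).astype(float) for _ in range(3)]
        atlases = _make_atlases(rng, shape, labels)
        target = rng.normal(size=shape)
        soft = fuse_labels(target, atlases, FusionParams(method="local_weighted", beta=1e-9))
        hard = fuse_labels(target, atlases, FusionParams(method="majority"))
        np.testing.assert_allclose(soft.probability, hard.probability, atol=1e-6)

    def test_atlases_disjoint_from_truth_give_dice_zero(self, grid):
        shape = grid.shape
        rng = np.random.default_rng(11)
        label = np.zeros(shape)
        label[2:5, 2:5, 2:5] = 1
        truth = np.zeros(shape)
        truth[10:13, 10:13, 10:13] = 1
        atlases = _make_atlases(rng, shape, [label] * 3)
        result = fuse_labels(rng.normal(size=shape), atlases, FusionParams(method="majority"))
        assert dice(ROIMask(grid, result.mask), ROIMask(grid, truth)) == 0.0

    def test_no_atlases_rejected(self):
        with pytest.raises(ValueError):
            fuse_labels(np.zeros((4, 4, 4)), [], FusionParams())


class TestLooExperiment:
    def test_identical_cohort_gives_perfect_dice(self):
        spec = dataclasses.replace(
            PhantomSpec(), subject_jitter=JitterParams(translation_mm=0.0, scale=0.0)
        )
        cohort = generate_cohort(spec, 3, seed=5)
        res = loo_experiment(cohort, FusionParams(method="majority"))
        assert res["mean_dice"] == pytest.approx(1.0)

    def test_too_small_cohort_rejected(self):
        cohort = generate_cohort(PhantomSpec(), 2, seed=5)
        with pytest.raises(ValueError):
            loo_experiment(cohort)
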