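import numpy as np
import pytest

from vimloc.guiot_targeting import (
    GuiotParams,
    GuiotTarget,
    LandmarkSet,
    TargetingSession,
    construct_guiot_target,
    session_within_one_voxel,
    simulate_repeated_targeting,
    sphere_roi,
    targeting_reproducibility,
)
from vimloc.volume_io import VoxelGrid


@pytest.fixture
def landmarks():
    return LandmarkSet(
        ac=(0.0, 12.5, 0.0),
        pc=(0.0, -12.5, 0.0),
        thalamus_height_mm=16.0,
        third_ventricle_wall_x_mm={"left": 2.0, "right": 2.0},
    )


@pytest.fixture
def grid():
    return VoxelGrid((128, 128, 128), (0.4, 0.4, 0.4), (-25.4, -25.4, -25.4))


class TestConstruction:
    def test_default_target_coordinates(self, landmarks):
        t = construct_guiot_target(landmarks, "right")
        assert t.point[0] == pytest.approx(13.0)  # wall 2 mm + 11 mm laterality
        assert t.point[1] == pytest.approx(-12.5 + 0.25 * 25.0)
        assert t.point[2] == pytest.approx(0.0)

    def test_left_right_mirror(self, landmarks):
        left = construct_guiot_target(landmarks, "left")
        right = construct_guiot_target(landmarks, "right")
        assert left.point[0] == -right.point[0]
        assert left.point[1:] == right.point[1:]

    def test_translation_equivariance(self, landmarks):
        t = np.array([1.3, -2.1, 0.7])
        base = construct_guiot_target(landmarks, "right").point
        moved = construct_guiot_target(landmarks.translated(t), "right").point
        np.testing.assert_allclose(np.asarray(moved)[1:], np.asarray(base)[1:] + t[1:], atol=1e-12)

    def test_hemisphere_mismatch_rejected(self, landmarks):
        pinned = LandmarkSet(
            ac=landmarks.ac,
            pc=landmarks.pc,
            thalamus_height_mm=landmarks.thalamus_height_mm,
            third_ventricle_wall_x_mm=landmarks.third_ventricle_wall_x_mm,
            hemisphere="left",
        )
        with pytest.raises(ValueError, match="pinned"):
            construct_guiot_target(pinned, "right")

    def test_invalid_landmarks_rejected(self):
        with pytest.raises(ValueError, match="anterior"):
            LandmarkSet((0, -1, 0), (0, 1, 0), 16.0, {"left": 2.0})

    def test_landmarks_json_roundtrip(self, landmarks, tmp_path):
        landmarks.to_json(tmp_path / "lm.json")
        back = LandmarkSet.from_json(tmp_path / "lm.json")
        assert back == landmarks


class TestRepeatedTargeting:
    def test_zero_jitter_gives_identical_points(self, landmarks, grid):
        session = simulate_repeated_targeting(landmarks, "right", grid, jitter_mm=0.0, seed=1)
        pts = session.quantized_points()
        assert np.ptp(pts, axis=0).max() == 0.0

    @pytest.mark.parametrize("seed", range(50))
    def test_half_voxel_jitter_stays_within_one_voxel(self, landmarks, grid, seed):
        session = simulate_repeated_targeting(landmarks, "right", grid, jitter_mm=0.2, seed=seed)
        assert session_within_one_voxel(session)

    def test_deterministic_for_fixed_seed(self, landmarks, grid):
        a = simulate_repeated_targeting(landmarks, "left", grid, seed=11).quantized_points()
        b = simulate_repeated_targeting(landmarks, "left", grid, seed=11).quantized_points()
        np.testing.assert_array_equal(a, b)

    def test_negative_jitter_rejected(self, landmarks, grid):
        with pytest.raises(ValueError):
            simulate_repeated_targeting(landmarks, "right", grid, jitter_mm=-0.1)

    def test_too_few_repetitions_rejected(self, landmarks, grid):
        with pytest.raises(ValueError):
            simulate_repeated_targeting(landmarks, "right", grid, n_rep=1)


def _session_from_points(points, grid):
    params = GuiotParams()
    lm = LandmarkSet((0, 12.5, 0), (0, -12.5, 0), 16.0, {"right": 2.0})
    targets = [
        GuiotTarget(tuple(p), "right", params, lm, quantized_point=tuple(p)) for p in points
    ]
    return TargetingSession(targets, grid, jitter_mm=0.0)


class TestReproducibility:
    def test_identical_points_zero_distances(self, grid):
        rep = targeting_reproducibility(_session_from_points([(1, 2, 3)] * 4, grid))
        assert rep["max_mm"] == 0.0 and rep["mean_mm"] == 0.0

    def test_one_voxel_diagonal_distance(self, grid):
        rep = targeting_reproducibility(
            _session_from_points([(0, 0, 0), (0.4, 0.4, 0.4)], grid)
        )
        assert rep["max_mm"] == pytest.approx(np.sqrt(3 * 0.16))

    def test_single_displaced_point_statistics(self, grid):
        pts = [(0, 0, 0)] * 6
        pts[3] = (0.4, 0.0, 0.0)
        rep = targeting_reproducibility(_session_from_points(pts, grid))
        assert rep["max_mm"] == pytest.approx(0.4)
        assert rep["mean_mm"] == pytest.approx(0.4 / 6)

    def test_requires_two_targets(self, grid):
        with pytest.raises(ValueError):
            _session_from_points([(0, 0, 0)], grid)


class TestSphereRoi:
    def bruteforce_count(self, center_ijk, radius, grid):
        """Exact integer-lattice enumeration for a center on a voxel center.

        With isotropic spacing s, a voxel at integer offset (di, dj, dk) is
        inside iff s^2 (di^2+dj^2+dk^2) <= r^2 — evaluated in exact integer
        arithmetic (spacing 0.4, r 2.0 => di^2+dj^2+dk^2 <= 25).
        """
        limit_sq = 25  # (radius / spacing)^2 = (2.0 / 0.4)^2
        assert (radius / grid.spacing[0]) ** 2 == pytest.approx(limit_sq)
        count = 0
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                for k in range(grid.shape[2]):
                    di, dj, dk = i - center_ijk[0], j - center_ijk[1], k - center_ijk[2]
                    if di * di + dj * dj + dk * dk <= limit_sq:
                        count += 1
        return count

    def test_count_matches_bruteforce(self):
        grid = VoxelGrid((16, 16, 16), (0.4, 0.4, 0.4), (-3.0, -3.0, -3.0))
        center = grid.voxel_to_world((8, 8, 8))
        mask = sphere_roi(center, 2.0, grid)
        assert mask.voxel_count == self.bruteforce_count((8, 8, 8), 2.0, grid)
        # ~4/3 pi r^3 within discretization error
        assert mask.volume_mm3 == pytest.approx(4 / 3 * np.pi * 8.0, rel=0.06)

    def test_subvoxel_radius_gives_single_voxel(self):
        grid = VoxelGrid((8, 8, 8))
        mask = sphere_roi(grid.voxel_to_world((4, 4, 4)), 0.19, grid)
        assert mask.voxel_count == 1

    def test_lattice_translation_invariance(self):
        grid = VoxelGrid((24, 24, 24))
        c0 = grid.voxel_to_world((8, 8, 8))
        c1 = grid.voxel_to_world((13, 10, 9))
        assert sphere_roi(c0, 1.5, grid).voxel_count == sphere_roi(c1, 1.5, grid).voxel_count

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            sphere_roi((0, 0, 0), 0.0, VoxelGrid((4, 4, 4)))
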