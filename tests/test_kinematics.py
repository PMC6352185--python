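"""Kinematic indicators: oracles, analytic cases and invariance properties."""

import numpy as np
import pytest

from mocapskill import (
    InsufficientDataError,
    KinematicsConfig,
    SyntheticSpec,
    compute_indicators,
    count_collisions,
    count_high_accel,
    economy_of_motion,
    generate_recording,
    task_time,
    used_workspace,
)
from mocapskill.kinematics import acceleration_magnitude, count_runs
from conftest import make_recording, random_walk_recording


def brute_force_runs(mask):
    """Frame-by-frame run-length scan (independent of the vectorised count)."""
    runs, inside = 0, False
    for flag in mask:
        if flag and not inside:
            runs += 1
        inside = bool(flag)
    return runs


def brute_force_path(pos):
    return sum(
        float(np.sqrt(((pos[i + 1] - pos[i]) ** 2).sum())) for i in range(len(pos) - 1)
    )


class TestTaskTime:
    def test_uniform_grid(self):
        n = 101
        rec = make_recording(np.zeros((n, 3)), np.zeros((n, 3)))
        assert task_time(rec) == pytest.approx(4.0)

    def test_two_frames(self):
        rec = make_recording(np.zeros((2, 3)), np.zeros((2, 3)), t=np.array([1.0, 2.5]))
        assert task_time(rec) == pytest.approx(1.5)

    def test_frame_count_rate_identity(self):
        # 2076 frames at 25 fps span (n-1)/fps = 83 s
        n = 2076
        rec = make_recording(np.zeros((n, 3)), np.zeros((n, 3)))
        assert task_time(rec) == pytest.approx(83.0)


class TestCollisions:
    def test_far_hands_never_collide(self, kin_cfg):
        n = 50
        right = np.tile([500.0, 0, 0], (n, 1))
        rec = make_recording(np.zeros((n, 3)), right)
        assert count_collisions(rec, kin_cfg) == 0

    def test_occasions_are_runs_not_frames(self, kin_cfg):
        distances = [150, 90, 80, 150, 95, 150]
        left = np.zeros((6, 3))
        right = np.array([[d, 0.0, 0.0] for d in distances])
        rec = make_recording(left, right)
        assert count_collisions(rec, kin_cfg) == 2

    def test_matches_brute_force_on_random_walks(self, rng, kin_cfg):
        for _ in range(30):
            rec = random_walk_recording(rng, n_frames=80, step_mm=60.0, offset=(120.0, 0, 0))
            dist = np.linalg.norm(rec.left.pos - rec.right.pos, axis=1)
            expected = brute_force_runs(dist < kin_cfg.collision_threshold)
            assert count_collisions(rec, kin_cfg) == expected

    def test_count_runs_equals_scan(self, rng):
        for _ in range(50):
            mask = rng.random(40) < 0.3
            assert count_runs(mask) == brute_force_runs(mask)


class TestHighAcceleration:
    def test_constant_velocity_has_none(self, kin_cfg):
        n = 100
        t = np.arange(n) / 25.0
        pos = np.outer(t, [50.0, 0, 0])  # 50 mm/s straight line
        rec = make_recording(pos, pos + [300.0, 0, 0])
        assert count_high_accel(rec, kin_cfg) == 0

    def test_single_burst_detected_once(self):
        # right hand accelerates at 15 m/s^2 for 0.2 s, otherwise coasts
        fps, n = 25.0, 200
        t = np.arange(n) / fps
        accel = np.where((t >= 4.0) & (t < 4.2), 15000.0, 0.0)  # mm/s^2
        vel = np.cumsum(accel) / fps
        x = np.concatenate(([0.0], np.cumsum(vel[:-1]) / fps))
        right = np.column_stack([x, np.zeros(n), np.zeros(n)])
        rec = make_recording(np.tile([400.0, 0, 0], (n, 1)), right)
        cfg = KinematicsConfig(smoothing_window=1)
        assert count_high_accel(rec, cfg) == 1
        acc = acceleration_magnitude(right, t, smoothing_window=1)
        interior = (t >= 4.05) & (t < 4.15)
        np.testing.assert_allclose(acc[interior], 15.0, rtol=1e-6)

    def test_run_count_matches_brute_force(self, rng, kin_cfg):
        for _ in range(20):
            rec = random_walk_recording(rng, n_frames=120, step_mm=35.0)
            expected = 0
            for track in (rec.left, rec.right):
                acc = acceleration_magnitude(
                    track.pos, track.t, smoothing_window=kin_cfg.smoothing_window
                )
                expected += brute_force_runs(acc > kin_cfg.accel_threshold)
            assert count_high_accel(rec, kin_cfg) == expected

    def test_too_short_recording_raises(self, kin_cfg):
        rec = make_recording(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(InsufficientDataError):
            count_high_accel(rec, kin_cfg)


class TestEconomyOfMotion:
    def test_stationary_hands(self):
        rec = make_recording(np.zeros((10, 3)), np.ones((10, 3)))
        assert economy_of_motion(rec) == (0.0, 0.0, 0.0)

    def test_straight_line_path(self):
        n = 11
        right = np.column_stack([np.linspace(0, 100, n), np.zeros(n), np.zeros(n)])
        rec = make_recording(np.zeros((n, 3)), right)
        left, right_len, mean = economy_of_motion(rec)
        assert (left, right_len, mean) == pytest.approx((0.0, 100.0, 50.0))

    def test_matches_brute_force_on_jittery_path(self, rng):
        rec = random_walk_recording(rng, n_frames=100, step_mm=15.0)
        left, right, mean = economy_of_motion(rec)
        assert left == pytest.approx(brute_force_path(rec.left.pos), rel=1e-12)
        assert right == pytest.approx(brute_force_path(rec.right.pos), rel=1e-12)
        assert mean == pytest.approx((left + right) / 2)

    def test_downsampling_never_lengthens_path(self):
        spec = SyntheticSpec(seed=5, tremor_sd=0.0, twitch_rate=0.0)
        rec = generate_recording(spec)
        full = economy_of_motion(rec)[1]
        half = make_recording(rec.left.pos[::2], rec.right.pos[::2], t=rec.left.t[::2])
        assert economy_of_motion(half)[1] <= full + 1e-9


class TestUsedWorkspace:
    CUBE = np.array(
        [[0, 0, 0], [100, 0, 0], [0, 100, 0], [0, 0, 100],
         [100, 100, 0], [100, 0, 100], [0, 100, 100], [100, 100, 100]],
        dtype=float,
    )

    def test_cube_corners_both_methods(self):
        rec = make_recording(np.tile([50.0, 50, 50], (8, 1)), self.CUBE)
        assert used_workspace(rec, KinematicsConfig()) == pytest.approx(1e6)
        assert used_workspace(rec, KinematicsConfig(hull_method="aabb")) == pytest.approx(1e6)

    def test_unit_tetrahedron_volume(self):
        tetra = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        rec = make_recording(np.zeros((4, 3)), tetra)
        assert used_workspace(rec, KinematicsConfig()) == pytest.approx(1 / 6)

    def test_coplanar_points_degenerate_to_zero(self, caplog):
        n = 10
        planar = np.column_stack([np.arange(n), np.arange(n) ** 2, np.zeros(n)]).astype(float)
        rec = make_recording(planar, planar + [1.0, 0, 0])
        with caplog.at_level("WARNING"):
            assert used_workspace(rec, KinematicsConfig()) == 0.0
        assert "degenerate" in caplog.text

    def test_hull_bounded_by_aabb(self, rng):
        for _ in range(20):
            rec = random_walk_recording(rng, n_frames=40, step_mm=25.0)
            hull = used_workspace(rec, KinematicsConfig())
            aabb = used_workspace(rec, KinematicsConfig(hull_method="aabb"))
            assert hull <= aabb + 1e-9


class TestRigidMotionInvariance:
    @staticmethod
    def _rotate(rec, rot, shift):
        return make_recording(
            rec.left.pos @ rot.T + shift, rec.right.pos @ rot.T + shift, t=rec.left.t
        )

    def test_path_collisions_hull_invariant(self, rng, kin_cfg):
        rec = random_walk_recording(rng, n_frames=60, step_mm=40.0, offset=(150.0, 0, 0))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rot = q * np.linalg.det(q)  # proper rotation
        moved = self._rotate(rec, rot, np.array([500.0, -200.0, 80.0]))
        assert economy_of_motion(moved)[2] == pytest.approx(
            economy_of_motion(rec)[2], rel=1e-9
        )
        assert count_collisions(moved, kin_cfg) == count_collisions(rec, kin_cfg)
        assert used_workspace(moved, kin_cfg) == pytest.approx(
            used_workspace(rec, kin_cfg), rel=1e-7
        )


class TestComputeIndicators:
    def test_derivatives_are_exact_ratios(self):
        rec = generate_recording(SyntheticSpec(seed=3))
        ind = compute_indicators(rec)
        assert ind.workspace_per_time == pytest.approx(ind.workspace_mm3 / ind.time_s)
        assert ind.time_per_workspace == pytest.approx(ind.time_s / ind.workspace_mm3)
        assert ind.eom_per_time == pytest.approx(ind.eom_mean_mm / ind.time_s)
        assert ind.time_per_eom == pytest.approx(ind.time_s / ind.eom_mean_mm)

    def test_deterministic_given_recording_and_config(self):
        rec = generate_recording(SyntheticSpec(seed=9))
        assert compute_indicators(rec).as_dict() == compute_indicators(rec).as_dict()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KinematicsConfig(smoothing_window=4)
        with pytest.raises(ValueError):
            KinematicsConfig(collision_threshold=0)
        with pytest.raises(ValueError):
            KinematicsConfig(hull_method="sphere")
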