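"""Camera transforms, fusion, filtering, and the vector flexion angle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitmmc.kinematics import (
    FusedSkeletonSeries,
    angles_from_skeleton,
    flexion_angle,
    fuse_keypoints,
    lowpass,
    to_world,
    trial_angles,
)
from gaitmmc.types import (
    CameraExtrinsics,
    KeypointFrameSet,
    StatsConfig,
    ValidationError,
)

Y = np.array([0.0, 1.0, 0.0])


def _frames(positions, camera_id="c", rate=30.0, conf=None, frame="world"):
    n = positions.shape[0]
    conf = np.full((n, 17), 0.9) if conf is None else conf
    return KeypointFrameSet(
        camera_id, rate, np.arange(n) / rate, positions, conf, frame
    )


class TestToWorld:
    def test_identity_extrinsics_unchanged(self):
        pos = np.random.default_rng(0).normal(size=(4, 17, 3))
        fs = _frames(pos, frame="camera")
        out = to_world(fs, CameraExtrinsics("c", np.eye(3), np.zeros(3)))
        np.testing.assert_array_equal(out.positions, pos)
        assert out.frame_of_reference == "world"

    def test_pure_translation(self):
        pos = np.zeros((2, 17, 3))
        fs = _frames(pos, frame="camera")
        out = to_world(fs, CameraExtrinsics("c", np.eye(3), np.array([1.0, 0, 0])))
        np.testing.assert_allclose(out.positions[..., 0], 1.0)

    def test_rotation_about_z(self):
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        pos = np.zeros((1, 17, 3))
        pos[0, :, 0] = 1.0  # all keypoints at (1,0,0)
        out = to_world(_frames(pos, frame="camera"), CameraExtrinsics("c", rz, np.zeros(3)))
        np.testing.assert_allclose(out.positions[0, 0], [0.0, 1.0, 0.0], atol=1e-12)

    def test_double_application_rejected(self):
        fs = _frames(np.zeros((2, 17, 3)), frame="world")
        with pytest.raises(ValidationError, match="world"):
            to_world(fs, CameraExtrinsics("c", np.eye(3), np.zeros(3)))


class TestFusion:
    def test_identical_cameras_return_point_with_unit_weight(self):
        pos = np.random.default_rng(1).normal(size=(3, 17, 3))
        fused = fuse_keypoints([_frames(pos, "a"), _frames(pos, "b")])
        np.testing.assert_allclose(fused.positions, pos, atol=1e-12)
        np.testing.assert_allclose(fused.weights.sum(axis=-1), 1.0)

    def test_missing_camera_uses_remaining(self):
        pos = np.zeros((2, 17, 3))
        pos_b = pos.copy()
        pos_b[..., 0] = 0.02
        pos_c = pos.copy()
        pos_c[:, 5] = np.nan  # camera c never sees left_shoulder
        conf_c = np.full((2, 17), 0.9)
        conf_c[:, 5] = 0.0
        fused = fuse_keypoints(
            [_frames(pos, "a"), _frames(pos_b, "b"), _frames(pos_c, "c", conf=conf_c)]
        )
        # left_shoulder fused from cameras a and b only
        np.testing.assert_allclose(fused.positions[:, 5, 0], 0.01, atol=1e-12)

    def test_outlier_gated_by_median_distance(self):
        pos_a = np.zeros((1, 17, 3))
        pos_b = np.zeros((1, 17, 3))
        pos_c = np.zeros((1, 17, 3))
        pos_c[..., 0] = 1.0  # one camera 1 m off
        fused = fuse_keypoints(
            [_frames(pos_a, "a", rate=30), _frames(pos_b, "b"), _frames(pos_c, "c")],
            gate_distance=0.5,
        )
        np.testing.assert_allclose(fused.positions, 0.0, atol=1e-12)
        assert np.all(fused.weights[..., 2] == 0.0)

    def test_single_camera_idempotent(self):
        pos = np.random.default_rng(2).normal(size=(5, 17, 3))
        fused = fuse_keypoints([_frames(pos)])
        np.testing.assert_allclose(fused.positions, pos, atol=1e-12)

    def test_camera_frame_input_rejected(self):
        with pytest.raises(ValidationError, match="world"):
            fuse_keypoints([_frames(np.zeros((2, 17, 3)), frame="camera")])

    def test_disjoint_time_support_rejected(self):
        a = _frames(np.zeros((3, 17, 3)))
        b = KeypointFrameSet(
            "b", 30.0, 10.0 + np.arange(3) / 30.0, np.zeros((3, 17, 3)), np.full((3, 17), 0.9), "world"
        )
        with pytest.raises(ValidationError, match="overlap"):
            fuse_keypoints([a, b])


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full(100, 7.3)
        np.testing.assert_allclose(lowpass(x, fs=30.0), x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        # analytic 4th-order Butterworth magnitude at 1 Hz, fc=6: |H|^2 (filtfilt)
        t = np.arange(0, 30, 1 / 30)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass(x, fs=30.0)
        amp = np.ptp(y[200:-200]) / 2
        expected = (1 / np.sqrt(1 + (1 / 6) ** 8)) ** 2
        assert amp == pytest.approx(expected, rel=0.01)

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(0, 30, 1 / 30)
        x = np.sin(2 * np.pi * 12.0 * t)
        y = lowpass(x, fs=30.0)
        assert np.max(np.abs(y[200:-200])) < 0.01  # > 99 % attenuation

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValidationError, match="Nyquist"):
            lowpass(np.zeros(100), fs=30.0, cutoff=15.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError, match="short"):
            lowpass(np.zeros(10), fs=30.0)

    def test_refiltering_is_nearly_idempotent(self, noise_free_trial):
        wave = noise_free_trial.truth_angles["knee"].values
        once = lowpass(wave, fs=100.0)
        twice = lowpass(once, fs=100.0)
        rms = np.sqrt(np.mean((twice - once)[100:-100] ** 2))
        assert rms < 0.1


class TestFlexionAngle:
    def test_collinear_is_zero(self):
        a = np.array([0.0, 0.0, 1.0])
        v = np.zeros(3)
        b = np.array([0.0, 0.0, -1.0])
        assert flexion_angle(a, v, b, Y) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_forty_degrees(self):
        hip = np.array([0.0, 0.0, 1.0])
        knee = np.zeros(3)
        ankle = np.array([np.sin(np.radians(40)), 0.0, -np.cos(np.radians(40))])
        assert flexion_angle(hip, knee, ankle, Y) == pytest.approx(40.0, abs=1e-9)

    def test_sagittal_reflection_preserves_magnitude(self):
        rng = np.random.default_rng(3)
        a, v, b = rng.normal(size=(3, 3))
        ang = flexion_angle(a, v, b, Y)
        refl = np.array([1.0, -1.0, 1.0])
        ang_r = flexion_angle(a * refl, v * refl, b * refl, Y)
        assert abs(ang) == pytest.approx(abs(ang_r), abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            flexion_angle(np.array([0.0, 1.0, 0.0]), np.zeros(3), np.array([0.0, 0.0, 1.0]), Y)

    @given(st.integers(0, 10_000))
    def test_rigid_invariance(self, seed):
        """A global rigid transform leaves every flexion angle unchanged."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 3))
        angle = flexion_angle(pts[0], pts[1], pts[2], Y)
        # random proper rotation via QR
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.normal(size=3)
        moved = pts @ q.T + t
        n_moved = q @ Y
        assert flexion_angle(moved[0], moved[1], moved[2], n_moved) == pytest.approx(
            angle, abs=1e-9
        )


class TestAnglesFromSkeleton:
    def test_noise_free_trial_recovers_truth(self, noise_free_trial):
        tr = noise_free_trial
        angles = trial_angles(
            list(tr.trial.markerless.values()), {e.camera_id: e for e in tr.extrinsics}
        )
        for joint in ("hip", "knee"):
            w = angles[joint]
            truth = np.interp(
                w.timestamps, tr.truth_angles[joint].timestamps, tr.truth_angles[joint].values
            )
            inner = slice(30, -30)  # discard filter edge transients
            rmse = np.sqrt(np.mean((w.values[inner] - truth[inner]) ** 2))
            assert rmse < 0.5

    def test_missing_ankle_rejected(self):
        pos = np.random.default_rng(4).normal(size=(40, 17, 3))
        pos[:, 16] = np.nan  # right_ankle always absent
        skel = FusedSkeletonSeries(
            30.0, np.arange(40) / 30.0, pos, np.ones((40, 17, 1)), ("c",)
        )
        with pytest.raises(ValidationError, match="right_ankle"):
            angles_from_skeleton(skel)

    def test_standing_pose_is_zero_everywhere(self):
        pos = np.zeros((40, 17, 3))
        pos[:, 6] = [0.0, -0.1, 1.4]  # right shoulder
        pos[:, 12] = [0.0, -0.1, 0.9]  # right hip
        pos[:, 14] = [0.0, -0.1, 0.5]  # right knee
        pos[:, 16] = [0.0, -0.1, 0.1]  # right ankle
        skel = FusedSkeletonSeries(
            30.0, np.arange(40) / 30.0, pos, np.ones((40, 17, 1)), ("c",)
        )
        out = angles_from_skeleton(skel)
        np.testing.assert_allclose(out["hip"].values, 0.0, atol=1e-9)
        np.testing.assert_allclose(out["knee"].values, 0.0, atol=1e-9)

    def test_long_gap_rejected(self):
        pos = np.random.default_rng(5).normal(size=(60, 17, 3))
        pos[10:16, 16] = np.nan  # 6-frame gap in right ankle (presence still >90 %)
        skel = FusedSkeletonSeries(
            30.0, np.arange(60) / 30.0, pos, np.ones((60, 17, 1)), ("c",)
        )
        with pytest.raises(ValidationError, match="gap"):
            angles_from_skeleton(skel)

    def test_unprojected_angle_agrees_in_sagittal_plane(self):
        """For coplanar geometry the 3-D included angle equals the projection."""
        hip = np.array([0.0, 0.0, 1.0])
        knee = np.zeros(3)
        ankle = np.array([np.sin(0.5), 0.0, -np.cos(0.5)])
        proj = flexion_angle(hip, knee, ankle, Y, projected=True)
        raw3d = flexion_angle(hip, knee, ankle, Y, projected=False)
        assert raw3d == pytest.approx(proj, abs=1e-9)

    def test_shoulder_midpoint_hip_reference(self, noise_free_trial):
        """The midpoint-of-shoulders option changes the hip trace only slightly
        for a symmetric synthetic trunk."""
        tr = noise_free_trial
        ext = {e.camera_id: e for e in tr.extrinsics}
        same = trial_angles(list(tr.trial.markerless.values()), ext)
        mid = trial_angles(
            list(tr.trial.markerless.values()), ext, hip_reference="shoulder_midpoint"
        )
        diff = np.abs(same["hip"].values - mid["hip"].values)
        assert diff.max() < 1.0  # both shoulders sit vertically above the hips
        np.testing.assert_allclose(same["knee"].values, mid["knee"].values, atol=1e-9)

    def test_per_camera_filtering_matches_post_fusion_on_clean_data(self, noise_free_trial):
        tr = noise_free_trial
        ext = {e.camera_id: e for e in tr.extrinsics}
        fused_first = trial_angles(list(tr.trial.markerless.values()), ext)
        cam_first = trial_angles(
            list(tr.trial.markerless.values()), ext, filter_per_camera=True
        )
        inner = slice(30, -30)
        for joint in ("hip", "knee"):
            rms = np.sqrt(
                np.mean(
                    (fused_first[joint].values[inner] - cam_first[joint].values[inner]) ** 2
                )
            )
            assert rms < 0.1

    def test_global_rigid_transform_leaves_angles_unchanged(self, noise_free_trial):
        """Yawing + translating the whole world (cameras included) changes nothing."""
        from gaitmmc.kinematics import fuse_keypoints

        tr = noise_free_trial
        ext = {e.camera_id: e for e in tr.extrinsics}
        th = 0.7
        rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        shift = np.array([2.0, -1.0, 0.5])
        moved_ext = {
            k: CameraExtrinsics(k, rz @ e.rotation, rz @ e.translation + shift)
            for k, e in ext.items()
        }

        def hip_angles(extrinsics, normal):
            world = [
                to_world(fs, extrinsics[fs.camera_id])
                for fs in tr.trial.markerless.values()
            ]
            skel = fuse_keypoints(world)
            return flexion_angle(
                skel.keypoint("right_shoulder"),
                skel.keypoint("right_hip"),
                skel.keypoint("right_knee"),
                normal,
            )

        np.testing.assert_allclose(
            hip_angles(moved_ext, rz @ Y), hip_angles(ext, Y), atol=1e-9
        )
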