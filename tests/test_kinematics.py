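"""Segment-line fitting and the two shoulder-angle definitions."""

import numpy as np
import pytest

from romscreen.kinematics import (
    AnatomicalFrame,
    AngleTrace,
    DegenerateGeometryError,
    RepetitionPeak,
    arm_vector,
    angle_trace,
    body_angle,
    fit_segment_vector,
    projection_angle,
    repetition_peak,
    rom_record,
    trunk_vector,
)
from romscreen.pipeline import extract_rom
from romscreen.preprocess import RepetitionWindow
from romscreen.simulate import TrajectoryConfig, synth_trajectory

from conftest import make_recording


def rigid_transform(rng):
    """Random rotation matrix (QR of a Gaussian) and translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-2, 2, size=3)


def upright_pose(arm_dir, side="right"):
    """Standing skeleton with a straight arm along arm_dir."""
    shoulder = np.array([-0.2, 1.5, 0.0]) if side == "right" else np.array([0.2, 1.5, 0.0])
    pose = {
        "hip_center": (0.0, 1.0, 0.0),
        "spine": (0.0, 1.25, 0.0),
        "shoulder_center": (0.0, 1.5, 0.0),
        "head": (0.0, 1.7, 0.0),
        "shoulder_left": (0.2, 1.5, 0.0),
        "shoulder_right": (-0.2, 1.5, 0.0),
    }
    arm_dir = np.asarray(arm_dir, dtype=float)
    for joint, dist in (("elbow", 0.3), ("wrist", 0.55), ("hand", 0.65)):
        pose[f"{joint}_{side}"] = tuple(shoulder + dist * arm_dir)
    return pose


class TestFitSegmentVector:
    def test_collinear_points(self):
        pts = [(0, 0, 0), (0, 1, 0), (0, 2, 0)]
        assert fit_segment_vector(pts, (0, 1, 0)) == pytest.approx((0, 1, 0))

    def test_orientation_hint_flips_sign(self):
        pts = [(0, 0, 0), (0, 1, 0), (0, 2, 0)]
        assert fit_segment_vector(pts, (0, -1, 0)) == pytest.approx((0, -1, 0))

    def test_matches_eigenvector_of_scatter_matrix(self, rng):
        base = np.array([0.3, -0.8, 0.52])
        base /= np.linalg.norm(base)
        pts = np.outer(np.linspace(0, 1, 4), base) + rng.normal(0, 0.01, size=(4, 3))
        got = fit_segment_vector(pts, base)
        centered = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        expected = evecs[:, np.argmax(evals)]
        expected *= np.sign(expected @ base)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_segment_vector([(1, 1, 1)], (1, 0, 0))
        with pytest.raises(DegenerateGeometryError):
            fit_segment_vector([(1, 1, 1)] * 4, (1, 0, 0))


class TestSegmentVectors:
    def test_vertical_trunk_points_down(self):
        frame = make_recording([upright_pose((0, -1, 0))]).frames[0]
        assert trunk_vector(frame) == pytest.approx((0, -1, 0), abs=1e-9)

    def test_tilted_trunk_angle(self):
        angle = np.radians(10)
        tilt = np.array(
            [
                [np.cos(angle), -np.sin(angle), 0],
                [np.sin(angle), np.cos(angle), 0],
                [0, 0, 1],
            ]
        )
        pose = upright_pose((0, -1, 0))
        tilted = {k: tuple(tilt @ np.asarray(v)) for k, v in pose.items()}
        frame = make_recording([tilted]).frames[0]
        caudal = trunk_vector(frame)
        assert np.degrees(np.arccos(caudal @ np.array([0, -1, 0]))) == pytest.approx(
            10.0, abs=1e-6
        )

    def test_trunk_rotation_equivariance(self, rng):
        pose = upright_pose((0, -1, 0))
        frame = make_recording([pose]).frames[0]
        base = trunk_vector(frame)
        for _ in range(10):
            rot, shift = rigid_transform(rng)
            moved = {k: tuple(rot @ np.asarray(v) + shift) for k, v in pose.items()}
            got = trunk_vector(make_recording([moved]).frames[0])
            assert got == pytest.approx(rot @ base, abs=1e-9)

    def test_arm_along_x(self):
        frame = make_recording([upright_pose((1, 0, 0))]).frames[0]
        assert arm_vector(frame, "right") == pytest.approx((1, 0, 0), abs=1e-9)

    def test_arm_hanging_down(self):
        frame = make_recording([upright_pose((0, -1, 0))]).frames[0]
        assert arm_vector(frame, "right") == pytest.approx((0, -1, 0), abs=1e-9)

    def test_bent_elbow_matches_eigen_oracle(self):
        pose = upright_pose((0, -1, 0))
        pose["shoulder_right"] = (0.0, 0.0, 0.0)
        pose["elbow_right"] = (0.3, 0.0, 0.0)
        pose["wrist_right"] = (0.3, -0.3, 0.0)
        del pose["hand_right"]
        frame = make_recording([pose]).frames[0]
        pts = np.array([pose["shoulder_right"], pose["elbow_right"], pose["wrist_right"]])
        centered = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        expected = evecs[:, np.argmax(evals)]
        expected *= np.sign(expected @ (pts[-1] - pts[0]))
        assert arm_vector(frame, "right") == pytest.approx(expected, abs=1e-9)

    def test_missing_landmarks_reported(self):
        pose = upright_pose((0, -1, 0))
        del pose["spine"]
        frame = make_recording([pose]).frames[0]
        with pytest.raises(DegenerateGeometryError, match="spine"):
            trunk_vector(frame)


DOWN = np.array([0.0, -1.0, 0.0])


class TestAngles:
    @pytest.mark.parametrize(
        "arm, expected",
        [
            ((0, -1, 0), 0.0),
            ((1, 0, 0), 90.0),
            (np.array([1, 1, 0]) / np.sqrt(2), 135.0),
        ],
    )
    def test_body_angle_hand_trig(self, arm, expected):
        assert body_angle(np.asarray(arm, float), DOWN) == pytest.approx(
            expected, abs=1e-6
        )

    def test_body_angle_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            body_angle(np.zeros(3), DOWN)

    @pytest.mark.parametrize("plane", ["coronal", "sagittal"])
    def test_projection_angle_arm_at_side(self, plane):
        frame = AnatomicalFrame.sensor_fixed()
        assert projection_angle(DOWN, frame, plane) == pytest.approx(0.0, abs=1e-6)

    def test_projection_angle_pure_abduction(self):
        frame = AnatomicalFrame.sensor_fixed()
        assert projection_angle(
            np.array([1.0, 0, 0]), frame, "coronal"
        ) == pytest.approx(90.0, abs=1e-6)

    def test_projection_angle_oblique_arm(self):
        # arm (1,1,1)/sqrt(3) projected on the coronal plane -> (1,1,0)/sqrt(2),
        # at 135 deg from the caudal (0,-1,0) direction
        frame = AnatomicalFrame.sensor_fixed()
        arm = np.ones(3) / np.sqrt(3)
        assert projection_angle(arm, frame, "coronal") == pytest.approx(135.0, abs=1e-6)

    def test_projection_degenerate_when_orthogonal_to_plane(self):
        frame = AnatomicalFrame.sensor_fixed()
        with pytest.raises(DegenerateGeometryError, match="orthogonal"):
            projection_angle(np.array([0.0, 0, 1]), frame, "coronal")

    def test_anatomical_frame_orthonormal(self, rng):
        pose = upright_pose((0, -1, 0))
        rot, shift = rigid_transform(rng)
        moved = {k: tuple(rot @ np.asarray(v) + shift) for k, v in pose.items()}
        f = AnatomicalFrame.from_frame(make_recording([moved]).frames[0])
        # right-handed in the order (mediolateral, longitudinal_up, anterior)
        triad = np.stack([f.mediolateral, f.longitudinal_up, f.anterior])
        assert triad @ triad.T == pytest.approx(np.eye(3), abs=1e-9)
        assert np.linalg.det(triad) == pytest.approx(1.0, abs=1e-9)


class TestAngleTrace:
    def test_static_arm_at_side(self):
        rec = make_recording([upright_pose((0, -1, 0), side="right")] * 30)
        for method in ("body", "projection"):
            tr = angle_trace(rec, method)
            assert len(tr.angle_deg) == 30
            assert np.abs(tr.angle_deg).max() < 1e-6

    def test_sweep_monotone_to_peak(self):
        cfg = TrajectoryConfig(movement="AA", peak_deg=150, n_reps=1, seed=0)
        rec = synth_trajectory(cfg)
        tr = angle_trace(rec, "body")
        peak_idx = int(np.argmax(tr.angle_deg))
        assert tr.angle_deg[peak_idx] == pytest.approx(150.0, abs=2.0)
        rising = tr.angle_deg[: peak_idx + 1]
        assert np.all(np.diff(rising) >= -1e-9)

    def test_in_plane_motion_methods_agree(self):
        for movement in ("AA", "AF"):
            cfg = TrajectoryConfig(movement=movement, peak_deg=120, n_reps=1, seed=0)
            rec = synth_trajectory(cfg)
            body = angle_trace(rec, "body").angle_deg
            proj = angle_trace(rec, "projection").angle_deg
            assert np.abs(body - proj).max() < 1e-6

    def test_rigid_motion_invariance(self, rng):
        cfg = TrajectoryConfig(movement="AA", peak_deg=100, n_reps=1, seed=3)
        rec = synth_trajectory(cfg)
        ref_body = angle_trace(rec, "body").angle_deg
        ref_proj = angle_trace(rec, "projection").angle_deg
        for _ in range(3):
            rot, shift = rigid_transform(rng)
            moved = rec.with_frames(
                [
                    fr.__class__(
                        t=fr.t,
                        landmarks=tuple(
                            lm.__class__(
                                name=lm.name,
                                position=tuple(rot @ np.asarray(lm.position) + shift),
                                tracked=lm.tracked,
                            )
                            for lm in fr.landmarks
                        ),
                    )
                    for fr in rec.frames
                ]
            )
            assert np.abs(angle_trace(moved, "body").angle_deg - ref_body).max() < 1e-6
            assert (
                np.abs(angle_trace(moved, "projection").angle_deg - ref_proj).max()
                < 1e-6
            )


def simple_trace(values):
    return AngleTrace(
        method="body",
        movement="AA",
        t=np.arange(len(values)) / 30.0,
        angle_deg=np.asarray(values, dtype=float),
    )


class TestRepetitionPeak:
    def test_interior_peak_three_frame_average(self):
        tr = simple_trace([10, 50, 90, 80, 70])
        peak = repetition_peak(tr, RepetitionWindow(1, 0, 5))
        assert peak.peak_frame == 2
        assert peak.peak_deg == pytest.approx((50 + 90 + 80) / 3)

    def test_constant_window(self):
        tr = simple_trace([42.0] * 5)
        assert repetition_peak(tr, RepetitionWindow(1, 0, 5)).peak_deg == 42.0

    def test_boundary_peak_shifts_inward(self):
        tr = simple_trace([90, 80, 70, 60])
        peak = repetition_peak(tr, RepetitionWindow(1, 0, 4))
        assert peak.peak_frame == 0
        assert peak.peak_deg == pytest.approx((90 + 80 + 70) / 3)

    def test_tie_broken_by_earliest_frame(self):
        tr = simple_trace([10, 80, 30, 80, 10])
        peak = repetition_peak(tr, RepetitionWindow(1, 0, 5))
        assert peak.peak_frame == 1

    def test_window_respected(self):
        tr = simple_trace([170, 10, 20, 30, 20, 10])
        peak = repetition_peak(tr, RepetitionWindow(1, 1, 6))
        assert peak.peak_frame == 3
        assert peak.peak_deg == pytest.approx((20 + 30 + 20) / 3)

    def test_short_window_rejected(self):
        tr = simple_trace([1, 2, 3])
        with pytest.raises(ValueError):
            repetition_peak(tr, RepetitionWindow(1, 0, 2))


class TestROMRecord:
    def test_mean_of_peaks(self):
        peaks = [RepetitionPeak(i + 1, v, 0) for i, v in enumerate((100, 110, 120))]
        rec = rom_record(peaks, "s1", "AA", "body")
        assert rec.rom_deg == pytest.approx(110.0)
        assert rec.n_reps == 3
        assert rec.complete

    def test_single_peak_flagged_excludable(self):
        rec = rom_record([RepetitionPeak(1, 90.0, 0)], "s1", "AA", "body")
        assert rec.rom_deg == 90.0
        assert not rec.complete

    def test_random_peaks_match_mean_oracle(self, rng):
        values = rng.uniform(0, 180, size=7)
        peaks = [RepetitionPeak(i + 1, float(v), 0) for i, v in enumerate(values)]
        rec = rom_record(peaks, "s", "PF", "projection")
        assert rec.rom_deg == pytest.approx(float(np.sum(values)) / len(values))

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            rom_record([], "s", "AA", "body")


class TestParameterRecovery:
    @pytest.mark.parametrize("peak", [60.0, 126.0, 150.0])
    def test_noise_free_recovery_within_one_degree(self, peak):
        cfg = TrajectoryConfig(movement="AA", peak_deg=peak, n_reps=3, seed=0)
        rom = extract_rom(synth_trajectory(cfg), "projection")
        assert rom.n_reps == 3
        assert rom.rom_deg == pytest.approx(peak, abs=1.0)

    def test_noisy_recovery_within_three_degrees(self):
        cfg = TrajectoryConfig(
            movement="AF", peak_deg=120, n_reps=3, landmark_noise_sd_m=0.005, seed=11
        )
        rom = extract_rom(synth_trajectory(cfg), "body")
        assert rom.rom_deg == pytest.approx(120.0, abs=3.0)
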