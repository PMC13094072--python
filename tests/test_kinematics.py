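"""Joint angles, differentiation, tip speed, segmentation, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import strikelab as sl
from strikelab import kinematics as kin
from strikelab.errors import (
    DegenerateGeometryError, ParameterError, SegmentationError,
)


def _track_from_positions(pos, fps=10000.0, scale=0.05):
    return kin.LandmarkTrack(positions=np.asarray(pos, float), fps=fps,
                             scale=scale)


def _frames_with_ct(coxal_base, ct, ft, n=3):
    """Minimal track where only the CT-defining landmarks matter."""
    frame = np.zeros((5, 2))
    frame[kin.BODY] = (-5.0, -5.0)
    frame[kin.COXAL_BASE] = coxal_base
    frame[kin.CT_JOINT] = ct
    frame[kin.FT_JOINT] = ft
    frame[kin.TARSUS_BASE] = np.asarray(ft) + (1.0, 1.0)
    return _track_from_positions(np.repeat(frame[None], n, axis=0))


def _oracle_angle(vertex, a, b):
    """Independent atan2 oracle: absolute wrapped difference of ray angles."""
    ang = math.atan2(a[1] - vertex[1], a[0] - vertex[0]) \
        - math.atan2(b[1] - vertex[1], b[0] - vertex[0])
    ang = abs(math.degrees(ang)) % 360.0
    return 360.0 - ang if ang > 180.0 else ang


@pytest.mark.parametrize("coxal,ct,ft,expected", [
    ((0, 0), (1, 0), (2, 0), 180.0),  # collinear
    ((0, 0), (1, 0), (1, 1), 90.0),  # perpendicular
    ((0, 0), (1, 0), (0, 0.000001), 0.0),  # nearly folded back
])
def test_ct_angle_constructed_cases(coxal, ct, ft, expected):
    track = _frames_with_ct(coxal, ct, ft)
    series = kin.joint_angles(track)
    assert series.ct_angle[0] == pytest.approx(expected, abs=1e-3)


def test_angles_match_atan2_oracle(rng):
    """Dot-product angles equal the brute-force atan2 oracle to <=1e-9 deg."""
    pos = rng.uniform(-100, 100, size=(500, 5, 2))
    track = _track_from_positions(pos)
    series = kin.joint_angles(track)
    for i in range(track.n_frames):
        ct = _oracle_angle(pos[i, kin.CT_JOINT], pos[i, kin.COXAL_BASE],
                           pos[i, kin.FT_JOINT])
        ft = _oracle_angle(pos[i, kin.FT_JOINT], pos[i, kin.CT_JOINT],
                           pos[i, kin.TARSUS_BASE])
        assert abs(series.ct_angle[i] - ct) <= 1e-9
        assert abs(series.ft_angle[i] - ft) <= 1e-9


@given(angle=st.floats(-math.pi, math.pi),
       tx=st.floats(-50, 50), ty=st.floats(-50, 50),
       s=st.floats(0.1, 10.0), flip=st.booleans())
def test_angles_invariant_under_similarity_transforms(angle, tx, ty, s, flip):
    """Rotation + translation + uniform scaling + y-flip leave angles put."""
    rng = np.random.default_rng(99)
    pos = rng.uniform(-10, 10, size=(3, 5, 2))
    base = kin.joint_angles(_track_from_positions(pos))
    R = np.array([[math.cos(angle), -math.sin(angle)],
                  [math.sin(angle), math.cos(angle)]])
    moved = s * pos @ R.T + (tx, ty)
    if flip:
        moved[..., 1] *= -1.0
    out = kin.joint_angles(_track_from_positions(moved))
    np.testing.assert_allclose(out.ct_angle, base.ct_angle, atol=1e-8)
    np.testing.assert_allclose(out.ft_angle, base.ft_angle, atol=1e-8)


def test_degenerate_frame_raises_with_frame_and_joint():
    pos = np.random.default_rng(0).uniform(0, 10, size=(4, 5, 2))
    pos[2, kin.FT_JOINT] = pos[2, kin.CT_JOINT]  # coincident at frame 2
    with pytest.raises(DegenerateGeometryError) as err:
        kin.joint_angles(_track_from_positions(pos))
    assert err.value.frame == 2
    assert "CT" in str(err.value) or "FT" in str(err.value)


class TestStandardize:
    def test_constant_series_maps_to_zero(self):
        series = kin.JointAngleSeries(fps=1000.0,
                                      ct_angle=np.full(5, 33.0),
                                      ft_angle=np.full(5, 90.0))
        out = kin.standardize_angles(series)
        assert np.all(out.ct_std == 0.0)
        assert np.all(out.ft_std == 0.0)

    def test_opening_positive_sign(self):
        series = kin.JointAngleSeries(fps=1000.0,
                                      ct_angle=np.array([20.0, 35.0, 50.0]),
                                      ft_angle=np.zeros(3) + 90.0)
        out = kin.standardize_angles(series)
        assert out.ct_std[2] == pytest.approx(30.0)
        literal = kin.standardize_angles(series, literal=True)
        assert literal.ct_std[2] == pytest.approx(-30.0)
        assert literal.sign_convention == "initial_minus_raw"

    def test_idempotent(self):
        series = kin.JointAngleSeries(fps=1000.0,
                                      ct_angle=np.array([20.0, 35.0, 50.0]),
                                      ft_angle=np.zeros(3) + 90.0)
        once = kin.standardize_angles(series)
        twice = kin.standardize_angles(once)
        assert twice is once


class TestAngularVelocity:
    def test_linear_ramp_analytic(self):
        # 10 deg/frame at 10,000 fps = 1e5 deg/s = 1745.329... rad/s
        n = 31
        series = kin.JointAngleSeries(fps=10000.0,
                                      ct_angle=10.0 * np.arange(n),
                                      ft_angle=np.full(n, 90.0))
        expected = math.radians(1e5)
        for method in ("central_difference", "savitzky_golay"):
            out = kin.angular_velocity(series, method=method)
            np.testing.assert_allclose(out.omega_ct[3:-3], expected,
                                       rtol=1e-12)
            assert np.all(out.omega_ft[3:-3] == pytest.approx(0.0, abs=1e-9))

    def test_even_window_rejected(self):
        series = kin.JointAngleSeries(fps=1000.0, ct_angle=np.arange(10.0),
                                      ft_angle=np.arange(10.0))
        with pytest.raises(ParameterError):
            kin.angular_velocity(series, window=4)

    def test_savgol_beats_central_difference_on_noise(self, rng):
        """S-G derivative has lower MSE than central difference on a noisy
        constant-slope ramp (known true slope)."""
        fps, slope = 10000.0, 2.0  # deg per frame
        n = 200
        truth = math.radians(slope * fps)
        noisy = slope * np.arange(n) + rng.normal(0, 0.5, n)
        series = kin.JointAngleSeries(fps=fps, ct_angle=noisy,
                                      ft_angle=np.full(n, 90.0))
        sg = kin.angular_velocity(series, method="savitzky_golay").omega_ct
        cd = kin.angular_velocity(series, method="central_difference").omega_ct
        mse_sg = np.mean((sg[5:-5] - truth) ** 2)
        mse_cd = np.mean((cd[5:-5] - truth) ** 2)
        assert mse_sg <= mse_cd

    def test_monotone_ramp_keeps_velocity_sign(self):
        series = kin.JointAngleSeries(fps=1000.0,
                                      ct_angle=np.linspace(10, 80, 50),
                                      ft_angle=np.linspace(10, 80, 50))
        out = kin.angular_velocity(series)
        assert np.all(out.omega_ct > 0)


class TestTipSpeed:
    def test_stationary_landmark_is_zero(self):
        pos = np.tile(np.arange(10.0).reshape(5, 2), (6, 1, 1))
        assert np.all(kin.tip_speed(_track_from_positions(pos)) == 0.0)

    def test_pure_rotation_matches_omega_r(self):
        # omega = 450 rad/s about the CT joint, radius 11 mm -> 4.95 m/s
        fps, scale, omega, r_mm = 1.0e6, 0.05, 450.0, 11.0
        n = 200
        t = np.arange(n) / fps
        r_px = r_mm / scale
        pos = np.zeros((n, 5, 2))
        pos[:, kin.COXAL_BASE] = (-50.0, 0.0)
        pos[:, kin.BODY] = (-80.0, 0.0)
        pos[:, kin.CT_JOINT] = (0.0, 0.0)
        pos[:, kin.FT_JOINT, 0] = 0.5 * r_px * np.cos(omega * t)
        pos[:, kin.FT_JOINT, 1] = 0.5 * r_px * np.sin(omega * t)
        pos[:, kin.TARSUS_BASE, 0] = r_px * np.cos(omega * t)
        pos[:, kin.TARSUS_BASE, 1] = r_px * np.sin(omega * t)
        speed = kin.tip_speed(_track_from_positions(pos, fps=fps, scale=scale))
        np.testing.assert_allclose(speed[1:-1], 4.95, rtol=1e-6)

    def test_speed_linear_in_scale(self):
        pos = np.random.default_rng(3).uniform(0, 50, size=(10, 5, 2))
        s1 = kin.tip_speed(_track_from_positions(pos, scale=0.05))
        s2 = kin.tip_speed(_track_from_positions(pos, scale=0.10))
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)


class TestSegmentation:
    @staticmethod
    def _series_and_tip(theta, fps=20000.0):
        series = kin.JointAngleSeries(fps=fps, ct_angle=np.asarray(theta, float),
                                      ft_angle=np.full(len(theta), 90.0))
        # synthetic tip speed proportional to |dtheta/dt|
        tip = np.abs(np.gradient(np.radians(series.ct_angle), 1.0 / fps)) * 0.01
        return series, tip

    def test_constructed_plateau_start_frame(self):
        theta = np.concatenate([np.full(20, 15.0),
                                15.0 + 1.3 * np.arange(1, 31),
                                np.full(10, 15.0 + 1.3 * 30)])
        series, tip = self._series_and_tip(theta)
        phases = kin.segment_strike(series, tip)
        assert phases.start_frame == 20
        assert phases.plateau[0] == 0
        assert phases.plateau[1] < 20

    def test_monotone_series_has_no_plateau(self):
        theta = np.linspace(10.0, 120.0, 60)
        series, tip = self._series_and_tip(theta)
        with pytest.raises(SegmentationError, match="plateau"):
            kin.segment_strike(series, tip)

    def test_misaligned_tip_rejected(self):
        theta = np.concatenate([np.full(20, 15.0), np.arange(16.0, 40.0)])
        series, tip = self._series_and_tip(theta)
        with pytest.raises(sl.ValidationError):
            kin.segment_strike(series, tip[:-3])

    def test_end_at_tip_speed_threshold(self):
        theta = np.concatenate([np.full(20, 15.0),
                                15.0 + 2.0 * np.arange(1, 21),
                                np.full(20, 55.0)])
        series, tip = self._series_and_tip(theta)
        phases = kin.segment_strike(series, tip)
        # tip at rest one frame after the ramp's last moving frame
        assert phases.end_frame == 40
        assert phases.start_frame == 20


class TestSummary:
    def test_recovers_generator_ground_truth(self, default_strike):
        scn, gt = default_strike
        track = sl.generate_strike_track(scn)
        series = kin.angular_velocity(kin.joint_angles(track))
        tip = kin.tip_speed(track)
        phases = kin.segment_strike(series, tip)
        summ = kin.summarize_strike(series, phases, tip)
        assert summ.sweep_duration == pytest.approx(gt.sweep_duration,
                                                    rel=1e-9)
        assert summ.peak_omega_ct == pytest.approx(gt.peak_omega_ct, rel=1e-6)

    def test_duration_halves_when_fps_doubles(self):
        theta = np.concatenate([np.full(20, 15.0),
                                15.0 + 1.3 * np.arange(1, 31),
                                np.full(10, 15.0 + 1.3 * 30)])
        durations = []
        for fps in (10000.0, 20000.0):
            series, tip = TestSegmentation._series_and_tip(theta, fps=fps)
            phases = kin.segment_strike(series, tip)
            series = kin.angular_velocity(series)
            durations.append(kin.summarize_strike(series, phases,
                                                  tip).sweep_duration)
        assert durations[0] == pytest.approx(2.0 * durations[1])

    def test_degenerate_window_start_equals_end(self):
        series = kin.JointAngleSeries(fps=1000.0, ct_angle=np.arange(10.0),
                                      ft_angle=np.arange(10.0))
        series = kin.angular_velocity(series)
        tip = np.linspace(0, 1, 10)
        phases = kin.StrikePhases(start_frame=4, end_frame=4, plateau=(0, 3),
                                  closed_level=0.0, noise_sd=0.0)
        summ = kin.summarize_strike(series, phases, tip)
        assert summ.sweep_duration == 0.0
        assert summ.peak_tip_speed == pytest.approx(tip[4])
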