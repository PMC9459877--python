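"""Generator: kinematics templates, forward IMU model, fabric coupling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from clothgait.errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidParameterError,
)
from clothgait.simulate import (
    FabricCoupling,
    GaitParams,
    ImuNoise,
    MountingSpec,
    SegmentKinematics,
    clothing_transform,
    generate_kinematics,
    generate_session,
    imu_from_kinematics,
)

ZERO = ImuNoise(0.0, 0.0, 0.0)


def _cycle_durations(kin):
    ms = [e[1] for e in kin.event_times]
    return np.diff(ms)


class TestGenerateKinematics:
    def test_stance_span_matches_fraction_by_construction(self):
        kin = generate_kinematics(GaitParams(n_cycles=10, variability=0.0), seed=0)
        for _, ms, ic, to in kin.event_times:
            assert to - ic == pytest.approx(0.60 * 1.2, abs=1e-9)

    def test_stance_span_scales_with_each_cycles_own_duration(self):
        kin = generate_kinematics(GaitParams(n_cycles=12, variability=0.05), seed=3)
        events = kin.event_times
        for k in range(len(events) - 1):
            T_k = events[k + 1][1] - events[k][1]
            span = events[k][3] - events[k][2]
            assert span == pytest.approx(0.60 * T_k, rel=1e-9)

    def test_zero_amplitude_gives_constant_angles_with_events(self):
        params = GaitParams(
            n_cycles=5,
            amplitude_waist_deg=0.0,
            amplitude_thigh_deg=0.0,
            amplitude_shank_deg=0.0,
            variability=0.0,
        )
        kin = generate_kinematics(params, seed=0)
        assert np.allclose(kin.angle_shank, kin.angle_shank[0])
        assert len(kin.event_times) == 5

    def test_same_seed_bitwise_identical_different_seed_differs(self):
        a = generate_kinematics(GaitParams(n_cycles=5), seed=11)
        b = generate_kinematics(GaitParams(n_cycles=5), seed=11)
        c = generate_kinematics(GaitParams(n_cycles=5), seed=12)
        assert np.array_equal(a.angle_shank, b.angle_shank)
        assert not np.array_equal(a.angle_shank, c.angle_shank)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(cycle_duration_s=0.0),
            dict(cycle_duration_s=-1.0),
            dict(n_cycles=0),
            dict(amplitude_shank_deg=-1.0),
            dict(stance_fraction=0.0),
            dict(stance_fraction=1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            GaitParams(**bad)

    def test_shank_rate_extrema_sit_at_the_events(self):
        """Template contract: |omega| global max at MS, local minima at IC/TO."""
        kin = generate_kinematics(GaitParams(n_cycles=8, variability=0.0), seed=0)
        t, rate = kin.time, kin.rate_shank
        for k, ms, ic, to in kin.event_times[1:-1]:
            in_cycle = (t >= ms) & (t < ms + 1.2)
            peak_t = t[in_cycle][np.argmax(np.abs(rate[in_cycle]))]
            assert abs(peak_t - ms) <= 0.021
            for ev in (ic, to):
                i = int(round(ev / 0.02))
                # a local minimum of the rate within one sample of the event
                w = rate[i - 3 : i + 4]
                assert np.argmin(w) in (2, 3, 4)

    def test_rates_are_derivatives_of_angles(self):
        kin = generate_kinematics(GaitParams(n_cycles=6, variability=0.0), seed=1)
        mid = slice(50, -50)
        num = np.gradient(kin.angle_shank, kin.time)
        err = np.sqrt(np.mean((num[mid] - kin.rate_shank[mid]) ** 2))
        assert err < 0.02 * np.max(np.abs(kin.rate_shank))


def _sine_kinematics(freq=0.5, amp=20.0, fs=50.0, duration=10.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    theta = amp * np.sin(2 * np.pi * freq * t)
    zeros = np.zeros_like(t)
    return SegmentKinematics(
        time=t,
        angle_waist=zeros,
        angle_thigh=zeros,
        angle_shank=theta,
        event_times=[],
        stance_fraction=0.6,
    ), t, theta


class TestImuForwardModel:
    def test_static_upright_identity_mounting(self):
        n = 100
        t = np.arange(n) / 50.0
        kin = SegmentKinematics(
            time=t,
            angle_waist=np.zeros(n),
            angle_thigh=np.zeros(n),
            angle_shank=np.zeros(n),
            event_times=[],
            stance_fraction=0.6,
        )
        imu = imu_from_kinematics(kin, MountingSpec("lower_shank", "body"), ZERO)
        assert np.allclose(imu.accel, [0.0, 0.0, 1.0], atol=1e-12)
        assert np.allclose(imu.gyro, 0.0, atol=1e-12)

    def test_gyro_matches_analytic_derivative_of_sine(self):
        """Finite-difference derivative of a 0.5 Hz sine vs the closed form."""
        kin, t, _ = _sine_kinematics()
        mount = MountingSpec("lower_shank", "body", lever_arm_m=0.0)
        imu = imu_from_kinematics(kin, mount, ZERO)
        omega_ml = -imu.gyro[:, 1]  # rightward medial-lateral axis
        analytic = 20.0 * 2 * np.pi * 0.5 * np.cos(2 * np.pi * 0.5 * t)
        mid = slice(5, -5)  # np.gradient edge samples are one-sided
        rms = np.sqrt(np.mean((omega_ml[mid] - analytic[mid]) ** 2))
        assert rms < 1e-3 * np.max(np.abs(analytic))

    def test_rotated_mounting_equals_rotated_signals(self, rng):
        kin, _, _ = _sine_kinematics()
        R = Rotation.random(random_state=7).as_matrix()
        base = imu_from_kinematics(kin, MountingSpec("thigh", "body"), ZERO)
        rot = imu_from_kinematics(
            kin, MountingSpec("thigh", "body", mounting_rotation=R), ZERO
        )
        assert np.allclose(rot.accel, base.accel @ R, atol=1e-12)
        assert np.allclose(rot.gyro, base.gyro @ R, atol=1e-12)

    def test_static_noise_free_magnitude_is_one_g_any_tilt(self):
        n = 200
        t = np.arange(n) / 50.0
        const = np.full(n, -25.0)
        kin = SegmentKinematics(
            time=t,
            angle_waist=const,
            angle_thigh=const,
            angle_shank=const,
            event_times=[],
            stance_fraction=0.6,
        )
        R = Rotation.random(random_state=3).as_matrix()
        imu = imu_from_kinematics(
            kin, MountingSpec("waist", "clothing", mounting_rotation=R), ZERO
        )
        assert np.allclose(np.linalg.norm(imu.accel, axis=1), 1.0, atol=1e-9)

    def test_too_short_series_rejected(self):
        t = np.arange(2) / 50.0
        kin = SegmentKinematics(
            time=t,
            angle_waist=np.zeros(2),
            angle_thigh=np.zeros(2),
            angle_shank=np.zeros(2),
            event_times=[],
            stance_fraction=0.6,
        )
        with pytest.raises(InsufficientDataError):
            imu_from_kinematics(kin, MountingSpec("waist", "body"), ZERO)

    def test_improper_mounting_rotation_rejected(self):
        flip = np.diag([1.0, 1.0, -1.0])  # det -1
        with pytest.raises(InvalidParameterError):
            MountingSpec("waist", "body", mounting_rotation=flip)


class TestClothingTransform:
    def test_rigid_limit_tracks_body_within_half_degree(self):
        kin = generate_kinematics(GaitParams(n_cycles=10), seed=2)
        stiff = FabricCoupling(stiffness=4e6, damping=2 * 0.7 * 2000.0, gain=1.0)
        cloth = clothing_transform(kin, stiff, seed=0)
        assert np.max(np.abs(cloth.angle_shank - kin.angle_shank)) < 0.5
        assert cloth.event_times == kin.event_times

    def test_quasi_static_gain_sets_amplitude_ratio(self):
        kin, t, theta = _sine_kinematics(freq=0.2, amp=10.0, duration=30.0)
        c = FabricCoupling(stiffness=400.0, damping=14.0, gain=1.2)
        cloth = clothing_transform(kin, c, seed=0)
        settled = slice(len(t) // 2, None)
        ratio = np.ptp(cloth.angle_shank[settled]) / np.ptp(theta[settled])
        assert ratio == pytest.approx(1.2, rel=0.02)

    def test_step_response_overshoot_matches_second_order_theory(self):
        zeta, wn = 0.3, 10.0
        n = 500
        t = np.arange(n) / 50.0
        step = np.where(t >= 1.0, 10.0, 0.0)
        zeros = np.zeros(n)
        kin = SegmentKinematics(
            time=t,
            angle_waist=zeros,
            angle_thigh=zeros,
            angle_shank=step,
            rate_waist=zeros,
            rate_thigh=zeros,
            rate_shank=zeros,
            event_times=[],
            stance_fraction=0.6,
        )
        c = FabricCoupling(stiffness=wn**2, damping=2 * zeta * wn, gain=1.0)
        cloth = clothing_transform(kin, c, seed=0)
        overshoot = (cloth.angle_shank.max() - 10.0) / 10.0
        expected = np.exp(-np.pi * zeta / np.sqrt(1 - zeta**2))
        assert overshoot == pytest.approx(expected, rel=0.05)

    def test_invalid_coupling_rejected(self):
        with pytest.raises(InvalidParameterError):
            FabricCoupling(stiffness=0.0, damping=1.0)
        with pytest.raises(InvalidParameterError):
            FabricCoupling(stiffness=100.0, damping=-1.0)


class TestGenerateSession:
    def test_activity_annotation_matches_protocol_order(self, small_session):
        session, _ = small_session
        labels = [a.label for a in session.activities]
        assert labels == ["standing", "sitting", "sit_to_stand", "leg_raise", "walking"]

    def test_ground_truth_has_one_triple_per_cycle(self, small_session):
        _, gt = small_session
        assert len(gt.body.event_times) == 20
        for k, ms, ic, to in gt.body.event_times:
            assert ms < ic < to

    def test_same_seed_identical_sessions(self):
        from conftest import SHORT_PROTOCOL

        a, _ = generate_session(protocol=SHORT_PROTOCOL, gait=GaitParams(n_cycles=5), seed=42)
        b, _ = generate_session(protocol=SHORT_PROTOCOL, gait=GaitParams(n_cycles=5), seed=42)
        for key in a.sensors:
            assert np.array_equal(a.sensors[key].accel, b.sensors[key].accel)
            assert np.array_equal(a.sensors[key].gyro, b.sensors[key].gyro)

    def test_noise_free_standing_magnitude_exactly_one_g(self, noise_free_session):
        session, _ = noise_free_session
        lo, hi = session.segments("standing")[0]
        lo += 50  # skip nothing at the head; guard the blend tail
        hi -= 100
        for s in session.sensors.values():
            if s.attachment == "body":
                assert np.allclose(s.accel_magnitude()[lo:hi], 1.0, atol=1e-9)

    def test_protocol_without_standing_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_session(protocol=[("walking", None)], seed=0)
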