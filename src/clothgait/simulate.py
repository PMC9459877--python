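"""Synthetic multi-sensor gait sessions with known ground truth.

The generator produces sagittal-plane segment-to-vertical angle trajectories
for the waist, thigh and lower shank over a scripted activity protocol
(standing, sitting, sit-to-stand repetitions, leg raises, walking), derives
body- and clothing-mounted 6-axis IMU signals from them through a rigid
forward model, and records the ground truth (true angles, true gait events,
true mounting rotations) needed to score every downstream pipeline stage.

Conventions
-----------
Angles are segment-to-vertical angles in degrees, negative when the segment
is inclined (leaning forward) and positive when reclined. The anatomical
frame is x anterior, y to the subject's left, z up; sagittal rotation rate
about y is therefore the *negative* time derivative of the angle. Gait
cycles run from one mid-swing (MS) instant to the next; initial contact (IC)
and toe-off (TO) lie inside each cycle with ``to - ic`` equal to the stance
fraction times the cycle duration, by construction.

The walking angular-velocity waveform per cycle is a periodic mixture of
von-Mises bumps: a broad positive swing bump whose maximum *is* the MS
instant, two sharp negative dips exactly at IC and TO, and a wide shallow
stance valley. This guarantees the detector signature the event-extraction
stage relies on: the angular speed has its per-cycle global maximum at MS
and prominent local minima at IC and TO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid
from scipy.special import i0e

from .config import ATTACHMENTS, GRAVITY_MS2, PLACEMENTS, logger
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidParameterError,
    NumericalFailureError,
)
from .session import ActivitySegment, ImuTimeSeries, SensorSession

__all__ = [
    "GaitParams",
    "ImuNoise",
    "SegmentKinematics",
    "MountingSpec",
    "FabricCoupling",
    "GroundTruth",
    "generate_kinematics",
    "imu_from_kinematics",
    "clothing_transform",
    "generate_session",
    "default_protocol",
    "random_mounting",
    "write_ground_truth",
]

#: Gait phase (fraction of a MS-to-MS cycle) at which walking segments start
#: and stop: early stance, where the shank rate template crosses zero.
_PHASE_START = 0.12

#: Cross-fade window between consecutive activities, seconds.
_BLEND_S = 1.5

#: Default lever arms (sensor distance from the effective segment pivot), m.
DEFAULT_LEVER_ARM_M = {"waist": 0.08, "thigh": 0.18, "lower_shank": 0.55}

_SITTING_POSE = {"waist": 0.0, "thigh": -78.0, "lower_shank": -8.0}
_STANDING_POSE = {"waist": 0.0, "thigh": 0.0, "lower_shank": 0.0}


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class GaitParams:
    """Timing and amplitude of the walking template.

    Defaults describe ordinary self-paced adult walking: 1.2 s stride,
    60 % stance, shank-dominated angle amplitudes (shank > thigh > waist).
    ``variability`` is the fractional cycle-to-cycle standard deviation
    applied to both stride duration and rate amplitude.
    """

    cycle_duration_s: float = 1.2
    n_cycles: int = 80
    amplitude_waist_deg: float = 3.5
    amplitude_thigh_deg: float = 22.0
    amplitude_shank_deg: float = 34.0
    stance_fraction: float = 0.60
    variability: float = 0.02

    def __post_init__(self) -> None:
        if self.cycle_duration_s <= 0:
            raise InvalidParameterError("cycle_duration_s must be positive")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")
        if not 0 < self.stance_fraction < 1:
            raise InvalidParameterError("stance_fraction must lie in (0, 1)")
        for name in ("amplitude_waist_deg", "amplitude_thigh_deg", "amplitude_shank_deg"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.variability < 0:
            raise InvalidParameterError("variability must be non-negative")

    def amplitude(self, placement: str) -> float:
        return {
            "waist": self.amplitude_waist_deg,
            "thigh": self.amplitude_thigh_deg,
            "lower_shank": self.amplitude_shank_deg,
        }[placement]


@dataclass
class ImuNoise:
    """White measurement noise and gyroscope bias of the simulated IMU."""

    accel_sd_g: float = 0.02
    gyro_sd_dps: float = 0.5
    gyro_bias_dps: float = 0.5

    def __post_init__(self) -> None:
        if min(self.accel_sd_g, self.gyro_sd_dps, self.gyro_bias_dps) < 0:
            raise InvalidParameterError("noise levels must be non-negative")


ZERO_NOISE = ImuNoise(0.0, 0.0, 0.0)


@dataclass
class MountingSpec:
    """How a sensor sits on its segment: a fixed rotation and a lever arm.

    ``mounting_rotation`` maps sensor-frame vectors into the nominal segment
    frame; it models the unknown initial orientation of a sensor relative to
    the limb that the alignment stage must undo.
    """

    placement: str
    attachment: str
    side: str = "right"
    mounting_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    lever_arm_m: float | None = None

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise InvalidParameterError(f"unknown placement {self.placement!r}")
        if self.attachment not in ATTACHMENTS:
            raise InvalidParameterError(f"unknown attachment {self.attachment!r}")
        R = np.asarray(self.mounting_rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise InvalidParameterError("mounting_rotation must be orthonormal 3x3")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise InvalidParameterError("mounting_rotation must be proper (det +1)")
        self.mounting_rotation = R
        if self.lever_arm_m is None:
            self.lever_arm_m = DEFAULT_LEVER_ARM_M[self.placement]
        if not math.isfinite(self.lever_arm_m):
            raise InvalidParameterError("lever_arm_m must be finite")


@dataclass
class FabricCoupling:
    """Linear spring-damper model of fabric motion relative to the limb.

    The clothing angle follows the damped second-order tracking system
    ``theta_c'' = -stiffness * (theta_c - gain * theta_b) - damping * theta_c'``
    plus band-limited additive angle noise of standard deviation ``noise_sd``
    degrees. ``gain`` > 1 reproduces the wider angle range observed on loose
    clothing; the stiffness/damping pair sets how faithfully the fabric tracks
    the limb.
    """

    stiffness: float  # 1/s^2
    damping: float  # 1/s
    gain: float = 1.0
    noise_sd: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise InvalidParameterError("stiffness must be positive")
        if self.damping < 0 or self.gain < 0 or self.noise_sd < 0:
            raise InvalidParameterError("damping, gain and noise_sd must be >= 0")


#: Per-placement fabric parameters calibrated to everyday loose trousers:
#: the waistband couples least stiffly (and picks up pouch/band interference),
#: the shank cuff most stiffly. Natural frequencies 3.2 / 3.9 / 8 Hz,
#: damping ratios ~0.35-0.45, gains slightly above 1.
DEFAULT_FABRIC = {
    "waist": FabricCoupling(stiffness=400.0, damping=14.0, gain=1.15, noise_sd=0.8),
    "thigh": FabricCoupling(stiffness=600.0, damping=20.0, gain=1.10, noise_sd=0.5),
    "lower_shank": FabricCoupling(stiffness=2500.0, damping=45.0, gain=1.06, noise_sd=0.3),
}


# ---------------------------------------------------------------------------
# Kinematics container


@dataclass
class SegmentKinematics:
    """Ground-truth sagittal segment-to-vertical angles on a uniform grid.

    ``event_times`` holds one ``(cycle_index, ms_time, ic_time, to_time)``
    tuple per complete walking cycle, in seconds on the same clock as
    ``time``. Rate channels are the exact analytic time derivatives of the
    angle channels in deg/s (optional; reconstructed by finite differences
    where absent).
    """

    time: np.ndarray
    angle_waist: np.ndarray
    angle_thigh: np.ndarray
    angle_shank: np.ndarray
    event_times: list[tuple[int, float, float, float]]
    stance_fraction: float
    rate_waist: np.ndarray | None = None
    rate_thigh: np.ndarray | None = None
    rate_shank: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("angle_waist", "angle_thigh", "angle_shank"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time.shape or not np.all(np.isfinite(arr)):
                raise InvalidParameterError(f"{name} must be finite, matching time")
            setattr(self, name, arr)
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-4 * dt[0]:
                raise InvalidParameterError("time must be a uniform increasing grid")
        prev_ms = -np.inf
        for k, ms, ic, to in self.event_times:
            if not prev_ms < ms < ic < to:
                raise InvalidParameterError(
                    f"cycle {k}: events must satisfy ms < ic < to and follow "
                    "the previous cycle"
                )
            prev_ms = ms

    def angle(self, placement: str) -> np.ndarray:
        return {
            "waist": self.angle_waist,
            "thigh": self.angle_thigh,
            "lower_shank": self.angle_shank,
        }[placement]

    def rate(self, placement: str) -> np.ndarray | None:
        return {
            "waist": self.rate_waist,
            "thigh": self.rate_thigh,
            "lower_shank": self.rate_shank,
        }[placement]

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the generator."""

    body: SegmentKinematics
    clothing: SegmentKinematics
    mountings: dict[tuple[str, str, str], MountingSpec]
    fabric: dict[str, FabricCoupling]


# ---------------------------------------------------------------------------
# Walking phase templates


def _von_mises_bump(u: np.ndarray, center: float, kappa: float) -> np.ndarray:
    """Smooth periodic bump on phase in [0, 1): exp(kappa * (cos(2pi(u-c)) - 1))."""
    return np.exp(kappa * (np.cos(2.0 * np.pi * (u - center)) - 1.0))


def _template_bumps(placement: str, stance_fraction: float):
    """Signed (amplitude, center, kappa) bumps of the rate shape per segment.

    IC sits at phase (1 - stance)/2 after MS (terminal swing), TO at
    IC + stance. The shank carries the sharpest event dips; the thigh a
    smoothed version; the waist a small two-bumps-per-stride pelvis wobble.
    """
    u_ic = (1.0 - stance_fraction) / 2.0
    u_to = u_ic + stance_fraction
    u_mid = 0.5 * (u_ic + u_to)
    if placement == "lower_shank":
        return [
            (1.0, 0.0, 8.0),
            (-0.25, u_ic, 12.0),
            (-0.35, u_to, 12.0),
            (-0.20, u_mid, 1.5),
        ]
    if placement == "thigh":
        return [
            (1.0, 0.0, 3.0),
            (-0.12, u_ic, 10.0),
            (-0.12, u_to, 10.0),
            (-0.35, u_mid, 1.2),
        ]
    if placement == "waist":
        return [(1.0, 0.0, 8.0), (0.7, 0.5, 10.0)]
    raise InvalidParameterError(f"unknown placement {placement!r}")


class _PhaseTemplate:
    """Normalized periodic angle/rate shapes for one segment.

    ``rate_shape(u)`` is analytic (zero cycle mean); ``angle_shape(u)`` is its
    exact primitive, normalized so the angle spans [-1, 1] over a cycle.
    """

    _GRID = 8192

    def __init__(self, placement: str, stance_fraction: float):
        self.bumps = _template_bumps(placement, stance_fraction)
        # cycle mean of each bump is amp * exp(-kappa) * I0(kappa)
        self.w_mean = sum(a * i0e(k) for a, _, k in self.bumps)
        u = np.linspace(0.0, 1.0, self._GRID + 1)
        w = self._w(u)
        base = cumulative_trapezoid(w - self.w_mean, u, initial=0.0)
        base -= base[-1] * u  # remove residual drift of the numeric primitive
        # anchor the angle at zero at mid-swing (the segment passes vertical
        # there), normalize to half the peak-to-peak span
        self.norm = 0.5 * (base.max() - base.min())
        self._u_grid = u
        self._base = (base - base[0]) / self.norm
        self.angle0 = 0.0

    def _w(self, u: np.ndarray) -> np.ndarray:
        out = np.zeros_like(u, dtype=float)
        for a, c, k in self.bumps:
            out += a * _von_mises_bump(u, c, k)
        return out

    def rate_shape(self, u: np.ndarray) -> np.ndarray:
        return (self._w(np.mod(u, 1.0)) - self.w_mean) / self.norm

    def angle_shape(self, u: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(u, 1.0), self._u_grid, self._base)


# ---------------------------------------------------------------------------
# Walking track


class _WalkingTrack:
    """Realized walking bout: per-cycle durations/amplitudes and event times.

    The bout starts and ends at phase ``_PHASE_START`` (early stance, near
    zero shank rate) so it splices smoothly between static activities; it
    contains ``n_cycles`` complete MS-to-MS cycles plus that partial lead-in
    and tail.
    """

    def __init__(self, gait: GaitParams, rng: np.random.Generator):
        self.gait = gait
        n = gait.n_cycles
        jitter = lambda: np.clip(  # noqa: E731
            1.0 + gait.variability * rng.standard_normal(n + 2), 0.5, 1.5
        )
        self.durations = gait.cycle_duration_s * jitter()
        self.amp_factors = jitter()
        self.templates = {p: _PhaseTemplate(p, gait.stance_fraction) for p in PLACEMENTS}
        # pseudo-cycle 0 is the lead-in [u0, 1); 1..n complete; n+1 the tail [0, u0)
        spans = self.durations.copy()
        spans[0] *= 1.0 - _PHASE_START
        spans[-1] *= _PHASE_START
        self.starts = np.concatenate([[0.0], np.cumsum(spans)])
        self.duration = float(self.starts[-1])

    def events(self, t0: float) -> list[tuple[int, float, float, float]]:
        u_ic = (1.0 - self.gait.stance_fraction) / 2.0
        u_to = u_ic + self.gait.stance_fraction
        out = []
        for k in range(1, self.gait.n_cycles + 1):
            ms = t0 + self.starts[k]
            T = self.durations[k]
            out.append((k - 1, float(ms), float(ms + u_ic * T), float(ms + u_to * T)))
        return out

    def _phases(self, t: np.ndarray):
        """Map bout-relative times to (pseudo-cycle index, phase, duration, amp)."""
        idx = np.clip(np.searchsorted(self.starts, t, side="right") - 1, 0, len(self.durations) - 1)
        T = self.durations[idx]
        u = (t - self.starts[idx]) / T
        u[idx == 0] += _PHASE_START
        return idx, u, T

    def evaluate(self, placement: str, t: np.ndarray, amplitude: float):
        """Angle (deg) and rate (deg/s) of one segment at bout-relative times."""
        tpl = self.templates[placement]
        idx, u, T = self._phases(np.asarray(t, dtype=float))
        a = self.amp_factors[idx]
        # anchor every cycle at the common boundary angle so amplitude jitter
        # cannot introduce steps at MS
        angle = amplitude * (a * (tpl.angle_shape(u) - tpl.angle0) + tpl.angle0)
        rate = amplitude * a * tpl.rate_shape(u) / T
        return angle, rate


def generate_kinematics(
    params: GaitParams, seed: int, sample_rate: float = 50.0
) -> SegmentKinematics:
    """Generate ground-truth walking kinematics for one bout.

    Returns smooth periodic-template angle trajectories for all three
    segments with embedded MS/IC/TO times for each of the ``n_cycles``
    complete cycles. Deterministic in ``seed``.
    """
    if sample_rate <= 0:
        raise InvalidParameterError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    track = _WalkingTrack(params, rng)
    dt = 1.0 / sample_rate
    t = np.arange(0.0, track.duration, dt)
    angles, rates = {}, {}
    for p in PLACEMENTS:
        angles[p], rates[p] = track.evaluate(p, t, params.amplitude(p))
    return SegmentKinematics(
        time=t,
        angle_waist=angles["waist"],
        angle_thigh=angles["thigh"],
        angle_shank=angles["lower_shank"],
        rate_waist=rates["waist"],
        rate_thigh=rates["thigh"],
        rate_shank=rates["lower_shank"],
        event_times=track.events(0.0),
        stance_fraction=params.stance_fraction,
    )


# ---------------------------------------------------------------------------
# Forward IMU model


def imu_from_kinematics(
    kin: SegmentKinematics,
    mount: MountingSpec,
    noise: ImuNoise = ZERO_NOISE,
    seed: int = 0,
) -> ImuTimeSeries:
    """Simulate one 6-axis IMU stream from segment kinematics.

    The segment is modelled as a rigid pendulum: the accelerometer senses
    gravity resolved into the segment frame plus the lever-arm tangential and
    centripetal accelerations, the gyroscope the sagittal rotation rate about
    the segment y-axis (negative angle derivative in the x-anterior / y-left
    / z-up frame). Both are then rotated into the sensor frame by the inverse
    mounting rotation, and white noise plus a constant gyroscope bias (drawn
    uniformly within ``+-gyro_bias_dps`` per axis) are added.
    """
    if len(kin.time) < 3:
        raise InsufficientDataError("need at least 3 samples to synthesize an IMU")
    theta_deg = kin.angle(mount.placement)
    rate_deg = kin.rate(mount.placement)
    if rate_deg is None:
        rate_deg = np.gradient(theta_deg, kin.time)
    theta = np.deg2rad(theta_deg)
    theta_dot = np.deg2rad(rate_deg)
    theta_ddot = np.gradient(theta_dot, kin.time)
    r = float(mount.lever_arm_m)
    f_seg = np.column_stack(
        [
            r * theta_ddot / GRAVITY_MS2 + np.sin(theta),
            np.zeros_like(theta),
            r * theta_dot**2 / GRAVITY_MS2 + np.cos(theta),
        ]
    )
    gyro_seg = np.column_stack(
        [np.zeros_like(rate_deg), -rate_deg, np.zeros_like(rate_deg)]
    )
    M = mount.mounting_rotation
    accel = f_seg @ M  # row-wise M.T @ v
    gyro = gyro_seg @ M
    rng = np.random.default_rng(seed)
    bias = rng.uniform(-noise.gyro_bias_dps, noise.gyro_bias_dps, 3)
    accel = accel + noise.accel_sd_g * rng.standard_normal(accel.shape)
    gyro = gyro + bias + noise.gyro_sd_dps * rng.standard_normal(gyro.shape)
    return ImuTimeSeries(
        time=kin.time.copy(),
        accel=accel,
        gyro=gyro,
        placement=mount.placement,
        attachment=mount.attachment,
        side=mount.side,
        sample_rate=kin.sample_rate,
    )


# ---------------------------------------------------------------------------
# Fabric coupling


def _fabric_channel(
    theta_b: np.ndarray, rate_b: np.ndarray, c: FabricCoupling, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the spring-damper tracking system for one angle channel.

    Uses exact matrix-exponential propagation of the LTI system with a cubic
    Hermite reconstruction of the driving angle between samples — fixed-step,
    deterministic, and unconditionally stable for any stiffness (including
    the rigid limit).
    """
    from scipy.linalg import expm

    A = np.array([[0.0, 1.0], [-c.stiffness, -c.damping]])
    B = np.array([0.0, c.stiffness * c.gain])
    # Exact propagation over one step with the input represented as the cubic
    # Hermite interpolant of (theta_b, rate_b): x[k+1] = Ad x[k] + sum_j c_j P_j
    # with P_j = integral_0^dt e^{A (dt - s)} B s^j ds. The P_j come from the
    # augmented exponential expm([[A, B, 0...], [0, N]]) with a nilpotent
    # integrator chain: its top blocks are P_j / j!. A linear-in-s input
    # (first-order hold) would be exact for the angle but carries a half-sample
    # lag in the rate channel; the Hermite form keeps the rigid limit exact in
    # both states.
    m = 4  # chain length: input polynomial degree 3
    M = np.zeros((2 + m, 2 + m))
    M[:2, :2] = A
    M[:2, 2] = B
    for j in range(m - 1):
        M[2 + j, 3 + j] = 1.0
    E = expm(M * dt)
    Ad = E[:2, :2]
    P = [math.factorial(j) * E[:2, 2 + j] for j in range(m)]
    n = len(theta_b)
    u0, u1 = theta_b[:-1], theta_b[1:]
    du0, du1 = rate_b[:-1], rate_b[1:]
    c0 = u0
    c1 = du0
    c2 = (3.0 * (u1 - u0) - (2.0 * du0 + du1) * dt) / dt**2
    c3 = (2.0 * (u0 - u1) + (du0 + du1) * dt) / dt**3
    x = np.empty((n, 2))
    x[0] = (c.gain * theta_b[0], rate_b[0])
    for k in range(n - 1):
        x[k + 1] = (
            Ad @ x[k] + c0[k] * P[0] + c1[k] * P[1] + c2[k] * P[2] + c3[k] * P[3]
        )
    theta_c = x[:, 0]
    rate_c = x[:, 1]
    if not (np.all(np.isfinite(theta_c)) and np.all(np.isfinite(rate_c))):
        raise NumericalFailureError(
            f"fabric integration diverged (stiffness={c.stiffness}, "
            f"damping={c.damping}, gain={c.gain})"
        )
    return theta_c, rate_c


def _band_limited_noise(
    n: int, sd_deg: float, cutoff_hz: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Fabric jitter: white noise low-passed at the fabric's own bandwidth."""
    if sd_deg == 0.0 or n < 20:
        return np.zeros(n)
    b, a = sps.butter(2, min(cutoff_hz, 0.45 * fs) / (fs / 2.0))
    x = sps.filtfilt(b, a, rng.standard_normal(n))
    s = x.std()
    return sd_deg * x / s if s > 0 else np.zeros(n)


def clothing_transform(
    kin: SegmentKinematics,
    coupling: FabricCoupling | dict[str, FabricCoupling],
    seed: int = 0,
) -> SegmentKinematics:
    """Derive clothing-mounted segment kinematics from body kinematics.

    Each angle channel is passed through its placement's spring-damper fabric
    model and band-limited angle noise is added; event times are copied
    unchanged from the body kinematics (they describe the gait, not the
    fabric).
    """
    couplings = (
        coupling if isinstance(coupling, dict) else {p: coupling for p in PLACEMENTS}
    )
    missing = set(PLACEMENTS) - set(couplings)
    if missing:
        raise InvalidParameterError(f"missing fabric couplings for {sorted(missing)}")
    dt = float(kin.time[1] - kin.time[0])
    fs = 1.0 / dt
    rng = np.random.default_rng(seed)
    out_angle, out_rate = {}, {}
    for p in PLACEMENTS:
        c = couplings[p]
        theta_b = kin.angle(p)
        rate_b = kin.rate(p)
        if rate_b is None:
            rate_b = np.gradient(theta_b, kin.time)
        theta_c, rate_c = _fabric_channel(theta_b, rate_b, c, dt)
        bandwidth = math.sqrt(c.stiffness) / (2.0 * math.pi)
        wobble = _band_limited_noise(len(theta_c), c.noise_sd, max(bandwidth, 1.0), fs, rng)
        out_angle[p] = theta_c + wobble
        out_rate[p] = rate_c + np.gradient(wobble, kin.time) if wobble.any() else rate_c
    return SegmentKinematics(
        time=kin.time.copy(),
        angle_waist=out_angle["waist"],
        angle_thigh=out_angle["thigh"],
        angle_shank=out_angle["lower_shank"],
        rate_waist=out_rate["waist"],
        rate_thigh=out_rate["thigh"],
        rate_shank=out_rate["lower_shank"],
        event_times=list(kin.event_times),
        stance_fraction=kin.stance_fraction,
    )


# ---------------------------------------------------------------------------
# Full sessions


def default_protocol() -> list[tuple[str, float | None]]:
    """The study protocol: five activities of roughly two minutes each.

    The walking entry's duration is ``None``: it is determined by the number
    of gait cycles requested in :class:`GaitParams`.
    """
    return [
        ("standing", 120.0),
        ("sitting", 120.0),
        ("sit_to_stand", 120.0),
        ("leg_raise", 120.0),
        ("walking", None),
    ]


def random_mounting(
    placement: str,
    attachment: str,
    rng: np.random.Generator,
    max_angle_deg: float = 60.0,
    side: str = "right",
) -> MountingSpec:
    """Draw a random sensor-on-segment orientation (uniform axis, bounded angle)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
    return MountingSpec(placement, attachment, side=side, mounting_rotation=R)


def _static_pose_track(pose: dict[str, float], n: int):
    return {p: (np.full(n, pose[p]), np.zeros(n)) for p in PLACEMENTS}


def _sit_to_stand_track(t: np.ndarray, duration: float, reps: int = 5):
    """Five sit-stand-sit repetitions with forward trunk lean at transitions."""
    Dr = duration / reps
    p = (t / Dr) % 1.0
    f = 0.5 * (1.0 - np.cos(2.0 * np.pi * p))  # 0 seated -> 1 standing -> 0
    df = np.pi * np.sin(2.0 * np.pi * p) / Dr
    lean = np.sin(2.0 * np.pi * p) ** 2  # peaks while rising and sitting down
    dlean = 2.0 * np.pi * np.sin(4.0 * np.pi * p) / Dr
    out = {}
    thigh0 = _SITTING_POSE["thigh"]
    shank0 = _SITTING_POSE["lower_shank"]
    out["waist"] = (-25.0 * lean, -25.0 * dlean)
    out["thigh"] = (thigh0 * (1.0 - f), -thigh0 * df)
    out["lower_shank"] = (
        shank0 * (1.0 - f) - 6.0 * lean,
        -shank0 * df - 6.0 * dlean,
    )
    return out


def _leg_raise_track(t: np.ndarray, duration: float, reps: int = 5):
    """Five standing leg raises: thigh to ~65 deg with knee flexion."""
    Dr = duration / reps
    p = (t / Dr) % 1.0
    q = np.sin(np.pi * p) ** 2
    dq = np.pi * np.sin(2.0 * np.pi * p) / Dr
    return {
        "waist": (4.0 * q, 4.0 * dq),
        "thigh": (-65.0 * q, -65.0 * dq),
        "lower_shank": (-20.0 * q, -20.0 * dq),
    }


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return x * x * (3.0 - 2.0 * x)


def generate_session(
    protocol: list[tuple[str, float | None]] | None = None,
    gait: GaitParams | None = None,
    noise: ImuNoise | None = None,
    fabric: dict[str, FabricCoupling] | None = None,
    mountings: dict[tuple[str, str, str], MountingSpec] | None = None,
    seed: int = 0,
    sample_rate: float = 50.0,
    subject: str = "S1",
    clothing_type: str = "jogging trousers",
    sensor_keys: list[tuple[str, str, str]] | None = None,
) -> tuple[SensorSession, GroundTruth]:
    """Simulate a full six-sensor session over an activity protocol.

    Builds ground-truth body kinematics segment by segment (with smooth
    1.5 s cross-fades between activities), derives clothing kinematics via
    the fabric model, draws a random mounting rotation per sensor, and
    synthesizes all IMU streams. ``sensor_keys`` restricts which of the six
    (placement, attachment, 'right') sensors are instrumented.

    Returns the session together with a :class:`GroundTruth` record. Fully
    deterministic in ``seed``.
    """
    protocol = list(protocol) if protocol is not None else default_protocol()
    gait = gait or GaitParams()
    noise = noise if noise is not None else ImuNoise()
    fabric = fabric or DEFAULT_FABRIC
    labels = [lab for lab, _ in protocol]
    if "standing" not in labels or "walking" not in labels:
        raise ConfigurationError(
            "protocol must include a standing segment (gravity alignment) and "
            "a walking segment (gait analysis)"
        )
    ss = np.random.SeedSequence(seed)
    kin_seed, fabric_seed, mount_seed, *imu_seeds = ss.spawn(9)
    dt = 1.0 / sample_rate

    # --- realize activity segments on a common clock
    walk_rng = np.random.default_rng(kin_seed)
    seg_curves = []  # per segment: dict placement -> (angle, rate)
    seg_bounds = []
    events: list[tuple[int, float, float, float]] = []
    t0 = 0.0
    for label, duration in protocol:
        if label == "walking":
            track = _WalkingTrack(gait, walk_rng)
            duration = track.duration
            n = int(round(duration / dt))
            tt = np.arange(n) * dt
            curves = {
                p: track.evaluate(p, tt, gait.amplitude(p)) for p in PLACEMENTS
            }
            events.extend(track.events(t0))
        else:
            if duration is None or duration <= 0:
                raise InvalidParameterError(f"{label} segment needs a positive duration")
            n = int(round(duration / dt))
            tt = np.arange(n) * dt
            if label == "standing":
                curves = _static_pose_track(_STANDING_POSE, n)
            elif label == "sitting":
                curves = _static_pose_track(_SITTING_POSE, n)
            elif label == "sit_to_stand":
                curves = _sit_to_stand_track(tt, duration)
            elif label == "leg_raise":
                curves = _leg_raise_track(tt, duration)
            else:
                raise ConfigurationError(f"unknown activity {label!r}")
        seg_curves.append(curves)
        seg_bounds.append((label, t0, t0 + n * dt))
        t0 += n * dt

    # --- concatenate and cross-fade activity boundaries
    angle = {p: np.concatenate([c[p][0] for c in seg_curves]) for p in PLACEMENTS}
    rate = {p: np.concatenate([c[p][1] for c in seg_curves]) for p in PLACEMENTS}
    n_total = len(angle["waist"])
    time = np.arange(n_total) * dt
    blend_n = int(round(_BLEND_S * sample_rate))
    offsets = np.cumsum([0] + [len(c["waist"][0]) for c in seg_curves])
    for i in range(1, len(seg_curves)):
        b = offsets[i]
        w = min(blend_n, offsets[i] - offsets[i - 1])
        if w < 2:
            continue
        s = _smoothstep(np.arange(w) / w)
        ds = 6.0 * (np.arange(w) / w) * (1.0 - np.arange(w) / w) / (w * dt)
        for p in PLACEMENTS:
            target = angle[p][b]
            prev = angle[p][b - w : b].copy()
            prev_rate = rate[p][b - w : b].copy()
            angle[p][b - w : b] = (1.0 - s) * prev + s * target
            rate[p][b - w : b] = (1.0 - s) * prev_rate + ds * (target - prev)

    body = SegmentKinematics(
        time=time,
        angle_waist=angle["waist"],
        angle_thigh=angle["thigh"],
        angle_shank=angle["lower_shank"],
        rate_waist=rate["waist"],
        rate_thigh=rate["thigh"],
        rate_shank=rate["lower_shank"],
        event_times=events,
        stance_fraction=gait.stance_fraction,
    )
    clothing = clothing_transform(body, fabric, seed=fabric_seed.generate_state(1)[0] % (2**31))

    # --- sensors
    if sensor_keys is None:
        sensor_keys = [(p, a, "right") for p in PLACEMENTS for a in ATTACHMENTS]
    mount_rng = np.random.default_rng(mount_seed)
    mounts = dict(mountings) if mountings else {}
    all_keys = [(p, a, "right") for p in PLACEMENTS for a in ATTACHMENTS]
    for key in all_keys:
        # always draw so the realized mountings do not depend on sensor_keys
        drawn = random_mounting(key[0], key[1], mount_rng)
        mounts.setdefault(key, drawn)
    sensors = {}
    for key, child in zip(all_keys, imu_seeds):
        if key not in sensor_keys:
            continue
        kin = body if key[1] == "body" else clothing
        sensors[key] = imu_from_kinematics(
            kin, mounts[key], noise, seed=child.generate_state(1)[0] % (2**31)
        )
    activities = [ActivitySegment(lab, a, b) for lab, a, b in seg_bounds]
    session = SensorSession(
        sensors=sensors,
        activities=activities,
        metadata={
            "sample_rate_hz": float(sample_rate),
            "subject": subject,
            "clothing_type": clothing_type,
        },
    )
    gt = GroundTruth(
        body=body,
        clothing=clothing,
        mountings={k: mounts[k] for k in sensor_keys},
        fabric=dict(fabric),
    )
    logger.info(
        "simulate: %d sensors, %d samples, %d ground-truth cycles",
        len(sensors),
        n_total,
        len(events),
    )
    return session, gt


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Serialize ground truth: events, mounting rotations and true angles."""
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        gt.body.event_times, columns=["cycle_index", "ms_time", "ic_time", "to_time"]
    ).to_csv(path / "ground_truth_events.csv", index=False, float_format="%.9f")
    rows = []
    for (p, a, _side), m in sorted(gt.mountings.items()):
        rows.append([p, a] + list(np.asarray(m.mounting_rotation).ravel()))
    pd.DataFrame(
        rows, columns=["placement", "attachment"] + [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)]
    ).to_csv(path / "ground_truth_mounting.csv", index=False, float_format="%.9f")
    for name, kin in (("body", gt.body), ("clothing", gt.clothing)):
        pd.DataFrame(
            {
                "time_s": kin.time,
                "angle_waist_deg": kin.angle_waist,
                "angle_thigh_deg": kin.angle_thigh,
                "angle_shank_deg": kin.angle_shank,
            }
        ).to_csv(path / f"ground_truth_angles_{name}.csv", index=False, float_format="%.6f")
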