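"""Madgwick orientation estimation and sensor-to-vertical angles.

Quaternions are scalar-first unit quaternions ``q = (q0, q1, q2, q3)``
mapping sensor-frame vectors into the world NWU frame (x north, y west,
z up) via ``r_world = q (x) r_sensor (x) q*``.

The sensor-to-vertical angle (SVA) is

    theta = arccos(2 q0 q2 + 2 q1 q3) - 90 deg,

the tilt of the sensor x-axis relative to horizontal, negative when the
segment is inclined (leaning forward) and positive when reclined. The
auxiliary z-axis angle ``theta_z = arccos(q0^2 - q1^2 - q2^2 + q3^2)`` is
the angle between the sensor z-axis and up; it cannot distinguish leaning
forward from backward and is reported for reference only.

The sagittal angular-velocity channel ``omega`` is the gyroscope rotation
rate about the medial-lateral axis oriented to the subject's right, i.e.
the negated y channel of the aligned gyroscope; with this sign omega is
the time derivative of theta, positive during the forward swing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import logger
from .errors import InvalidParameterError, InvalidQuaternionError
from .session import ImuTimeSeries

__all__ = [
    "QuaternionSeries",
    "SvaSeries",
    "madgwick_orientation",
    "sva_from_quaternion",
    "sva_z_from_quaternion",
    "angular_velocity_ml",
    "compute_sva",
]

_UNIT_TOL = 1e-9

#: Gravity-mismatch magnitude (in normalized objective units, ~rad) below
#: which the Madgwick correction scales proportionally instead of taking a
#: full normalized step.
_PROPORTIONAL_BAND = 0.1


@dataclass
class QuaternionSeries:
    """Per-sample scalar-first unit quaternions (sensor frame -> NWU)."""

    time: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.time), 4):
            raise InvalidQuaternionError(
                f"q must be (n, 4) matching time, got {self.q.shape}"
            )
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidQuaternionError(
                f"quaternions deviate from unit norm by up to "
                f"{np.max(np.abs(norms - 1.0)):.2e}"
            )
        dots = np.sum(self.q[1:] * self.q[:-1], axis=1)
        if np.any(dots < 0):
            raise InvalidQuaternionError("quaternion series has sign flips")


@dataclass
class SvaSeries:
    """Sensor-to-vertical angle track for one sensor.

    theta, theta_z in degrees; omega in deg/s (sagittal rate, see module
    docstring).
    """

    time: np.ndarray
    theta: np.ndarray
    theta_z: np.ndarray
    omega: np.ndarray
    placement: str
    attachment: str
    side: str = "right"

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("theta", "theta_z", "omega"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError(f"{name} length must match time")


def _quat_multiply(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    p0, p1, p2, p3 = p
    r0, r1, r2, r3 = r
    return np.array(
        [
            p0 * r0 - p1 * r1 - p2 * r2 - p3 * r3,
            p0 * r1 + p1 * r0 + p2 * r3 - p3 * r2,
            p0 * r2 - p1 * r3 + p2 * r0 + p3 * r1,
            p0 * r3 + p1 * r2 - p2 * r1 + p3 * r0,
        ]
    )


def _quat_exp_half(omega_rad: np.ndarray, dt: float) -> np.ndarray:
    """exp(dt/2 * omega) as a unit quaternion — exact for constant body rate."""
    angle = float(np.linalg.norm(omega_rad)) * dt
    if angle < 1e-14:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = omega_rad / np.linalg.norm(omega_rad)
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def _tilt_quaternion_from_accel(a: np.ndarray) -> np.ndarray:
    """Tilt-only initial quaternion mapping the measured gravity onto +z."""
    a_hat = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    d = float(np.clip(np.dot(a_hat, z), -1.0, 1.0))
    if d > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if d < -1.0 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180 deg about x
    axis = np.cross(a_hat, z)
    axis /= np.linalg.norm(axis)
    half = 0.5 * np.arccos(d)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def madgwick_orientation(
    series: ImuTimeSeries,
    beta: float = 0.1,
    q_init: np.ndarray | str = "from-accel",
    accel_gate_g: float | None = 0.1,
    rate_gate_dps: float = 60.0,
) -> QuaternionSeries:
    """Estimate per-sample orientation with the IMU Madgwick filter.

    Gyroscope integration (exact quaternion-exponential step) is corrected
    each sample by a normalized gradient-descent step of size ``beta``
    (rad/s) on the mismatch between the quaternion-predicted gravity
    direction and the normalized accelerometer reading. Samples with
    zero-norm acceleration get a gyro-only update. Quaternions are
    renormalized every step and kept sign-continuous.

    During vigorous motion the accelerometer measures gravity plus large
    kinematic (lever-arm) accelerations, and an ungated correction drags the
    attitude several degrees off within every gait cycle. The correction is
    therefore down-weighted away from quasi-static samples by a smooth taper
    that vanishes once the acceleration magnitude deviates from 1 g by
    ``accel_gate_g`` or the angular speed reaches ``rate_gate_dps`` (the
    magnitude criterion alone is fooled whenever gravity plus a large
    kinematic acceleration happens to cross 1 g mid-swing). Stance and
    static-activity samples keep the correction active often enough to bleed
    off residual gyroscope drift; the taper is continuous so that nearly
    identical input streams receive nearly identical corrections. Pass
    ``accel_gate_g=None`` to disable the gate and recover the textbook
    update.
    """
    if beta < 0:
        raise InvalidParameterError("beta must be non-negative")
    n = len(series)
    if n == 0 or (not np.any(series.accel) and not np.any(series.gyro)):
        raise InvalidParameterError("cannot orient an empty or all-zero series")
    dt = 1.0 / series.sample_rate
    if isinstance(q_init, str):
        if q_init != "from-accel":
            raise InvalidParameterError(f"unknown q_init mode {q_init!r}")
        norms = np.linalg.norm(series.accel, axis=1)
        if np.any(norms > 0):
            q = _tilt_quaternion_from_accel(series.accel[int(np.argmax(norms > 0))])
        else:
            q = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        q = np.asarray(q_init, dtype=float)
        if q.shape != (4,) or abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise InvalidQuaternionError("q_init must be a unit quaternion")
        q = q / np.linalg.norm(q)
    gyro_rad = np.deg2rad(series.gyro)
    out = np.empty((n, 4))
    warned = False
    for i in range(n):
        if i > 0:
            # trapezoidal body rate: q_k belongs to sample k, so stepping
            # k-1 -> k with the rectangle rule would lag by dt/2 * omega
            omega_mid = 0.5 * (gyro_rad[i - 1] + gyro_rad[i])
            q = _quat_multiply(q, _quat_exp_half(omega_mid, dt))
        a = series.accel[i]
        a_norm = np.linalg.norm(a)
        if accel_gate_g is None:
            weight = 1.0
        else:
            w_mag = max(0.0, 1.0 - abs(a_norm - 1.0) / accel_gate_g)
            w_rate = max(0.0, 1.0 - np.linalg.norm(series.gyro[i]) / rate_gate_dps)
            weight = w_mag * w_rate
        if a_norm > 0 and beta > 0 and weight > 0:
            ax, ay, az = a / a_norm
            q0, q1, q2, q3 = q
            f = np.array(
                [
                    2.0 * (q1 * q3 - q0 * q2) - ax,
                    2.0 * (q0 * q1 + q2 * q3) - ay,
                    2.0 * (0.5 - q1 * q1 - q2 * q2) - az,
                ]
            )
            J = np.array(
                [
                    [-2.0 * q2, 2.0 * q3, -2.0 * q0, 2.0 * q1],
                    [2.0 * q1, 2.0 * q0, 2.0 * q3, 2.0 * q2],
                    [0.0, -4.0 * q1, -4.0 * q2, 0.0],
                ]
            )
            grad = J.T @ f
            g_norm = np.linalg.norm(grad)
            if g_norm > 0:
                # slew-limited for large errors, proportional below ~6 deg of
                # gravity mismatch: a purely normalized step never settles
                # below beta*dt and leaves a limit-cycle jitter instead of
                # converging
                scale = min(1.0, np.linalg.norm(f) / _PROPORTIONAL_BAND)
                q = q - weight * beta * dt * scale * grad / g_norm
        elif a_norm == 0 and not warned:
            logger.warning("orientation: zero-norm accelerometer sample, gyro-only step")
            warned = True
        q = q / np.linalg.norm(q)
        if i > 0 and np.dot(q, out[i - 1]) < 0:
            q = -q
        out[i] = q
    return QuaternionSeries(time=series.time.copy(), q=out)


def _check_unit(qs: QuaternionSeries) -> np.ndarray:
    q = np.asarray(qs.q, dtype=float)
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise InvalidQuaternionError("quaternions are not unit norm")
    return q


def sva_from_quaternion(qs: QuaternionSeries) -> np.ndarray:
    """Sensor-to-vertical angle theta in degrees, in [-90, 90].

    The arccos argument is clamped to [-1, 1] to absorb rounding near
    vertical orientations.
    """
    q = _check_unit(qs)
    arg = np.clip(2.0 * (q[:, 0] * q[:, 2] + q[:, 1] * q[:, 3]), -1.0, 1.0)
    return np.degrees(np.arccos(arg)) - 90.0


def sva_z_from_quaternion(qs: QuaternionSeries) -> np.ndarray:
    """Angle between the sensor z-axis and up, degrees in [0, 180]."""
    q = _check_unit(qs)
    arg = np.clip(
        q[:, 0] ** 2 - q[:, 1] ** 2 - q[:, 2] ** 2 + q[:, 3] ** 2, -1.0, 1.0
    )
    return np.degrees(np.arccos(arg))


def angular_velocity_ml(series: ImuTimeSeries) -> np.ndarray:
    """Sagittal angular velocity omega in deg/s from an aligned series.

    The medial-lateral axis is taken pointing to the subject's right, so in
    the x-anterior / y-left / z-up aligned frame omega is the negated
    gyroscope y channel; positive omega = reclining (forward-swing) rotation
    = increasing theta.
    """
    return -series.gyro[:, 1]


def compute_sva(
    series: ImuTimeSeries,
    beta: float = 0.1,
    q_init="from-accel",
    accel_gate_g: float | None = 0.1,
    rate_gate_dps: float = 60.0,
) -> SvaSeries:
    """Full orientation stage for one aligned, filtered sensor stream."""
    qs = madgwick_orientation(
        series,
        beta=beta,
        q_init=q_init,
        accel_gate_g=accel_gate_g,
        rate_gate_dps=rate_gate_dps,
    )
    return SvaSeries(
        time=series.time.copy(),
        theta=sva_from_quaternion(qs),
        theta_z=sva_z_from_quaternion(qs),
        omega=angular_velocity_ml(series),
        placement=series.placement,
        attachment=series.attachment,
        side=series.side,
    )
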