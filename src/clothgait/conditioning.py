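"""Sensor-to-anatomy alignment and low-pass filtering.

Sensors are worn in unknown orientations relative to the limbs, so two
rotations bring every stream into a common anatomical frame before any
angle estimation:

1. a *gravity* rotation, built with Rodrigues' formula from the mean
   acceleration of a standing segment, aligning the sensor z-axis with up;
2. a *sagittal* rotation about the world z-axis, aligning the x-axis with
   the anterior-posterior direction found from the dominant horizontal
   acceleration during sagittal-plane movements (sit-to-stand, leg raises,
   walking).

A 180-degree yaw flip leaves every intrinsic second moment of a single
sensor's data unchanged, so the anterior *sign* cannot come from the
principal axis itself; it is resolved from the one reliable asymmetry of
gait, namely that the fastest sagittal rotation is the forward (reclining)
leg swing, visible as negative skewness of the medial-lateral gyroscope
channel in this frame. When gyroscope excitation is too weak the largest
horizontal-acceleration sample is used instead.

Filtering is a zero-phase (forward-backward) Butterworth low-pass applied
independently per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .config import PipelineConfig, logger
from .errors import (
    DegenerateAxisError,
    InsufficientDataError,
    InsufficientExcitationError,
    InvalidParameterError,
    NotStandingError,
)
from .session import ImuTimeSeries

__all__ = [
    "AlignmentRotations",
    "estimate_gravity_rotation",
    "estimate_sagittal_rotation",
    "apply_alignment",
    "lowpass_filter",
]


@dataclass
class AlignmentRotations:
    """The two alignment rotations, applied gravity-first."""

    r_gravity: np.ndarray
    r_sagittal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("r_gravity", "r_sagittal"):
            R = np.asarray(getattr(self, name), dtype=float)
            if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
                raise InvalidParameterError(f"{name} must be an orthonormal 3x3 matrix")
            if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
                raise InvalidParameterError(f"{name} must be proper (det +1)")
            setattr(self, name, R)
        if not np.allclose(self.r_sagittal @ [0, 0, 1], [0, 0, 1], atol=1e-9):
            raise InvalidParameterError("r_sagittal must leave the world z-axis fixed")

    @property
    def composed(self) -> np.ndarray:
        return self.r_sagittal @ self.r_gravity


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis by an angle (Rodrigues' formula)."""
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def estimate_gravity_rotation(
    standing: ImuTimeSeries, config: PipelineConfig | None = None
) -> np.ndarray:
    """Rotation aligning the sensor z-axis with gravity from standing data.

    The axis is the unit vector perpendicular to both the mean measured
    acceleration and (0, 0, 1); the angle is the angle between them. The
    returned matrix maps the mean acceleration onto ``(0, 0, ||a||)``.

    Raises
    ------
    NotStandingError
        if the mean acceleration magnitude falls outside the quasi-static
        band (the segment is not quiet standing).
    DegenerateAxisError
        if the mean acceleration is antiparallel to z (axis undefined).
    """
    config = config or PipelineConfig()
    if len(standing) < int(2.0 * standing.sample_rate):
        raise InsufficientDataError("standing segment must be at least 2 s long")
    a = standing.accel.mean(axis=0)
    mag = float(np.linalg.norm(a))
    if not config.quasi_static_low_g <= mag <= config.quasi_static_high_g:
        raise NotStandingError(
            f"mean acceleration magnitude {mag:.3f} g outside quasi-static band "
            f"[{config.quasi_static_low_g}, {config.quasi_static_high_g}] g"
        )
    a_hat = a / mag
    cos_angle = float(np.clip(a_hat[2], -1.0, 1.0))
    angle = float(np.arccos(cos_angle))
    if angle > np.deg2rad(179.0):
        raise DegenerateAxisError(
            "mean acceleration is antiparallel to z: rotation axis undefined"
        )
    if angle < 1e-12:
        return np.eye(3)
    axis = np.cross(a_hat, [0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    return _rodrigues(axis, angle)


def estimate_sagittal_rotation(
    dynamic: ImuTimeSeries,
    config: PipelineConfig | None = None,
    sign_reference: ImuTimeSeries | None = None,
) -> np.ndarray:
    """Rotation about z mapping the dominant horizontal acceleration to x.

    ``dynamic`` must already be gravity-aligned. The axis is the first
    principal component of the zero-meaned horizontal (x, y) acceleration.
    The sign is taken from ``sign_reference`` (defaults to ``dynamic``;
    pass the walking segment when available): the yaw is chosen so the
    medial-lateral gyroscope skewness is negative — forward leg swing — or,
    without usable gyroscope excitation, so the largest-magnitude horizontal
    acceleration sample projects positively on the new x-axis.
    """
    config = config or PipelineConfig()
    if len(dynamic) < int(5.0 * dynamic.sample_rate):
        raise InsufficientDataError("dynamic segment must be at least 5 s long")
    h = dynamic.accel[:, :2] - dynamic.accel[:, :2].mean(axis=0)
    cov = h.T @ h / len(h)
    if float(np.trace(cov)) < config.min_horizontal_var_g2:
        raise InsufficientExcitationError(
            f"horizontal acceleration variance {np.trace(cov):.2e} g^2 below "
            f"threshold {config.min_horizontal_var_g2:.2e} g^2"
        )
    evals, evecs = np.linalg.eigh(cov)
    d = evecs[:, int(np.argmax(evals))]  # dominant direction, sign arbitrary

    def yaw_matrix(direction: np.ndarray) -> np.ndarray:
        c, s = direction  # rotate direction onto +x
        return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    ref = sign_reference if sign_reference is not None else dynamic
    gyro_y = ref.gyro @ yaw_matrix(d)[1]  # candidate medial-lateral channel
    if np.max(np.abs(gyro_y)) >= config.gyro_sign_min_excursion_dps:
        flip = stats.skew(gyro_y) > 0
    else:
        ref_h = ref.accel[:, :2] - ref.accel[:, :2].mean(axis=0)
        proj = ref_h @ d
        flip = proj[int(np.argmax(np.abs(proj)))] < 0
    if flip:
        d = -d
    return yaw_matrix(d)


def apply_alignment(series: ImuTimeSeries, rot: AlignmentRotations) -> ImuTimeSeries:
    """Rotate accelerometer and gyroscope sample-wise by r_sagittal @ r_gravity."""
    R = rot.composed
    return series.replace(accel=series.accel @ R.T, gyro=series.gyro @ R.T)


def lowpass_filter(
    series: ImuTimeSeries, cutoff_hz: float = 3.0, order: int = 2
) -> ImuTimeSeries:
    """Zero-phase Butterworth low-pass, per channel; DC gain exactly 1.

    The filter runs forwards and backwards (``filtfilt`` with odd-reflection
    edge padding) so the net group delay is zero and event timings are
    preserved.
    """
    if cutoff_hz >= series.sample_rate / 2.0:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie below Nyquist "
            f"({series.sample_rate / 2.0} Hz)"
        )
    padlen = 3 * (order + 1)
    if len(series) <= max(padlen, 6 * order):
        raise InsufficientDataError(
            f"series of {len(series)} samples too short for stable zero-phase "
            f"filtering (need > {max(padlen, 6 * order)})"
        )
    b, a = sps.butter(order, cutoff_hz / (series.sample_rate / 2.0))
    return series.replace(
        accel=sps.filtfilt(b, a, series.accel, axis=0),
        gyro=sps.filtfilt(b, a, series.gyro, axis=0),
    )


def remove_gyro_bias(
    series: ImuTimeSeries, standing: ImuTimeSeries
) -> tuple[ImuTimeSeries, np.ndarray]:
    """Static gyroscope-bias calibration.

    The mean gyroscope reading over a quiet standing segment estimates the
    constant rate bias (the true rate there is zero); it is subtracted from
    every sample. Returns the corrected series and the bias estimate
    (deg/s).
    """
    if len(standing) < int(2.0 * standing.sample_rate):
        raise InsufficientDataError("standing segment must be at least 2 s long")
    bias = standing.gyro.mean(axis=0)
    return series.replace(gyro=series.gyro - bias), bias


def align_and_filter(
    series: ImuTimeSeries,
    standing: ImuTimeSeries,
    dynamic: ImuTimeSeries,
    config: PipelineConfig,
    sign_reference: ImuTimeSeries | None = None,
) -> tuple[ImuTimeSeries, AlignmentRotations]:
    """Convenience composition: gyro-bias removal, both rotations, filter."""
    series, bias = remove_gyro_bias(series, standing)
    logger.debug("align: gyro bias %s deg/s removed", np.round(bias, 3))
    r_g = estimate_gravity_rotation(standing, config)
    partial = AlignmentRotations(r_gravity=r_g, r_sagittal=np.eye(3))
    dyn_aligned = apply_alignment(dynamic, partial)
    ref_aligned = (
        apply_alignment(sign_reference, partial) if sign_reference is not None else None
    )
    r_s = estimate_sagittal_rotation(dyn_aligned, config, sign_reference=ref_aligned)
    rots = AlignmentRotations(r_gravity=r_g, r_sagittal=r_s)
    aligned = apply_alignment(series, rots)
    logger.debug(
        "align: %s/%s yaw %.1f deg",
        series.placement,
        series.attachment,
        np.degrees(np.arctan2(r_s[0, 1], r_s[0, 0])),
    )
    return lowpass_filter(aligned, config.filter_cutoff_hz, config.filter_order), rots
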