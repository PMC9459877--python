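"""Session containers and the columnar file formats.

A *session* is one multi-sensor recording: six synchronized 6-axis IMU streams
(waist / thigh / lower shank, each body- and clothing-mounted) plus an
activity annotation track. On disk a session is a directory of plain CSV
files:

``imu.csv``
    long format, one row per sample per sensor, columns
    ``time_s, placement, attachment, side, ax_g, ay_g, az_g, gx_dps, gy_dps,
    gz_dps``. Accelerometers in g, gyroscopes in deg/s.
``activities.csv``
    columns ``label, start_s, end_s``; non-overlapping intervals.
``metadata.yaml``
    ``sample_rate_hz``, ``subject``, ``clothing_type`` free text.

Values round-trip at 9 decimal digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .config import ACTIVITIES, ATTACHMENTS, PLACEMENTS, SIDES
from .errors import SchemaError, SynchronizationError

IMU_COLUMNS = [
    "time_s",
    "placement",
    "attachment",
    "side",
    "ax_g",
    "ay_g",
    "az_g",
    "gx_dps",
    "gy_dps",
    "gz_dps",
]
ACTIVITY_COLUMNS = ["label", "start_s", "end_s"]

#: Relative tolerance on the constancy of the sampling step.
_DT_RTOL = 1e-4


@dataclass
class ImuTimeSeries:
    """One sensor's synchronized accelerometer/gyroscope record.

    time
        seconds, uniform grid.
    accel
        (n, 3) in g, sensor frame.
    gyro
        (n, 3) in deg/s, sensor frame.
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    placement: str
    attachment: str
    side: str = "right"
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.time.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise SchemaError(
                f"accel/gyro must be (n, 3) arrays matching time (n={n}); "
                f"got {self.accel.shape} and {self.gyro.shape}"
            )
        if not (
            np.all(np.isfinite(self.time))
            and np.all(np.isfinite(self.accel))
            and np.all(np.isfinite(self.gyro))
        ):
            raise SchemaError("IMU series contains non-finite values")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise SchemaError(f"time not strictly increasing at sample {row}")
            step = float(np.median(dt))
            if np.max(np.abs(dt - step)) > _DT_RTOL * step:
                raise SchemaError("sampling step not constant within 1e-4")
        if self.placement not in PLACEMENTS:
            raise SchemaError(f"unknown placement {self.placement!r}")
        if self.attachment not in ATTACHMENTS:
            raise SchemaError(f"unknown attachment {self.attachment!r}")
        if self.side not in SIDES:
            raise SchemaError(f"unknown side {self.side!r}")

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.placement, self.attachment, self.side)

    def accel_magnitude(self) -> np.ndarray:
        """Per-sample Euclidean norm of the acceleration, in g."""
        return np.linalg.norm(self.accel, axis=1)

    def replace(self, **kw) -> "ImuTimeSeries":
        data = dict(
            time=self.time,
            accel=self.accel,
            gyro=self.gyro,
            placement=self.placement,
            attachment=self.attachment,
            side=self.side,
            sample_rate=self.sample_rate,
        )
        data.update(kw)
        return ImuTimeSeries(**data)

    def slice(self, start: int, stop: int) -> "ImuTimeSeries":
        return self.replace(
            time=self.time[start:stop],
            accel=self.accel[start:stop],
            gyro=self.gyro[start:stop],
        )


@dataclass
class ActivitySegment:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in ACTIVITIES:
            raise SchemaError(f"unknown activity label {self.label!r}")
        if not self.end_s > self.start_s:
            raise SchemaError(f"activity {self.label}: end must follow start")


@dataclass
class SensorSession:
    """A full multi-sensor recording with activity annotations."""

    sensors: dict[tuple[str, str, str], ImuTimeSeries]
    activities: list[ActivitySegment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sensors:
            raise SchemaError("session has no sensors")
        times = [s.time for s in self.sensors.values()]
        ref = times[0]
        for t in times[1:]:
            if t.shape != ref.shape or not np.allclose(t, ref, atol=1e-9):
                raise SynchronizationError("sensors do not share one time base")
        segs = sorted(self.activities, key=lambda a: a.start_s)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise SchemaError(
                    f"activity intervals overlap: {a.label} and {b.label}"
                )
        # activity intervals are half-open: the record spans t[-1] + dt
        step = float(np.median(np.diff(ref))) if ref.size > 1 else 0.0
        t_end = (float(ref[-1]) + step) if ref.size else 0.0
        for a in segs:
            if a.start_s < -1e-9 or a.end_s > t_end + 1e-6:
                raise SchemaError(f"activity {a.label} lies outside the record")

    @property
    def time(self) -> np.ndarray:
        return next(iter(self.sensors.values())).time

    @property
    def sample_rate(self) -> float:
        return float(self.metadata.get("sample_rate_hz", 50.0))

    def sensor(self, placement: str, attachment: str, side: str = "right"):
        return self.sensors.get((placement, attachment, side))

    def segments(self, label: str) -> list[tuple[int, int]]:
        """Index ranges [start, stop) of all segments with the given label."""
        t = self.time
        out = []
        for a in self.activities:
            if a.label == label:
                start = int(np.searchsorted(t, a.start_s - 1e-9))
                stop = int(np.searchsorted(t, a.end_s - 1e-9))
                if stop > start:
                    out.append((start, stop))
        return out


# ---------------------------------------------------------------------------
# File round trip


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def write_session(session: SensorSession, path) -> None:
    """Write a session directory (imu.csv, activities.csv, metadata.yaml)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = []
    for key in sorted(session.sensors):
        s = session.sensors[key]
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.time,
                    "placement": s.placement,
                    "attachment": s.attachment,
                    "side": s.side,
                    "ax_g": s.accel[:, 0],
                    "ay_g": s.accel[:, 1],
                    "az_g": s.accel[:, 2],
                    "gx_dps": s.gyro[:, 0],
                    "gy_dps": s.gyro[:, 1],
                    "gz_dps": s.gyro[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path / "imu.csv", index=False, float_format="%.9f"
    )
    pd.DataFrame(
        [(a.label, a.start_s, a.end_s) for a in session.activities],
        columns=ACTIVITY_COLUMNS,
    ).to_csv(path / "activities.csv", index=False, float_format="%.9f")
    with open(path / "metadata.yaml", "w") as fh:
        yaml.safe_dump(session.metadata, fh, sort_keys=True)


def read_session(path) -> SensorSession:
    """Read a session directory written by :func:`write_session`.

    Schema violations raise :class:`SchemaError` naming the file and, for
    ordering problems, the first offending data row (1-based, excluding the
    header).
    """
    path = Path(path)
    imu_path = path / "imu.csv"
    if not imu_path.exists():
        raise SchemaError(f"{imu_path}: file not found")
    df = pd.read_csv(imu_path)
    _require_columns(df, IMU_COLUMNS, imu_path)
    sensors: dict[tuple[str, str, str], ImuTimeSeries] = {}
    meta_path = path / "metadata.yaml"
    metadata = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = yaml.safe_load(fh) or {}
    rate = float(metadata.get("sample_rate_hz", 50.0))
    for key, group in df.groupby(["placement", "attachment", "side"], sort=True):
        t = group["time_s"].to_numpy()
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            row = int(group.index[bad[0] + 1]) + 1
            raise SchemaError(
                f"{imu_path}: non-monotonic time for sensor {key} at data row {row}"
            )
        sensors[key] = ImuTimeSeries(
            time=t,
            accel=group[["ax_g", "ay_g", "az_g"]].to_numpy(),
            gyro=group[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(),
            placement=key[0],
            attachment=key[1],
            side=key[2],
            sample_rate=rate,
        )
    steps = {round(float(np.median(np.diff(s.time))), 9) for s in sensors.values() if len(s) > 1}
    if len(steps) > 1:
        raise SchemaError(f"{imu_path}: mixed sample rates {sorted(steps)}")
    act_path = path / "activities.csv"
    if not act_path.exists():
        raise SchemaError(f"{act_path}: file not found")
    adf = pd.read_csv(act_path)
    _require_columns(adf, ACTIVITY_COLUMNS, act_path)
    activities = [
        ActivitySegment(str(r.label), float(r.start_s), float(r.end_s))
        for r in adf.itertuples()
    ]
    return SensorSession(sensors=sensors, activities=activities, metadata=metadata)
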