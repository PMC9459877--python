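"""Gait-cycle extraction from lower-shank signals.

Mid-swing (MS) instants are high peaks of the lower-shank acceleration
magnitude (above 2.0 g for clothing-mounted and 1.8 g for body-mounted
sensors, at most one peak per 1 s window). Cycles run MS-to-MS with one
fixed length per session — the rounded mean MS-to-MS gap — so that cycles
can be averaged without time normalisation. Within each cycle, initial
contact (IC) is the first prominent local minimum of the sagittal
angular-velocity channel after the MS start and toe-off (TO) the last
prominent local minimum before the cycle end. Waist and thigh streams,
being synchronized with the shank, are segmented with the same start and
end points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import logger
from .errors import CannotSegmentError, EmptyResultError, SynchronizationError

__all__ = [
    "Cycle",
    "GaitCycleSet",
    "detect_midswing",
    "segment_cycles",
    "detect_ic_to",
    "propagate_segmentation",
    "stance_fraction",
]


@dataclass
class Cycle:
    """One fixed-length gait cycle: absolute sample indices."""

    start: int
    ic: int | None = None
    to: int | None = None
    flagged: bool = False


@dataclass
class GaitCycleSet:
    """Mid-swing segmentation of one session for one attachment."""

    ms_indices: np.ndarray
    cycle_length: int
    cycles: list[Cycle]
    source_attachment: str = "body"
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        self.ms_indices = np.asarray(self.ms_indices, dtype=int)
        if np.any(np.diff(self.ms_indices) <= 0):
            raise CannotSegmentError("ms_indices must be strictly increasing")

    @property
    def valid_cycles(self) -> list[Cycle]:
        return [c for c in self.cycles if not c.flagged]

    @property
    def n_flagged(self) -> int:
        return sum(c.flagged for c in self.cycles)


def _refine_extremum(
    values: np.ndarray, idx: int, radius: int, find_max: bool
) -> int:
    lo = max(0, idx - radius)
    hi = min(values.size, idx + radius + 1)
    window = values[lo:hi]
    return lo + int(np.argmax(window) if find_max else np.argmin(window))


def detect_midswing(
    accel_mag: np.ndarray,
    threshold_g: float,
    min_separation_s: float = 1.0,
    sample_rate: float = 50.0,
    refine_mag: np.ndarray | None = None,
    refine_radius_s: float = 0.12,
) -> np.ndarray:
    """Mid-swing peaks: local maxima of ||accel|| above a threshold.

    Within any window shorter than ``min_separation_s`` only the largest
    peak is retained (greedy, largest first) — one mid-swing per stride at
    normal cadence. The threshold must exceed the 1 g gravity baseline.

    Detection is normally run on the low-passed magnitude (robust against
    broadband heel-strike transients). The acceleration magnitude localizes
    mid-swing only coarsely — its centripetal peak is flanked by tangential
    lobes of similar size — so ``refine_mag`` may carry a sharper
    synchronized signal whose local maximum pinpoints mid-swing (the raw
    sagittal angular velocity, maximal at mid-swing by definition); each
    retained peak is relocated to that signal's maximum within
    ``refine_radius_s``.

    Returns sorted sample indices; an empty array (with a warning) for
    series too short to contain a peak.
    """
    if threshold_g <= 1.0:
        raise ValueError("mid-swing threshold must exceed the 1 g gravity baseline")
    accel_mag = np.asarray(accel_mag, dtype=float)
    if accel_mag.size < 3:
        warnings.warn("series too short for mid-swing detection", stacklevel=2)
        return np.array([], dtype=int)
    peaks, props = sps.find_peaks(accel_mag, height=threshold_g)
    if peaks.size == 0:
        return np.array([], dtype=int)
    min_gap = min_separation_s * sample_rate
    order = np.argsort(props["peak_heights"])[::-1]
    kept: list[int] = []
    for idx in peaks[order]:
        if all(abs(idx - k) >= min_gap for k in kept):
            kept.append(int(idx))
    if refine_mag is not None:
        radius = int(round(refine_radius_s * sample_rate))
        refine_mag = np.asarray(refine_mag, dtype=float)
        kept = [_refine_extremum(refine_mag, k, radius, find_max=True) for k in kept]
    return np.array(sorted(set(kept)), dtype=int)


def segment_cycles(
    ms_indices: np.ndarray,
    series_length: int,
    sample_rate: float = 50.0,
    source_attachment: str = "body",
) -> GaitCycleSet:
    """Cut fixed-length cycles at each mid-swing point.

    The common cycle length is the rounded mean of consecutive MS gaps;
    cycles whose fixed window would run past the end of the series are
    dropped. Because each window has the *mean* length, windows may overlap
    or leave small gaps where individual strides deviate from the mean —
    the accepted cost of avoiding time normalisation.
    """
    ms_indices = np.asarray(ms_indices, dtype=int)
    if ms_indices.size < 2:
        raise CannotSegmentError(
            f"need at least 2 mid-swing points to segment, got {ms_indices.size}"
        )
    gaps = np.diff(ms_indices)
    cycle_length = int(round(float(np.mean(gaps))))
    cycles = [
        Cycle(start=int(m))
        for m in ms_indices
        if m + cycle_length <= series_length
    ]
    logger.info(
        "segment: %d MS points, cycle length %d samples, %d cycles fit",
        ms_indices.size,
        cycle_length,
        len(cycles),
    )
    return GaitCycleSet(
        ms_indices=ms_indices,
        cycle_length=cycle_length,
        cycles=cycles,
        source_attachment=source_attachment,
        sample_rate=sample_rate,
    )


def detect_ic_to(
    shank_omega: np.ndarray,
    cycles: GaitCycleSet,
    prominence_dps: float = 30.0,
    refine_omega: np.ndarray | None = None,
    refine_radius_s: float = 0.08,
) -> GaitCycleSet:
    """Fill IC and TO for each cycle from the shank angular-velocity minima.

    IC is the first local minimum of prominence at least ``prominence_dps``
    after the cycle's MS start, TO the last such minimum before the cycle
    end. Cycles missing either event (flat or monotone windows) are flagged
    and excluded from downstream statistics, not raised as errors.

    As with mid-swing detection, passing the raw (unfiltered) angular
    velocity as ``refine_omega`` relocates each minimum to the raw local
    minimum within ``refine_radius_s``, removing the timing bias that the
    low-pass smearing of the neighbouring swing peak would otherwise cause.
    """
    shank_omega = np.asarray(shank_omega, dtype=float)
    radius = int(round(refine_radius_s * cycles.sample_rate))
    n_flagged = 0
    for cyc in cycles.cycles:
        window = shank_omega[cyc.start : cyc.start + cycles.cycle_length]
        minima, _ = sps.find_peaks(-window, prominence=prominence_dps)
        if minima.size >= 2:
            ic = cyc.start + int(minima[0])
            to = cyc.start + int(minima[-1])
            if refine_omega is not None:
                ic = _refine_extremum(refine_omega, ic, radius, find_max=False)
                to = _refine_extremum(refine_omega, to, radius, find_max=False)
            cyc.ic, cyc.to = ic, to
            cyc.flagged = not ic < to
            n_flagged += cyc.flagged
        else:
            cyc.ic = cyc.to = None
            cyc.flagged = True
            n_flagged += 1
    if n_flagged:
        logger.info("events: %d/%d cycles flagged (missing IC/TO)", n_flagged, len(cycles.cycles))
    return cycles


def propagate_segmentation(
    cycles: GaitCycleSet,
    values: np.ndarray,
    time: np.ndarray | None = None,
    reference_time: np.ndarray | None = None,
    include_flagged: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut any synchronized stream into the per-cycle matrix.

    Returns ``(matrix, mean, sd)`` where ``matrix`` is n_cycles x
    cycle_length and mean/sd are pointwise across cycles (the mean-cycle
    band plot surface). ``time``/``reference_time`` may be passed to verify
    the stream shares the cycle set's time base.
    """
    values = np.asarray(values, dtype=float)
    if time is not None and reference_time is not None:
        if len(time) != len(reference_time) or not np.allclose(
            time, reference_time, atol=1e-9
        ):
            raise SynchronizationError("stream time base differs from the cycle set's")
    rows = [
        values[c.start : c.start + cycles.cycle_length]
        for c in cycles.cycles
        if (include_flagged or not c.flagged)
        and c.start + cycles.cycle_length <= values.size
    ]
    if not rows:
        raise EmptyResultError("no unflagged cycles to propagate")
    matrix = np.vstack(rows)
    return matrix, matrix.mean(axis=0), matrix.std(axis=0, ddof=0)


def stance_fraction(cycles: GaitCycleSet) -> tuple[np.ndarray, float]:
    """Per-cycle (TO - IC) / cycle_length over unflagged cycles, and its mean."""
    vals = [
        (c.to - c.ic) / cycles.cycle_length
        for c in cycles.cycles
        if not c.flagged and c.ic is not None and c.to is not None
    ]
    if not vals:
        raise EmptyResultError("no valid cycles with IC/TO to compute stance fraction")
    arr = np.asarray(vals, dtype=float)
    return arr, float(arr.mean())
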