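"""Agreement between clothing- and body-mounted sensor pairs.

For each placement the two synchronized SVA streams are cut with a common
cycle set and compared: Pearson correlation per gait cycle, and
clothing-minus-body angle differences during quiet standing, at initial
contact, and at the instant in stance when the body-mounted lower-shank
sensor is vertical (theta crosses zero). Phase portraits (omega against
theta over one cycle, with MS/IC/TO markers) summarize cycle shape and
range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import logger
from .errors import EmptyResultError, InvalidParameterError
from .segmentation import GaitCycleSet
from .orientation import SvaSeries

__all__ = [
    "PairComparison",
    "PhasePortrait",
    "per_cycle_correlation",
    "angle_difference_at",
    "find_shank_vertical",
    "assemble_phase_portrait",
]


@dataclass
class PairComparison:
    """Agreement summary for one clothing/body sensor pair."""

    placement: str
    r_per_cycle: np.ndarray
    r_mean: float
    diff_standing: tuple[float, float]  # (mean, sd), degrees
    diff_ic: tuple[float, float]
    diff_shank_vertical: tuple[float, float]
    n_cycles: int
    shapiro_p: float | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.r_per_cycle = np.asarray(self.r_per_cycle, dtype=float)
        if self.n_cycles != len(self.r_per_cycle):
            raise InvalidParameterError("n_cycles must equal len(r_per_cycle)")
        if self.r_per_cycle.size and (
            np.nanmax(self.r_per_cycle) > 1 + 1e-9 or np.nanmin(self.r_per_cycle) < -1 - 1e-9
        ):
            raise InvalidParameterError("correlations must lie in [-1, 1]")


@dataclass
class PhasePortrait:
    """One cycle's (theta, omega) trajectory with event markers."""

    theta: np.ndarray
    omega: np.ndarray
    markers: dict[str, int | None]
    theta_range: float = field(init=False)
    omega_range: float = field(init=False)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.theta.shape != self.omega.shape:
            raise InvalidParameterError("theta and omega must have equal length")
        n = self.theta.size
        for name, idx in self.markers.items():
            if idx is not None and not 0 <= idx < n:
                raise InvalidParameterError(f"marker {name} out of range")
        self.theta_range = float(np.ptp(self.theta)) if n else 0.0
        self.omega_range = float(np.ptp(self.omega)) if n else 0.0


def per_cycle_correlation(
    sva_body: np.ndarray, sva_clothing: np.ndarray
) -> tuple[np.ndarray, float, float | None, int]:
    """Pearson correlation of each cycle row of the two per-cycle matrices.

    Returns ``(r_per_cycle, r_mean, shapiro_p, n_excluded)``. Zero-variance
    cycles have undefined correlation and are excluded with a warning. The
    normality of the per-cycle correlations is screened with a Shapiro-Wilk
    test and reported, but never blocks the computation.
    """
    b = np.asarray(sva_body, dtype=float)
    c = np.asarray(sva_clothing, dtype=float)
    if b.shape != c.shape or b.ndim != 2:
        raise InvalidParameterError(
            f"matrices must share shape (n_cycles, cycle_length); got {b.shape} vs {c.shape}"
        )
    bc = b - b.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    sb = np.sqrt((bc**2).sum(axis=1))
    sc = np.sqrt((cc**2).sum(axis=1))
    ok = (sb > 0) & (sc > 0)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} zero-variance cycle(s) excluded from correlation",
            stacklevel=2,
        )
    r = (bc[ok] * cc[ok]).sum(axis=1) / (sb[ok] * sc[ok])
    if r.size == 0:
        raise EmptyResultError("no cycles with positive variance to correlate")
    shapiro_p = None
    if r.size >= 3 and np.ptp(r) > 0:
        shapiro_p = float(stats.shapiro(r).pvalue)
        if shapiro_p < 0.05:
            logger.info("comparison: Shapiro-Wilk p=%.3g (non-normal r distribution)", shapiro_p)
    return r, float(r.mean()), shapiro_p, n_excluded


def angle_difference_at(
    sva_body: SvaSeries | np.ndarray,
    sva_clothing: SvaSeries | np.ndarray,
    event: str,
    cycles: GaitCycleSet | None = None,
    standing_range: tuple[int, int] | None = None,
    vertical_indices: list[int | None] | None = None,
) -> tuple[float, float]:
    """Mean and SD of the clothing-minus-body angle at a gait event.

    ``event`` selects the sampling points: ``"standing"`` uses every sample
    of the given standing index range; ``"ic"`` the IC sample of each
    unflagged cycle; ``"shank_vertical"`` the per-cycle indices returned by
    :func:`find_shank_vertical` (None entries skipped).
    """
    tb = sva_body.theta if isinstance(sva_body, SvaSeries) else np.asarray(sva_body)
    tc = (
        sva_clothing.theta
        if isinstance(sva_clothing, SvaSeries)
        else np.asarray(sva_clothing)
    )
    if event == "standing":
        if standing_range is None:
            raise InvalidParameterError("standing event needs a standing index range")
        lo, hi = standing_range
        diffs = tc[lo:hi] - tb[lo:hi]
    elif event == "ic":
        if cycles is None:
            raise InvalidParameterError("ic event needs a cycle set")
        idx = [c.ic for c in cycles.valid_cycles if c.ic is not None]
        diffs = tc[idx] - tb[idx] if idx else np.array([])
    elif event == "shank_vertical":
        if vertical_indices is None:
            raise InvalidParameterError(
                "shank_vertical event needs the per-cycle vertical indices"
            )
        idx = [i for i in vertical_indices if i is not None]
        diffs = tc[idx] - tb[idx] if idx else np.array([])
    else:
        raise InvalidParameterError(f"unknown event {event!r}")
    if len(diffs) == 0:
        raise EmptyResultError(f"no samples available for event {event!r}")
    return float(np.mean(diffs)), float(np.std(diffs, ddof=0))


def find_shank_vertical(
    theta_body_shank: np.ndarray, cycles: GaitCycleSet
) -> list[int | None]:
    """Per cycle, the stance sample where the body shank crosses vertical.

    Looks for the first sign change of theta in [IC, TO] and returns the
    nearer of the two straddling samples (no interpolation; sample-level
    precision is adequate at 50 Hz). Cycles without a crossing — or without
    IC/TO — yield None and are excluded by the callers.
    """
    theta = np.asarray(theta_body_shank, dtype=float)
    out: list[int | None] = []
    for c in cycles.cycles:
        if c.flagged or c.ic is None or c.to is None:
            out.append(None)
            continue
        seg = theta[c.ic : c.to + 1]
        sign_change = np.nonzero(np.diff(np.signbit(seg)))[0]
        if sign_change.size == 0:
            out.append(None)
            continue
        i = int(sign_change[0])
        pick = i if abs(seg[i]) <= abs(seg[i + 1]) else i + 1
        out.append(c.ic + pick)
    return out


def assemble_phase_portrait(sva: SvaSeries, cycle, cycle_length: int) -> PhasePortrait:
    """(theta, omega) trajectory of one cycle with MS/IC/TO markers.

    Marker indices are relative to the cycle window. The theta and omega
    ranges are exposed so the wider-range behaviour of clothing-mounted
    sensors is directly assertable.
    """
    sl = slice(cycle.start, cycle.start + cycle_length)
    rel = lambda i: None if i is None else i - cycle.start  # noqa: E731
    return PhasePortrait(
        theta=sva.theta[sl],
        omega=sva.omega[sl],
        markers={"ms": 0, "ic": rel(cycle.ic), "to": rel(cycle.to)},
    )
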