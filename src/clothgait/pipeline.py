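"""End-to-end pipeline: align, filter, orient, segment, compare, report.

``run_pipeline`` executes the full analysis on one session and returns an
in-memory results bundle; ``write_results`` serializes the bundle as plain
CSV tables (plus an optional set of figures) and a formatted text report
with one row per placement: mean per-cycle correlation and the three
clothing-minus-body angle differences (standing, initial contact,
shank-vertical), each as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import (
    PairComparison,
    angle_difference_at,
    assemble_phase_portrait,
    find_shank_vertical,
    per_cycle_correlation,
)
from .conditioning import AlignmentRotations, align_and_filter
from .config import ATTACHMENTS, PLACEMENTS, PipelineConfig, logger
from .errors import CannotSegmentError, ConfigurationError, EmptyResultError
from .orientation import SvaSeries, compute_sva
from .segmentation import (
    GaitCycleSet,
    detect_ic_to,
    detect_midswing,
    propagate_segmentation,
    segment_cycles,
    stance_fraction,
)
from .session import ImuTimeSeries, SensorSession

__all__ = ["PipelineResult", "run_pipeline", "write_results", "format_report"]


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one session."""

    config: PipelineConfig
    sva: dict[tuple[str, str, str], SvaSeries]
    alignments: dict[tuple[str, str, str], AlignmentRotations]
    cycle_sets: dict[str, GaitCycleSet]  # keyed by attachment
    comparisons: dict[str, PairComparison | None]  # keyed by placement
    stance_per_cycle: np.ndarray
    stance_mean: float
    mean_cycles: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    counts: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _pooled_dynamic(session: SensorSession, key) -> ImuTimeSeries | None:
    """Concatenate all labelled dynamic segments of one sensor.

    The pooled stream gets a synthetic uniform time base; only its sample
    statistics matter (principal horizontal direction), not its clock.
    """
    s = session.sensors[key]
    parts = []
    for label in ("sit_to_stand", "leg_raise", "walking"):
        for lo, hi in session.segments(label):
            parts.append((s.accel[lo:hi], s.gyro[lo:hi]))
    if not parts:
        return None
    accel = np.vstack([p[0] for p in parts])
    gyro = np.vstack([p[1] for p in parts])
    dt = 1.0 / s.sample_rate
    return s.replace(time=np.arange(len(accel)) * dt, accel=accel, gyro=gyro)


def _walking_slice(session: SensorSession, key) -> ImuTimeSeries | None:
    segs = session.segments("walking")
    if not segs:
        return None
    lo, hi = segs[0]
    s = session.sensors[key]
    sl = s.slice(lo, hi)
    return sl.replace(time=sl.time - sl.time[0])


def run_pipeline(session: SensorSession, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a session.

    Stages, in order: per-sensor alignment (gravity rotation from standing,
    sagittal rotation from pooled dynamic segments with the sign anchored on
    walking), zero-phase low-pass filtering, Madgwick orientation and SVA,
    mid-swing/IC/TO gait-cycle extraction from each lower-shank stream, and
    clothing-vs-body comparison per placement using the body-derived cycle
    set. Placements missing either sensor of the pair are reported as absent
    rather than raising.
    """
    config = config or PipelineConfig()
    if not session.segments("standing"):
        raise ConfigurationError("session has no standing segment: cannot align")
    if not session.segments("walking"):
        raise ConfigurationError("session has no walking segment: nothing to segment")
    stand_lo, stand_hi = session.segments("standing")[0]
    trim = int(config.segment_edge_trim_s * config.sample_rate_hz)
    trim = min(trim, (stand_hi - stand_lo) // 4)
    cal_lo, cal_hi = stand_lo + trim, stand_hi - trim

    aligned: dict[tuple[str, str, str], ImuTimeSeries] = {}
    alignments: dict[tuple[str, str, str], AlignmentRotations] = {}
    sva: dict[tuple[str, str, str], SvaSeries] = {}
    for key, s in session.sensors.items():
        standing = s.slice(cal_lo, cal_hi)
        standing = standing.replace(time=standing.time - standing.time[0])
        dynamic = _pooled_dynamic(session, key)
        if dynamic is None:
            raise ConfigurationError(f"sensor {key}: no dynamic segments to align with")
        filt, rots = align_and_filter(
            s, standing, dynamic, config, sign_reference=_walking_slice(session, key)
        )
        aligned[key] = filt
        alignments[key] = rots
        sva[key] = compute_sva(
            filt,
            beta=config.madgwick_beta,
            accel_gate_g=config.madgwick_accel_gate_g,
            rate_gate_dps=config.madgwick_rate_gate_dps,
        )
        logger.info("pipeline: aligned and oriented %s/%s", key[0], key[1])

    # --- gait-cycle extraction per attachment from the lower-shank streams
    walking_segments = session.segments("walking")
    cycle_sets: dict[str, GaitCycleSet] = {}
    for attachment in ATTACHMENTS:
        key = ("lower_shank", attachment, "right")
        if key not in aligned:
            continue
        mag = aligned[key].accel_magnitude()
        raw_gyro = session.sensors[key].gyro @ alignments[key].composed.T
        raw_omega = -raw_gyro[:, 1]  # sagittal rate, maximal at mid-swing
        ms_all = []
        for lo, hi in walking_segments:
            ms = detect_midswing(
                mag[lo:hi],
                threshold_g=config.ms_threshold(attachment),
                min_separation_s=config.min_separation_s,
                sample_rate=config.sample_rate_hz,
                refine_mag=raw_omega[lo:hi],
            )
            ms_all.extend((ms + lo).tolist())
        try:
            cset = segment_cycles(
                np.asarray(ms_all, dtype=int),
                series_length=len(mag),
                sample_rate=config.sample_rate_hz,
                source_attachment=attachment,
            )
        except CannotSegmentError:
            logger.warning("pipeline: %s shank stream yields <2 MS points", attachment)
            continue
        raw_aligned = session.sensors[key].gyro @ alignments[key].composed.T
        detect_ic_to(
            sva[key].omega,
            cset,
            prominence_dps=config.ic_to_prominence_dps,
            refine_omega=-raw_aligned[:, 1],
        )
        cycle_sets[attachment] = cset
        logger.info(
            "pipeline: %s cycles detected=%d flagged=%d length=%d",
            attachment,
            len(cset.cycles),
            cset.n_flagged,
            cset.cycle_length,
        )

    # --- pair comparison with the body-derived segmentation
    ref_attachment = "body" if "body" in cycle_sets else next(iter(cycle_sets), None)
    comparisons: dict[str, PairComparison | None] = {}
    mean_cycles: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    stance_arr, stance_avg = np.array([]), float("nan")
    if ref_attachment is None:
        logger.warning("pipeline: no cycle set available; skipping comparisons")
        comparisons = {p: None for p in PLACEMENTS}
    else:
        cset = cycle_sets[ref_attachment]
        try:
            stance_arr, stance_avg = stance_fraction(cset)
        except EmptyResultError:
            logger.warning("pipeline: no valid cycles for stance fraction")
        shank_body_key = ("lower_shank", "body", "right")
        vertical = None
        if shank_body_key in sva:
            vertical = find_shank_vertical(sva[shank_body_key].theta, cset)
        standing_stop = min(
            cal_hi, cal_lo + int(config.standing_window_s * config.sample_rate_hz)
        )
        for placement in PLACEMENTS:
            kb = (placement, "body", "right")
            kc = (placement, "clothing", "right")
            for k in (kb, kc):
                if k in sva:
                    try:
                        _, m, sd = propagate_segmentation(cset, sva[k].theta)
                        mean_cycles[(placement, k[1])] = (m, sd)
                    except EmptyResultError:
                        pass
            if kb not in sva or kc not in sva:
                comparisons[placement] = None
                logger.info("pipeline: %s pair absent, comparison skipped", placement)
                continue
            mat_b, _, _ = propagate_segmentation(cset, sva[kb].theta)
            mat_c, _, _ = propagate_segmentation(cset, sva[kc].theta)
            r, r_mean, shapiro_p, n_exc = per_cycle_correlation(mat_b, mat_c)
            d_stand = angle_difference_at(
                sva[kb], sva[kc], "standing", standing_range=(cal_lo, standing_stop)
            )
            d_ic = angle_difference_at(sva[kb], sva[kc], "ic", cycles=cset)
            if vertical is not None:
                d_sv = angle_difference_at(
                    sva[kb], sva[kc], "shank_vertical", vertical_indices=vertical
                )
            else:
                d_sv = (float("nan"), float("nan"))
            comparisons[placement] = PairComparison(
                placement=placement,
                r_per_cycle=r,
                r_mean=r_mean,
                diff_standing=d_stand,
                diff_ic=d_ic,
                diff_shank_vertical=d_sv,
                n_cycles=len(r),
                shapiro_p=shapiro_p,
                n_excluded=n_exc,
            )

    counts = {
        "sensors": len(session.sensors),
        "cycles_detected": sum(len(c.cycles) for c in cycle_sets.values()),
        "cycles_flagged": sum(c.n_flagged for c in cycle_sets.values()),
        "pairs_compared": sum(v is not None for v in comparisons.values()),
    }
    logger.info("pipeline: done %s", counts)
    return PipelineResult(
        config=config,
        sva=sva,
        alignments=alignments,
        cycle_sets=cycle_sets,
        comparisons=comparisons,
        stance_per_cycle=stance_arr,
        stance_mean=stance_avg,
        mean_cycles=mean_cycles,
        counts=counts,
        metadata=dict(session.metadata),
    )


# ---------------------------------------------------------------------------
# Serialization


def _fmt_pm(pair: tuple[float, float]) -> str:
    m, s = pair
    return f"{m:+7.2f} ± {s:5.2f}"


def format_report(result: PipelineResult) -> str:
    """Render the per-placement agreement table as fixed-width text."""
    lines = [
        "Clothing-mounted vs body-mounted sensor agreement",
        f"subject: {result.metadata.get('subject', '?')}    "
        f"clothing: {result.metadata.get('clothing_type', '?')}",
        f"stance fraction (body cycles): {result.stance_mean:.3f}"
        if np.isfinite(result.stance_mean)
        else "stance fraction: n/a",
        "",
        f"{'placement':<13}{'n_cycles':>9}{'corr.coef':>11}"
        f"{'standing (deg)':>18}{'walking IC (deg)':>18}{'shank-vert (deg)':>18}",
    ]
    for placement in PLACEMENTS:
        comp = result.comparisons.get(placement)
        if comp is None:
            lines.append(f"{placement:<13}{'-':>9}{'-':>11}{'-':>18}{'-':>18}{'-':>18}")
            continue
        lines.append(
            f"{placement:<13}{comp.n_cycles:>9d}{comp.r_mean:>11.3f}"
            f"{_fmt_pm(comp.diff_standing):>18}{_fmt_pm(comp.diff_ic):>18}"
            f"{_fmt_pm(comp.diff_shank_vertical):>18}"
        )
    return "\n".join(lines) + "\n"


def write_results(result: PipelineResult, outdir, plots: bool = False) -> None:
    """Write the results bundle to a directory of CSV tables (+ report.txt).

    Always emitted: the comparison table, per-cycle correlations, cycle
    tables per attachment, mean-cycle bands, a representative phase portrait
    per sensor, stance fractions, SVA tracks and the composed alignment
    rotations. Figures are rendered only on request so headless runs stay
    deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dt = 1.0 / result.config.sample_rate_hz

    rows = []
    for placement in PLACEMENTS:
        comp = result.comparisons.get(placement)
        if comp is None:
            rows.append({"placement": placement, "available": False})
            continue
        rows.append(
            {
                "placement": placement,
                "available": True,
                "n_cycles": comp.n_cycles,
                "r_mean": comp.r_mean,
                "shapiro_p": comp.shapiro_p,
                "diff_standing_mean": comp.diff_standing[0],
                "diff_standing_sd": comp.diff_standing[1],
                "diff_ic_mean": comp.diff_ic[0],
                "diff_ic_sd": comp.diff_ic[1],
                "diff_shank_vertical_mean": comp.diff_shank_vertical[0],
                "diff_shank_vertical_sd": comp.diff_shank_vertical[1],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "comparison.csv", index=False, float_format="%.6f")

    rrows = []
    for placement, comp in result.comparisons.items():
        if comp is None:
            continue
        for i, r in enumerate(comp.r_per_cycle):
            rrows.append({"placement": placement, "cycle": i, "r": r})
    pd.DataFrame(rrows, columns=["placement", "cycle", "r"]).to_csv(
        outdir / "r_per_cycle.csv", index=False, float_format="%.6f"
    )

    for attachment, cset in result.cycle_sets.items():
        pd.DataFrame(
            [
                {
                    "cycle_index": i,
                    "start_time": c.start * dt,
                    "ic_time": c.ic * dt if c.ic is not None else np.nan,
                    "to_time": c.to * dt if c.to is not None else np.nan,
                    "flagged": c.flagged,
                }
                for i, c in enumerate(cset.cycles)
            ]
        ).to_csv(outdir / f"cycles_{attachment}.csv", index=False, float_format="%.6f")

    mrows = []
    for (placement, attachment), (m, sd) in sorted(result.mean_cycles.items()):
        for i, (mi, si) in enumerate(zip(m, sd)):
            mrows.append(
                {
                    "placement": placement,
                    "attachment": attachment,
                    "sample": i,
                    "theta_mean": mi,
                    "theta_sd": si,
                }
            )
    pd.DataFrame(
        mrows, columns=["placement", "attachment", "sample", "theta_mean", "theta_sd"]
    ).to_csv(outdir / "mean_cycles.csv", index=False, float_format="%.6f")

    if np.size(result.stance_per_cycle):
        pd.DataFrame(
            {
                "cycle": np.arange(len(result.stance_per_cycle)),
                "stance_fraction": result.stance_per_cycle,
            }
        ).to_csv(outdir / "stance.csv", index=False, float_format="%.6f")

    for key, s in sorted(result.sva.items()):
        pd.DataFrame(
            {
                "time_s": s.time,
                "theta_deg": s.theta,
                "theta_z_deg": s.theta_z,
                "omega_deg_s": s.omega,
                "placement": s.placement,
                "attachment": s.attachment,
            }
        ).to_csv(
            outdir / f"sva_{key[0]}_{key[1]}.csv", index=False, float_format="%.6f"
        )

    arows = []
    for (placement, attachment, _side), rot in sorted(result.alignments.items()):
        arows.append([placement, attachment] + list(rot.composed.ravel()))
    pd.DataFrame(
        arows,
        columns=["placement", "attachment"]
        + [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)],
    ).to_csv(outdir / "alignment.csv", index=False, float_format="%.9f")

    prows = []
    ref = "body" if "body" in result.cycle_sets else next(iter(result.cycle_sets), None)
    if ref is not None:
        cset = result.cycle_sets[ref]
        valid = cset.valid_cycles
        if valid:
            cyc = valid[len(valid) // 2]
            for key, s in sorted(result.sva.items()):
                pp = assemble_phase_portrait(s, cyc, cset.cycle_length)
                for i, (th, om) in enumerate(zip(pp.theta, pp.omega)):
                    prows.append(
                        {
                            "placement": key[0],
                            "attachment": key[1],
                            "sample": i,
                            "theta_deg": th,
                            "omega_deg_s": om,
                        }
                    )
    pd.DataFrame(
        prows, columns=["placement", "attachment", "sample", "theta_deg", "omega_deg_s"]
    ).to_csv(outdir / "phase_portrait.csv", index=False, float_format="%.6f")

    result.config.to_yaml(outdir / "config.yaml")
    (outdir / "report.txt").write_text(format_report(result))
    if plots:
        render_plots(result, outdir)


def render_plots(result: PipelineResult, outdir) -> None:
    """Render the four standard figures as PNGs (mean cycles, 3-D angle
    trajectories, phase portraits, correlation box plots)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    colors = {"body": "tab:red", "clothing": "tab:blue"}

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
    for ax, placement in zip(axes, PLACEMENTS):
        for attachment in ATTACHMENTS:
            mc = result.mean_cycles.get((placement, attachment))
            if mc is None:
                continue
            m, sd = mc
            x = np.arange(len(m))
            ax.plot(x, m, color=colors[attachment], label=attachment)
            ax.fill_between(x, m - sd, m + sd, color=colors[attachment], alpha=0.25)
        ax.set_title(placement)
        ax.set_xlabel("sample in cycle")
    axes[0].set_ylabel("SVA (deg)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(outdir / "mean_cycles.png", dpi=120)
    plt.close(fig)

    ref = "body" if "body" in result.cycle_sets else next(iter(result.cycle_sets), None)
    if ref is not None and result.cycle_sets[ref].valid_cycles:
        cset = result.cycle_sets[ref]

        def theta_of(placement, attachment):
            s = result.sva.get((placement, attachment, "right"))
            if s is None:
                return None
            mat, _, _ = propagate_segmentation(cset, s.theta)
            return mat

        fig = plt.figure(figsize=(5, 4.5))
        ax = fig.add_subplot(projection="3d")
        for attachment in ATTACHMENTS:
            mats = [theta_of(p, attachment) for p in PLACEMENTS]
            if any(m is None for m in mats):
                continue
            ax.plot(
                mats[0].ravel(), mats[1].ravel(), mats[2].ravel(),
                ".", ms=1, color=colors[attachment], label=attachment,
            )
        ax.set_xlabel("waist (deg)")
        ax.set_ylabel("thigh (deg)")
        ax.set_zlabel("shank (deg)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "angles_3d.png", dpi=120)
        plt.close(fig)

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        cyc = cset.valid_cycles[len(cset.valid_cycles) // 2]
        for ax, placement in zip(axes, PLACEMENTS):
            for attachment in ATTACHMENTS:
                s = result.sva.get((placement, attachment, "right"))
                if s is None:
                    continue
                pp = assemble_phase_portrait(s, cyc, cset.cycle_length)
                ax.plot(pp.theta, pp.omega, color=colors[attachment], label=attachment)
                for name, marker in (("ms", "r*"), ("ic", "gd"), ("to", "bo")):
                    i = pp.markers[name]
                    if i is not None:
                        ax.plot(pp.theta[i], pp.omega[i], marker, ms=6)
            ax.set_title(placement)
            ax.set_xlabel("SVA (deg)")
        axes[0].set_ylabel("omega (deg/s)")
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(outdir / "phase_portraits.png", dpi=120)
        plt.close(fig)

    data = [
        result.comparisons[p].r_per_cycle
        for p in PLACEMENTS
        if result.comparisons.get(p) is not None
    ]
    labels = [p for p in PLACEMENTS if result.comparisons.get(p) is not None]
    if data:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("per-cycle Pearson r")
        fig.tight_layout()
        fig.savefig(outdir / "correlations_box.png", dpi=120)
        plt.close(fig)
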