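"""Shared constants, pipeline configuration and logging.

The defaults mirror the hardware and processing choices of the study setup the
package emulates: 50 Hz sampling, a zero-phase second-order Butterworth
low-pass at 3 Hz, mid-swing acceleration-magnitude thresholds of 1.8 g
(body-mounted) and 2.0 g (clothing-mounted) with a 1 s minimum peak
separation, and a Madgwick filter gain of 0.1.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import yaml

from .errors import ConfigurationError

#: Anatomical placements along the lower body, proximal to distal.
PLACEMENTS = ("waist", "thigh", "lower_shank")
#: Sensor attachment: taped to the skin or mounted in the trouser fabric.
ATTACHMENTS = ("body", "clothing")
SIDES = ("left", "right")
#: Activity labels of the recording protocol.
ACTIVITIES = ("standing", "sitting", "sit_to_stand", "leg_raise", "walking")

#: Standard gravity, m/s^2; accelerometer channels are expressed in g.
GRAVITY_MS2 = 9.80665

logger = logging.getLogger("clothgait")


def configure_logging(verbosity: int = 0) -> None:
    """Route stage-tagged log lines to stderr.

    verbosity 0 -> WARNING, 1 -> INFO, >=2 -> DEBUG.
    """
    level = logging.WARNING - 10 * min(int(verbosity), 2)
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis pipeline.

    All rates are in Hz, thresholds on acceleration magnitude in g, angular
    quantities in degrees or deg/s.
    """

    sample_rate_hz: float = 50.0
    filter_cutoff_hz: float = 3.0
    filter_order: int = 2
    #: Mid-swing peak thresholds on acceleration magnitude.
    ms_threshold_body_g: float = 1.8
    ms_threshold_clothing_g: float = 2.0
    #: Minimum separation between retained mid-swing peaks.
    min_separation_s: float = 1.0
    #: Madgwick gradient-descent gain (rad/s of corrective slew).
    madgwick_beta: float = 0.1
    #: Quasi-static gate on the Madgwick accelerometer correction: the
    #: correction runs only on samples with | ||a|| - 1 g | below this band
    #: and angular speed below the rate gate; others are gyro-only.
    madgwick_accel_gate_g: float = 0.1
    madgwick_rate_gate_dps: float = 60.0
    #: Minimum prominence of gyroscope minima accepted as IC/TO, deg/s.
    ic_to_prominence_dps: float = 30.0
    #: Quasi-static band on mean acceleration magnitude for standing data.
    quasi_static_low_g: float = 0.8
    quasi_static_high_g: float = 1.2
    #: Minimum horizontal acceleration variance (g^2) for sagittal alignment.
    min_horizontal_var_g2: float = 1e-4
    #: Minimum medial-lateral gyroscope excursion (deg/s) for sign resolution.
    gyro_sign_min_excursion_dps: float = 10.0
    #: Window of standing data used for the standing angle difference, s.
    standing_window_s: float = 120.0
    #: Guard band trimmed off each end of the standing segment before static
    #: calibration, so activity-transition motion cannot contaminate the
    #: gravity and gyro-bias estimates (capped at 25% of the segment).
    segment_edge_trim_s: float = 2.0
    #: Optional per-cycle correlation-to-mean outlier screen (off by default).
    cycle_outlier_screen: bool = False
    cycle_outlier_min_r: float = 0.0
    #: Root seed for any stochastic stage (the pipeline itself is deterministic).
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.filter_cutoff_hz <= 0:
            raise ConfigurationError("sample rate and filter cutoff must be positive")
        if self.filter_cutoff_hz >= self.sample_rate_hz / 2:
            raise ConfigurationError(
                f"filter cutoff {self.filter_cutoff_hz} Hz must lie below the "
                f"Nyquist frequency {self.sample_rate_hz / 2} Hz"
            )
        if self.filter_order < 1:
            raise ConfigurationError("filter order must be >= 1")
        for name in (
            "ms_threshold_body_g",
            "ms_threshold_clothing_g",
            "min_separation_s",
            "ic_to_prominence_dps",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.madgwick_beta < 0:
            raise ConfigurationError("madgwick_beta must be non-negative")
        if not 0 < self.quasi_static_low_g < 1 < self.quasi_static_high_g:
            raise ConfigurationError("quasi-static band must bracket 1 g")

    def ms_threshold(self, attachment: str) -> float:
        """Mid-swing threshold for a given attachment."""
        if attachment == "body":
            return self.ms_threshold_body_g
        if attachment == "clothing":
            return self.ms_threshold_clothing_g
        raise ConfigurationError(f"unknown attachment {attachment!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
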