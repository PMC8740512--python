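"""Core domain types shared across the pipeline.

Signals are plain 1-D float arrays with an attached sampling rate, axis label
and unit; trials bundle the paired force/acceleration traces with the static
per-trial descriptors that later become model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

G = 9.81
"""Gravitational acceleration [m/s^2] used for bodyweight normalization."""

#: Signed-slope range [degrees] covered by the training envelope.
SLOPE_ENVELOPE = (-10.0, 10.0)

AXES = ("grf_normal_BW", "acc_vertical", "acc_anteroposterior")
STEP_FREQ_CONDITIONS = ("preferred", "+10%", "-10%")


@dataclass
class SignalTrace:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : ndarray
        Finite sample values.
    rate : float
        Sampling rate in Hz, > 0.
    axis : str
        One of ``grf_normal_BW``, ``acc_vertical``, ``acc_anteroposterior``.
    units : str
        ``BW``, ``N`` or ``m/s2``.
    """

    samples: np.ndarray
    rate: float
    axis: str
    units: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if len(self.samples) < 1:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / rate)."""
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    def with_samples(self, samples: np.ndarray, rate: Optional[float] = None,
                     units: Optional[str] = None) -> "SignalTrace":
        return SignalTrace(
            samples=np.asarray(samples, dtype=float),
            rate=self.rate if rate is None else rate,
            axis=self.axis,
            units=self.units if units is None else units,
        )


@dataclass
class TrialMeta:
    """Static per-trial descriptors.

    ``slope`` is signed in degrees (+ = uphill); foot-strike percentages must
    sum to 100.
    """

    subject_id: str
    mass: float          # kg
    height: float        # cm
    speed: float         # m/s
    slope: float         # degrees
    fs_rear: float       # % of steps
    fs_mid: float
    fs_fore: float
    step_freq_condition: str = "preferred"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        total = self.fs_rear + self.fs_mid + self.fs_fore
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"foot-strike percentages sum to {total}, expected 100")
        lo, hi = SLOPE_ENVELOPE
        if not (lo <= self.slope <= hi):
            raise ValueError(
                f"slope {self.slope} deg outside training envelope [{lo}, {hi}]")
        if self.step_freq_condition not in STEP_FREQ_CONDITIONS:
            raise ValueError(
                f"unknown step_freq_condition {self.step_freq_condition!r}")

    @property
    def slope_rad(self) -> float:
        return float(np.deg2rad(self.slope))


@dataclass
class GroundTruthKinetics:
    """Per-step ground truth recorded by the simulator.

    ``contact_s`` is the operational contact time — the analytic duration the
    half-sine exceeds the 5% BW stance threshold — while ``halfsine_s`` is the
    full half-sine support. ``impulse_BWs`` is the closed-form step impulse
    (half-sine plus Gaussian impact bump).
    """

    onset_s: np.ndarray
    contact_s: np.ndarray
    halfsine_s: np.ndarray
    active_BW: np.ndarray
    impact_BW: np.ndarray
    impact_frac: np.ndarray
    impulse_BWs: np.ndarray
    step_freq_hz: float

    def __post_init__(self) -> None:
        for name in ("onset_s", "contact_s", "halfsine_s", "active_BW",
                     "impact_BW", "impact_frac", "impulse_BWs"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.contact_s <= 0):
            raise ValueError("contact durations must be positive")
        if np.any(self.active_BW < 0) or np.any(self.impact_BW < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_steps(self) -> int:
        return len(self.onset_s)


@dataclass
class GaitTrial:
    """Paired GRF + biaxial sacral acceleration with per-trial metadata."""

    meta: TrialMeta
    acc_v: SignalTrace
    acc_ap: SignalTrace
    grf: Optional[SignalTrace] = None
    truth: Optional[GroundTruthKinetics] = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.acc_v.rate != self.acc_ap.rate:
            raise ValueError("acceleration channels must share a sampling rate")
        if len(self.acc_v) != len(self.acc_ap):
            raise ValueError("acceleration channels must share a length")
        if self.grf is not None:
            if self.grf.rate != self.acc_v.rate:
                raise ValueError("GRF and acceleration must share a sampling rate")
            if len(self.grf) != len(self.acc_v):
                raise ValueError("GRF and acceleration must share a length")

    @property
    def rate(self) -> float:
        return self.acc_v.rate

    @property
    def n_frames(self) -> int:
        return len(self.acc_v)

    def replace(self, **kwargs) -> "GaitTrial":
        return replace(self, **kwargs)
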