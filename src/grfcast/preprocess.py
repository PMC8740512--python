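"""Raw-signal conditioning: downsampling, filtering, clipping, windowing.

The model-ready representation is 500 Hz, bodyweight-normalized GRF filtered
at 30 Hz, acceleration filtered at 20 Hz with negatives clipped, and the
acceleration split into overlapping 6-frame (12 ms) windows, one per GRF
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import G, GaitTrial, SignalTrace

__all__ = [
    "FilterSpec",
    "WindowedAcceleration",
    "PrepConfig",
    "downsample",
    "lowpass",
    "normalize_bw",
    "clip_negative",
    "make_windows",
    "preprocess_trial",
]

LEAD_PAD = 3
TRAIL_PAD = 2


@dataclass(frozen=True)
class FilterSpec:
    """4th-order low-pass Butterworth, applied zero-phase (forward-backward).

    Zero-phase filtering doubles the effective attenuation of the one-pass
    design; the stated order/cutoff refer to the one-pass prototype.
    """

    cutoff_hz: float
    order: int = 4
    family: str = "butterworth_lowpass"
    phase: str = "zero"

    def validate(self, rate: float) -> None:
        if not (0 < self.cutoff_hz < rate / 2):
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={rate / 2} Hz)")


@dataclass
class WindowedAcceleration:
    """T overlapping windows x width frames x 2 axes (vertical, AP).

    Window t spans source frames t-3 ... t+2; edge windows are filled by
    repeating the first (3 copies) and last (2 copies) values so the window
    count equals the GRF frame count.
    """

    windows: np.ndarray  # (T, width, 2)
    rate: float
    lead_pad: int = LEAD_PAD
    trail_pad: int = TRAIL_PAD

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[2] != 2:
            raise ValueError("windows must have shape (T, width, 2)")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def width(self) -> int:
        return self.windows.shape[1]


def downsample(trace: SignalTrace, target_rate: float) -> SignalTrace:
    """Anti-alias filtered polyphase decimation to ``target_rate``.

    The source rate must be an integer multiple of the target rate; output
    length is ceil(n * target / source).
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    ratio = trace.rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"source rate {trace.rate} Hz is not an integer multiple of "
            f"target rate {target_rate} Hz")
    if q == 1:
        return trace.with_samples(trace.samples.copy())
    # padtype="line" keeps DC gain exactly 1 and is edge-exact for trends
    out = sps.resample_poly(trace.samples, up=1, down=q, padtype="line")
    return trace.with_samples(out, rate=target_rate)


def lowpass(trace: SignalTrace, spec: FilterSpec) -> SignalTrace:
    """Zero-phase Butterworth low-pass; same length and rate, unit DC gain."""
    spec.validate(trace.rate)
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low",
                     fs=trace.rate, output="sos")
    out = sps.sosfiltfilt(sos, trace.samples)
    return trace.with_samples(out)


def butterworth_gain(spec: FilterSpec, rate: float, freq_hz: float) -> float:
    """Analytic magnitude response of the zero-phase filter at ``freq_hz``.

    Independent oracle for :func:`lowpass`: |H(f)|^2 of the one-pass design
    (forward-backward squares the magnitude).
    """
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate,
                     output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=rate)
    return float(np.abs(h[0]) ** 2)


def normalize_bw(grf: SignalTrace, mass: float) -> SignalTrace:
    """Convert a GRF trace from Newtons to bodyweights (mass * g)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if grf.units == "BW":
        return grf.with_samples(grf.samples.copy())
    return grf.with_samples(grf.samples / (mass * G), units="BW")


def clip_negative(trace: SignalTrace) -> SignalTrace:
    """Replace negative samples with zeros (vertical acceleration channel)."""
    return trace.with_samples(np.maximum(trace.samples, 0.0))


def make_windows(acc_v: SignalTrace, acc_ap: SignalTrace,
                 width: int = 6) -> WindowedAcceleration:
    """Overlapping ``width``-frame windows, one per frame.

    Padding is asymmetric (3 lead, 2 trail copies of the edge values) so that
    window t covers frames t-3 ... t+2 and the window count equals the input
    length for any trial length >= 1.
    """
    if len(acc_v) != len(acc_ap):
        raise ValueError("acceleration channels must share a length")
    if acc_v.rate != acc_ap.rate:
        raise ValueError("acceleration channels must share a rate")
    if width != LEAD_PAD + TRAIL_PAD + 1:
        raise ValueError("only the 6-frame (t-3..t+2) window layout is supported")
    cols = []
    for tr in (acc_v, acc_ap):
        padded = np.concatenate([
            np.full(LEAD_PAD, tr.samples[0]),
            tr.samples,
            np.full(TRAIL_PAD, tr.samples[-1]),
        ])
        cols.append(np.lib.stride_tricks.sliding_window_view(padded, width))
    windows = np.stack(cols, axis=-1)  # (T, width, 2)
    return WindowedAcceleration(windows.copy(), rate=acc_v.rate)


@dataclass
class PrepConfig:
    """Preprocessing parameters; defaults follow the published pipeline."""

    rate_hz: float = 500.0
    grf_filter: FilterSpec = field(default_factory=lambda: FilterSpec(30.0))
    acc_filter: FilterSpec = field(default_factory=lambda: FilterSpec(20.0))
    window_frames: int = 6


def preprocess_trial(trial: GaitTrial, cfg: Optional[PrepConfig] = None
                     ) -> tuple[GaitTrial, WindowedAcceleration]:
    """Full conditioning chain for one trial.

    Downsample all channels to ``cfg.rate_hz``; BW-normalize and 30 Hz-filter
    the GRF; 20 Hz-filter both acceleration channels and clip negative
    vertical acceleration; build the per-frame windows. Returns the
    preprocessed trial and its windowed acceleration.
    """
    cfg = cfg or PrepConfig()
    acc_v = lowpass(downsample(trial.acc_v, cfg.rate_hz), cfg.acc_filter)
    acc_v = clip_negative(acc_v)
    acc_ap = lowpass(downsample(trial.acc_ap, cfg.rate_hz), cfg.acc_filter)
    grf = None
    if trial.grf is not None:
        grf = downsample(trial.grf, cfg.rate_hz)
        grf = normalize_bw(grf, trial.meta.mass)
        grf = lowpass(grf, cfg.grf_filter)
    prepped = trial.replace(acc_v=acc_v, acc_ap=acc_ap, grf=grf)
    return prepped, make_windows(acc_v, acc_ap, cfg.window_frames)
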