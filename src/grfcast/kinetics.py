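"""Stance segmentation, discrete biomechanical variables, boundary checks.

Stance is the region where the normal GRF exceeds 5% BW. From each contact we
compute the active peak (max within 40-60% of stance), impulse (trapezoidal
integral), loading rate (secant slope over the first 25 ms) and contact time;
step frequency is contacts per second over the whole trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import SignalTrace

__all__ = [
    "StanceSegmentation",
    "StepKinetics",
    "BoundaryVerdict",
    "segment_stance",
    "discrete_variables",
    "check_boundaries",
]

THRESHOLD_BW = 0.05
MIN_CONTACT_S = 0.025   # debounce: drop shorter contacts
MIN_GAP_S = 0.010       # debounce: merge shorter aerial gaps
LOADING_RATE_WINDOW_S = 0.025
ACTIVE_PEAK_WINDOW = (0.40, 0.60)
MAX_STEP_FREQ_HZ = 4.0
VARIABLE_NAMES = ("step_frequency", "contact_time", "impulse",
                  "active_peak", "loading_rate")


@dataclass
class StanceSegmentation:
    """Ordered, disjoint half-open frame intervals [start, end) of contacts."""

    intervals: list[tuple[int, int]]
    threshold: float
    rate: float

    n_frames: int = 0  # trace length; 0 = unknown (treat all contacts complete)

    @property
    def n_contacts(self) -> int:
        return len(self.intervals)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([s for s, _ in self.intervals], dtype=int)

    def complete_intervals(self) -> list[tuple[int, int]]:
        """Contacts whose full stance lies inside the trace.

        A contact touching either trace boundary is truncated by the analysis
        window: its onset or toe-off was not observed, so its duration,
        impulse and peak are undefined.
        """
        if not self.n_frames:
            return list(self.intervals)
        return [(s, e) for s, e in self.intervals
                if s > 0 and e < self.n_frames]

    def onset_count(self, edge_buffer_s: float = 0.0) -> int:
        """Number of observed contact onsets (upward threshold crossings).

        An interval starting at frame 0 was already in stance when the window
        opened, so its onset was not observed. ``edge_buffer_s`` additionally
        ignores onsets within a margin of either window edge, making counts
        robust to frame-level onset-timing differences near the boundaries.
        """
        buf = max(1, int(round(edge_buffer_s * self.rate)))
        hi = (self.n_frames - buf) if self.n_frames else np.inf
        return sum(1 for s, _ in self.intervals if buf <= s < hi)


@dataclass
class StepKinetics:
    """Per-contact discrete variables plus trial-level step frequency.

    ``loading_rate`` is NaN for contacts shorter than 25 ms (flagged in
    ``loading_rate_valid`` and excluded from aggregates).
    """

    active_peak: np.ndarray     # BW
    impulse: np.ndarray         # BW*s
    loading_rate: np.ndarray    # BW/s
    contact_time: np.ndarray    # ms
    loading_rate_valid: np.ndarray
    step_frequency: float       # Hz

    @property
    def n_contacts(self) -> int:
        return len(self.contact_time)

    def aggregate(self) -> dict[str, float]:
        """Trial-level variable means (flagged loading rates excluded)."""
        lr = self.loading_rate[self.loading_rate_valid]
        return {
            "step_frequency": float(self.step_frequency),
            "contact_time": float(np.mean(self.contact_time)) if self.n_contacts else np.nan,
            "impulse": float(np.mean(self.impulse)) if self.n_contacts else np.nan,
            "active_peak": float(np.mean(self.active_peak)) if self.n_contacts else np.nan,
            "loading_rate": float(np.mean(lr)) if len(lr) else np.nan,
        }


@dataclass
class BoundaryVerdict:
    contact_count_ok: bool
    step_freq_ok: bool
    diagnostics: str = ""

    @property
    def passed(self) -> bool:
        return self.contact_count_ok and self.step_freq_ok


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment_stance(grf: SignalTrace, threshold: float = THRESHOLD_BW,
                   min_contact_s: Optional[float] = MIN_CONTACT_S,
                   min_gap_s: Optional[float] = MIN_GAP_S) -> StanceSegmentation:
    """Threshold-crossing stance segmentation with optional debounce.

    Raw thresholding chatters on noisy predictions, so aerial gaps shorter
    than ``min_gap_s`` are merged and contacts shorter than ``min_contact_s``
    dropped. Pass ``None`` (or 0) for either to disable. Zero contacts is a
    valid result.
    """
    if grf.units != "BW":
        raise ValueError("stance segmentation expects a GRF trace in BW")
    intervals = _runs(grf.samples > threshold)
    if min_gap_s and len(intervals) > 1:
        merged = [intervals[0]]
        min_gap = min_gap_s * grf.rate
        for s, e in intervals[1:]:
            ps, pe = merged[-1]
            if s - pe < min_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        intervals = merged
    if min_contact_s:
        min_len = min_contact_s * grf.rate
        intervals = [(s, e) for s, e in intervals if e - s >= min_len]
    return StanceSegmentation(intervals, threshold=threshold, rate=grf.rate,
                              n_frames=len(grf.samples))


def _active_peak(contact: np.ndarray) -> float:
    """Max GRF within the 40-60% stance window (inclusive, round half-up)."""
    L = len(contact)
    lo = int(np.floor(ACTIVE_PEAK_WINDOW[0] * L + 0.5))
    hi = int(np.floor(ACTIVE_PEAK_WINDOW[1] * L + 0.5))
    hi = min(hi, L - 1)
    lo = min(lo, hi)
    return float(np.max(contact[lo:hi + 1]))


def _loading_rate(samples: np.ndarray, start: int, end: int,
                  rate: float) -> float:
    """Secant slope over the first 25 ms of stance, interpolated endpoints."""
    pos = start + LOADING_RATE_WINDOW_S * rate
    if pos > end - 1:
        return np.nan
    i0 = int(np.floor(pos))
    frac = pos - i0
    f_end = samples[i0] if frac == 0 else \
        samples[i0] * (1 - frac) + samples[i0 + 1] * frac
    return float((f_end - samples[start]) / LOADING_RATE_WINDOW_S)


def discrete_variables(grf: SignalTrace, seg: StanceSegmentation,
                       complete_only: bool = True,
                       edge_buffer_s: float = 0.0) -> StepKinetics:
    """The five discrete variables from a segmented GRF trace.

    Per-contact variables are computed for complete contacts only by default
    (a stance truncated by the trace boundary has no defined duration or
    impulse). Step frequency is observed contact onsets per second of the
    (buffer-trimmed) analysis window; see
    :meth:`StanceSegmentation.onset_count`.
    """
    if seg.rate != grf.rate:
        raise ValueError("segmentation must come from the same trace")
    dt = 1.0 / grf.rate
    intervals = seg.complete_intervals() if complete_only else seg.intervals
    peaks, impulses, rates, ctimes, valid = [], [], [], [], []
    for s, e in intervals:
        contact = grf.samples[s:e]
        peaks.append(_active_peak(contact))
        impulses.append(float(np.trapezoid(contact, dx=dt)))
        lr = _loading_rate(grf.samples, s, e, grf.rate)
        rates.append(lr)
        valid.append(np.isfinite(lr))
        ctimes.append(1000.0 * len(contact) / grf.rate)
    return StepKinetics(
        active_peak=np.array(peaks),
        impulse=np.array(impulses),
        loading_rate=np.array(rates),
        contact_time=np.array(ctimes),
        loading_rate_valid=np.array(valid, dtype=bool),
        step_frequency=seg.onset_count(edge_buffer_s)
        / (grf.duration - 2 * edge_buffer_s),
    )


DEFAULT_EDGE_BUFFER_S = 0.1


def check_boundaries(pred: SignalTrace,
                     measured: Optional[SignalTrace] = None,
                     max_step_freq: float = MAX_STEP_FREQ_HZ,
                     threshold: float = THRESHOLD_BW,
                     edge_buffer_s: float = DEFAULT_EDGE_BUFFER_S
                     ) -> BoundaryVerdict:
    """The two biomechanical plausibility criteria for a predicted waveform.

    1. (validation mode, requires ``measured``) equal number of observed
       foot-ground contact onsets in predicted and measured waveforms at the
       5% BW threshold. Onsets within ``edge_buffer_s`` of the window edges
       are not compared: whether a boundary-straddling contact crosses the
       threshold inside the window flips on frame-level timing error.
    2. predicted step frequency <= 4 Hz (inclusive).
    """
    seg_pred = segment_stance(pred, threshold)
    notes = []
    if measured is not None:
        if measured.rate != pred.rate:
            raise ValueError("predicted and measured traces must share a rate")
        seg_meas = segment_stance(measured, threshold)
        n_p = seg_pred.onset_count(edge_buffer_s)
        n_m = seg_meas.onset_count(edge_buffer_s)
        count_ok = n_p == n_m
        notes.append(f"observed onsets pred={n_p} meas={n_m}")
    else:
        count_ok = True
        notes.append("no measured trace: contact-count criterion skipped")
    freq = seg_pred.onset_count(edge_buffer_s) / \
        (pred.duration - 2 * edge_buffer_s)
    freq_ok = freq <= max_step_freq
    notes.append(f"step_freq={freq:.3f} Hz (bound {max_step_freq} Hz)")
    return BoundaryVerdict(contact_count_ok=bool(count_ok),
                           step_freq_ok=bool(freq_ok),
                           diagnostics="; ".join(notes))
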