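"""Per-frame input features: window statistics plus static descriptors.

Thirteen features per frame: mean/SD/range of each 12 ms acceleration window
on both axes (6), plus body mass, height, speed, slope and the three
foot-strike percentages broadcast across frames (7). All features are min-max
scaled to the training set's [0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import GaitTrial
from .preprocess import WindowedAcceleration

__all__ = [
    "FEATURE_NAMES",
    "FOOTSTRIKE_FEATURES",
    "FeatureSequence",
    "NormalizationParams",
    "window_stats",
    "raw_features",
    "fit_normalization",
    "build_features",
    "drop_footstrike",
]

FEATURE_NAMES = (
    "mean_v", "sd_v", "range_v",
    "mean_ap", "sd_ap", "range_ap",
    "mass", "height", "speed", "slope",
    "fs_rear", "fs_mid", "fs_fore",
)
FOOTSTRIKE_FEATURES = ("fs_rear", "fs_mid", "fs_fore")


def window_stats(window: np.ndarray) -> tuple[float, float, float]:
    """(mean, population SD, range) of one 6-frame window of one axis."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or len(w) != 6:
        raise ValueError("window must be a 1-D array of 6 frames")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    return float(w.mean()), float(w.std()), float(w.max() - w.min())


@dataclass
class NormalizationParams:
    """Per-feature min/max fitted on training frames only."""

    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if len(self.mins) != len(self.feature_names) or \
                len(self.maxs) != len(self.feature_names):
            raise ValueError("min/max length must match feature names")
        if np.any(self.maxs < self.mins):
            raise ValueError("max must be >= min for every feature")

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        """Scale columns to [0, 1]; degenerate (min == max) columns map to 0.

        Out-of-range values (e.g. test frames beyond the training extrema)
        are not clipped.
        """
        span = self.maxs - self.mins
        safe = np.where(span == 0, 1.0, span)
        out = (matrix - self.mins) / safe
        out[:, span == 0] = 0.0
        return out


@dataclass
class FeatureSequence:
    """T x K per-frame feature matrix with its provenance."""

    matrix: np.ndarray
    feature_names: tuple[str, ...]
    rate: float
    params: Optional[NormalizationParams] = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("column count must match feature names")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def raw_features(trial: GaitTrial, windows: WindowedAcceleration) -> np.ndarray:
    """Unscaled T x 13 feature matrix in canonical column order."""
    w = windows.windows  # (T, 6, 2): axis 0 = vertical, 1 = AP
    stats = []
    for axis in (0, 1):
        wa = w[:, :, axis]
        stats.extend([wa.mean(axis=1), wa.std(axis=1),
                      wa.max(axis=1) - wa.min(axis=1)])
    m = trial.meta
    static = [m.mass, m.height, m.speed, m.slope, m.fs_rear, m.fs_mid, m.fs_fore]
    T = windows.n_windows
    cols = stats + [np.full(T, v, dtype=float) for v in static]
    return np.column_stack(cols)


def fit_normalization(trials_windows: Sequence[tuple[GaitTrial, WindowedAcceleration]],
                      provenance: str = "") -> NormalizationParams:
    """Fit per-feature min/max over the pooled frames of the training trials."""
    if len(trials_windows) == 0:
        raise ValueError("cannot fit normalization on an empty training set")
    mins = np.full(len(FEATURE_NAMES), np.inf)
    maxs = np.full(len(FEATURE_NAMES), -np.inf)
    for trial, windows in trials_windows:
        mat = raw_features(trial, windows)
        mins = np.minimum(mins, mat.min(axis=0))
        maxs = np.maximum(maxs, mat.max(axis=0))
    return NormalizationParams(FEATURE_NAMES, mins, maxs, provenance=provenance)


def build_features(trial: GaitTrial, windows: WindowedAcceleration,
                   params: NormalizationParams) -> FeatureSequence:
    """Scaled T x 13 feature sequence for one trial."""
    if tuple(params.feature_names) != FEATURE_NAMES:
        raise ValueError(
            f"normalization params were fitted for {params.feature_names}, "
            f"expected {FEATURE_NAMES}")
    mat = params.transform(raw_features(trial, windows))
    return FeatureSequence(mat, FEATURE_NAMES, rate=windows.rate,
                           params=params, trial_id=trial.trial_id)


def drop_footstrike(seq: FeatureSequence) -> FeatureSequence:
    """Remove the three foot-strike columns (single-accelerometer ablation)."""
    missing = [n for n in FOOTSTRIKE_FEATURES if n not in seq.feature_names]
    if missing:
        raise ValueError(f"foot-strike columns already absent: {missing}")
    keep = [i for i, n in enumerate(seq.feature_names)
            if n not in FOOTSTRIKE_FEATURES]
    return FeatureSequence(
        seq.matrix[:, keep],
        tuple(seq.feature_names[i] for i in keep),
        rate=seq.rate, params=seq.params, trial_id=seq.trial_id)
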