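"""Synthetic paired GRF/accelerometer gait generator.

Produces physically consistent trials over a slope x speed x step-frequency
grid with closed-form per-step ground truth, so every downstream stage
(preprocessing, features, model, kinetics, evaluation) has an exact oracle.

Step model
----------
Each step period P = 1/f holds one stance of duration tc < P:

* active component  A * sin(pi * t / tc) on [0, tc], zero in the aerial phase;
* impact transient  I * exp(-(t - t_imp)^2 / (2 sigma^2)) confined to stance,
  peaking at 15% of stance with width sigma = 4% of stance. I grows with
  downhill slope and rearfoot-strike fraction.

A is chosen per step so that the mean normal force over one period is exactly
cos(slope) bodyweights:  A = pi * (cos(theta) * P - I * sigma * sqrt(2 pi)) / (2 tc).

Vertical acceleration follows whole-body dynamics, a_v = g * (F_BW - cos(theta)),
plus impact-synchronous damped ringing and sensor noise; the anteroposterior
channel carries a braking-propulsion biphasic wave with a slope-dependent bias.
A per-subject rotation mixes the two axes (no sensor-to-surface calibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    G,
    GaitTrial,
    GroundTruthKinetics,
    SignalTrace,
    TrialMeta,
)

__all__ = [
    "StepParams",
    "SimConfig",
    "simulate_step_grf",
    "simulate_trial",
    "simulate_cohort",
]

IMPACT_PEAK_FRAC = 0.15   # impact bump peak, fraction of stance
IMPACT_WIDTH_FRAC = 0.04  # impact bump sigma, fraction of stance
STANCE_THRESHOLD_BW = 0.05


@dataclass
class StepParams:
    """Closed-form parameters of one simulated step."""

    period_s: float
    tc_s: float
    active_BW: float
    impact_BW: float = 0.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("step period must be positive")
        if not (0 < self.tc_s < self.period_s):
            raise ValueError(
                f"contact time {self.tc_s} s must lie in (0, period={self.period_s} s): "
                "no aerial phase otherwise")
        if self.active_BW < 0 or self.impact_BW < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def impulse_BWs(self) -> float:
        """Analytic step impulse: half-sine + Gaussian bump integral."""
        sigma = IMPACT_WIDTH_FRAC * self.tc_s
        return 2.0 * self.active_BW * self.tc_s / math.pi + \
            self.impact_BW * sigma * math.sqrt(2.0 * math.pi)

    @property
    def contact_above_threshold_s(self) -> float:
        """Duration the half-sine exceeds the 5% BW stance threshold."""
        if self.active_BW <= STANCE_THRESHOLD_BW:
            return 0.0
        x = STANCE_THRESHOLD_BW / self.active_BW
        return self.tc_s * (1.0 - 2.0 * math.asin(x) / math.pi)


def _step_waveform(t_local: np.ndarray, tc: np.ndarray, A: np.ndarray,
                   I: np.ndarray) -> np.ndarray:
    """Evaluate the step GRF at local times ``t_local`` within each period."""
    stance = t_local <= tc
    grf = np.where(stance, A * np.sin(np.pi * np.clip(t_local / tc, 0.0, 1.0)), 0.0)
    sigma = IMPACT_WIDTH_FRAC * tc
    bump = I * np.exp(-0.5 * ((t_local - IMPACT_PEAK_FRAC * tc) / sigma) ** 2)
    grf = grf + np.where(stance, bump, 0.0)
    return np.maximum(grf, 0.0)


def simulate_step_grf(step: StepParams, rate: float) -> SignalTrace:
    """One step period of normal GRF in bodyweights at ``rate`` Hz."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(round(step.period_s * rate))
    t = np.arange(n) / rate
    tc = np.full(n, step.tc_s)
    grf = _step_waveform(t, tc, np.full(n, step.active_BW),
                         np.full(n, step.impact_BW))
    return SignalTrace(grf, rate=rate, axis="grf_normal_BW", units="BW")


def impact_amplitude(meta: TrialMeta) -> float:
    """Impact-bump amplitude [BW]: grows downhill and with rearfoot fraction."""
    w_fs = (meta.fs_rear + 0.4 * meta.fs_mid + 0.1 * meta.fs_fore) / 100.0
    return w_fs * max(0.0, 0.30 - 0.035 * meta.slope)


def preferred_step_frequency(meta: TrialMeta) -> float:
    """Base step frequency [Hz] for a trial's speed/slope/SF condition."""
    f = 3.05 + 0.015 * max(meta.slope, 0.0) + 0.06 * (meta.speed - 3.33)
    if meta.step_freq_condition == "+10%":
        f *= 1.1
    elif meta.step_freq_condition == "-10%":
        f *= 0.9
    return float(np.clip(f, 2.2, 3.95))


@dataclass
class SimConfig:
    """Cohort/trial generation settings. ``seed`` fixes all randomness."""

    slopes: Sequence[float] = (-10.0, -5.0, 0.0, 5.0, 10.0)
    speeds: Sequence[float] = (2.5, 3.33, 4.17)
    include_sf_conditions: bool = True
    sf_condition_speed: float = 3.33
    n_subjects: int = 2
    n_repeats: int = 1
    duration_s: float = 5.0
    rate_hz: float = 2000.0
    # noise magnitudes
    sensor_noise_sd: float = 0.3        # white noise on both axes [m/s^2]
    ringing_amp: float = 2.0            # soft-tissue ringing scale [m/s^2]
    ringing_freq_hz: float = 35.0
    ringing_tau_s: float = 0.04
    orientation_jitter_deg: float = 2.0  # sd of per-subject axis rotation
    step_var: float = 0.02              # per-step relative tc variability
    subject_var: float = 1.0            # scale of between-subject gait variability
    fs_profile: Optional[tuple] = None  # fixed (rear, mid, fore) %; None = sampled
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if self.n_subjects < 1 or self.n_repeats < 1:
            raise ValueError("n_subjects and n_repeats must be >= 1")
        for val in (self.sensor_noise_sd, self.ringing_amp, self.step_var):
            if val < 0:
                raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def noiseless(cls, **kwargs) -> "SimConfig":
        kwargs.setdefault("sensor_noise_sd", 0.0)
        kwargs.setdefault("ringing_amp", 0.0)
        kwargs.setdefault("orientation_jitter_deg", 0.0)
        kwargs.setdefault("step_var", 0.0)
        return cls(**kwargs)

    def conditions(self) -> list[tuple[float, float, str]]:
        """(slope, speed, step-frequency condition) grid for one subject."""
        conds = [(s, v, "preferred") for s in self.slopes for v in self.speeds]
        if self.include_sf_conditions:
            for s in self.slopes:
                for c in ("+10%", "-10%"):
                    conds.append((s, self.sf_condition_speed, c))
        return conds


def simulate_trial(meta: TrialMeta, cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None, *,
                   base_freq_hz: Optional[float] = None,
                   duty: float = 0.68,
                   phase: float = 0.0,
                   orientation_deg: Optional[float] = None,
                   trial_id: str = "") -> GaitTrial:
    """Simulate one trial of paired GRF and biaxial sacral acceleration.

    With all noise magnitudes at zero the trial is fully deterministic and its
    per-step ground truth is exact (closed form). ``phase`` in [0, 1) shifts
    the gait cycle: the first full contact onset falls at phase * period, with
    the tail of the preceding step visible before it (that partial step is not
    part of the truth record). Cohorts randomize the phase per trial so step
    timing cannot be inferred from the static descriptors alone.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not (0.0 <= phase < 1.0):
        raise ValueError("phase must lie in [0, 1)")
    f = base_freq_hz if base_freq_hz is not None else preferred_step_frequency(meta)
    period = 1.0 / f
    duty_eff = float(np.clip(duty - 0.06 * (meta.speed - 3.33), 0.35, 0.9))

    n = int(round(cfg.duration_s * cfg.rate_hz))
    t = np.arange(n) / cfg.rate_hz
    t0 = phase * period  # first full onset
    n_steps = int(np.floor((cfg.duration_s - t0 - 1e-12) / period)) + 1
    n_all = n_steps + 1  # index 0 = partial step preceding the trace

    # per-step parameters
    tc = duty_eff * period * (1.0 + cfg.step_var * rng.standard_normal(n_all))
    tc = np.clip(tc, 0.3 * period, 0.95 * period)
    impact = np.full(n_all, impact_amplitude(meta))
    sigma = IMPACT_WIDTH_FRAC * tc
    cos_th = math.cos(meta.slope_rad)
    # conservation: mean force over each period == cos(slope) BW
    active = np.pi * (cos_th * period - impact * sigma * np.sqrt(2 * np.pi)) / (2 * tc)
    if np.any(active <= STANCE_THRESHOLD_BW):
        raise ValueError("degenerate step: active amplitude below stance threshold")

    k = np.clip(np.floor((t - t0) / period).astype(int) + 1, 0, n_all - 1)
    t_local = t - (t0 + (k - 1) * period)
    grf = _step_waveform(t_local, tc[k], active[k], impact[k])

    # vertical acceleration from whole-body dynamics + ringing + noise
    acc_v = G * (grf - cos_th)
    if cfg.ringing_amp > 0:
        ring = (cfg.ringing_amp * (impact[k] + 0.1)
                * np.exp(-t_local / cfg.ringing_tau_s)
                * np.sin(2 * np.pi * cfg.ringing_freq_hz * t_local))
        acc_v = acc_v + ring

    # anteroposterior: braking-propulsion biphasic wave + slope bias
    b_amp = 2.5 * (meta.speed / 3.33)
    stance = t_local <= tc[k]
    acc_ap = np.where(stance, -b_amp * np.sin(2 * np.pi * t_local / tc[k]), 0.0)
    acc_ap = acc_ap + 0.25 * G * math.sin(meta.slope_rad) * grf

    if cfg.sensor_noise_sd > 0:
        acc_v = acc_v + cfg.sensor_noise_sd * rng.standard_normal(n)
        acc_ap = acc_ap + cfg.sensor_noise_sd * rng.standard_normal(n)

    # per-subject orientation cross-talk (sensor not aligned to surface)
    phi = 0.0 if orientation_deg is None else math.radians(orientation_deg)
    if phi != 0.0:
        c, s = math.cos(phi), math.sin(phi)
        acc_v, acc_ap = c * acc_v - s * acc_ap, s * acc_v + c * acc_ap

    onsets = t0 + np.arange(n_steps) * period
    steps = [StepParams(period, tc[i + 1], active[i + 1], impact[i + 1])
             for i in range(n_steps)]
    truth = GroundTruthKinetics(
        onset_s=onsets,
        contact_s=np.array([s.contact_above_threshold_s for s in steps]),
        halfsine_s=tc[1:].copy(),
        active_BW=active[1:].copy(),
        impact_BW=impact[1:].copy(),
        impact_frac=np.full(n_steps, IMPACT_PEAK_FRAC),
        impulse_BWs=np.array([s.impulse_BWs for s in steps]),
        step_freq_hz=n_steps / cfg.duration_s,
    )
    return GaitTrial(
        meta=meta,
        acc_v=SignalTrace(acc_v, cfg.rate_hz, "acc_vertical", "m/s2"),
        acc_ap=SignalTrace(acc_ap, cfg.rate_hz, "acc_anteroposterior", "m/s2"),
        grf=SignalTrace(grf, cfg.rate_hz, "grf_normal_BW", "BW"),
        truth=truth,
        trial_id=trial_id,
    )


def simulate_cohort(cfg: SimConfig) -> list[GaitTrial]:
    """n_subjects x len(conditions) x n_repeats trials, deterministic in seed.

    Subject mass, height, foot-strike profile, preferred-frequency offset and
    sensor orientation are drawn once per subject.
    """
    rng = np.random.default_rng(cfg.seed)
    trials: list[GaitTrial] = []
    for si in range(cfg.n_subjects):
        sid = f"S{si + 1:02d}"
        mass = float(np.clip(rng.normal(68.1, 9.9), 48.0, 95.0))
        height = float(np.clip(rng.normal(173.0, 9.0), 150.0, 200.0))
        if cfg.fs_profile is not None:
            fs = np.asarray(cfg.fs_profile, dtype=float)
        else:
            alpha = np.array([8.0, 2.0, 1.0]) / max(cfg.subject_var, 1e-3) ** 2
            fs = 100.0 * rng.dirichlet(alpha)
        fs = fs * (100.0 / fs.sum())  # exact sum for the meta invariant
        f_off = float(rng.normal(0.0, 0.08 * cfg.subject_var))
        duty0 = float(np.clip(rng.normal(0.68, 0.02 * cfg.subject_var), 0.5, 0.85))
        phi = float(rng.normal(0.0, cfg.orientation_jitter_deg)) \
            if cfg.orientation_jitter_deg > 0 else 0.0
        for rep in range(cfg.n_repeats):
            for slope, speed, cond in cfg.conditions():
                meta = TrialMeta(
                    subject_id=sid, mass=mass, height=height, speed=speed,
                    slope=slope, fs_rear=fs[0], fs_mid=fs[1], fs_fore=fs[2],
                    step_freq_condition=cond)
                f = float(np.clip(preferred_step_frequency(meta) + f_off, 2.2, 3.95))
                tid = f"{sid}_sl{slope:+.0f}_v{speed:.2f}_{cond}"
                if cfg.n_repeats > 1:
                    tid += f"_r{rep}"
                trials.append(simulate_trial(
                    meta, cfg, rng, base_freq_hz=f, duty=duty0,
                    phase=float(rng.uniform(0.0, 1.0)),
                    orientation_deg=phi, trial_id=tid))
    return trials
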