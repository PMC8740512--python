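"""Error metrics, cross-validation protocols and permutation importance.

Waveform error is RMSE over the full trace and relative RMSE (RMSE divided by
the mean of the two waveforms' ranges, as a percentage). Discrete variables
are compared with MAPE aggregated trial -> subject -> cohort. Generalization
is assessed with leave-one-subject-out cross-validation and a single-subject
slope split; feature relevance with trial-level permutation importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GaitTrial, SignalTrace
from .features import (FeatureSequence, NormalizationParams,
                       build_features, drop_footstrike, fit_normalization)
from .kinetics import (DEFAULT_EDGE_BUFFER_S, VARIABLE_NAMES,
                       check_boundaries, discrete_variables, segment_stance)
from .model import ModelConfig, TrainedModel, build, predict_batch, train
from .preprocess import PrepConfig, preprocess_trial

__all__ = [
    "EvalReport", "PFIResult", "PAPER_GROUPS",
    "rmse", "rrmse", "mape",
    "score_prediction", "score_predictions",
    "loso", "slope_split", "permutation_importance",
]

#: Grouped features as reported in the source study's importance analysis.
PAPER_GROUPS = {
    "vertical_acceleration": ["mean_v", "sd_v", "range_v"],
    "anteroposterior_acceleration": ["mean_ap", "sd_ap", "range_ap"],
    "foot_strike": ["fs_rear", "fs_mid", "fs_fore"],
    "slope": ["slope"],
    "speed": ["speed"],
    "height": ["height"],
    "mass": ["mass"],
}


def _samples(x) -> np.ndarray:
    return x.samples if isinstance(x, SignalTrace) else np.asarray(x, dtype=float)


def rmse(pred, meas) -> float:
    """Root mean square error over all frames (stance + aerial) [BW]."""
    p, m = _samples(pred), _samples(meas)
    if len(p) != len(m):
        raise ValueError(f"length mismatch: {len(p)} vs {len(m)}")
    d = p - m
    return float(np.sqrt(np.mean(d * d)))


def rrmse(pred, meas) -> float:
    """RMSE normalized to the average of the two waveform ranges [%]."""
    p, m = _samples(pred), _samples(meas)
    denom = 0.5 * ((p.max() - p.min()) + (m.max() - m.min()))
    if denom == 0:
        raise ValueError("both waveforms have zero range; rRMSE undefined")
    return float(rmse(p, m) / denom * 100.0)


def mape(pred_vars, meas_vars) -> dict[str, float]:
    """Per-variable absolute percent error on trial-aggregated variables.

    Variables whose measured value is 0 (or undefined) are NaN-flagged and
    excluded from aggregates.
    """
    p = pred_vars.aggregate() if hasattr(pred_vars, "aggregate") else dict(pred_vars)
    m = meas_vars.aggregate() if hasattr(meas_vars, "aggregate") else dict(meas_vars)
    out = {}
    for name in VARIABLE_NAMES:
        pv, mv = p.get(name, np.nan), m.get(name, np.nan)
        if not np.isfinite(mv) or mv == 0 or not np.isfinite(pv):
            out[name] = np.nan
        else:
            out[name] = abs(pv - mv) / abs(mv) * 100.0
    return out


@dataclass
class FoldInfo:
    """Per-fold provenance kept for leak auditing."""

    name: str
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    train_trial_ids: tuple[str, ...]
    test_trial_ids: tuple[str, ...]
    norm_params: NormalizationParams
    history: list


@dataclass
class EvalReport:
    """Per-trial and per-subject error tables plus cohort summary."""

    per_trial: pd.DataFrame
    per_subject: pd.DataFrame
    summary: dict
    folds: dict[str, FoldInfo] = field(default_factory=dict)


@dataclass
class PFIResult:
    """Permutation feature importance ratios (permuted RMSE / baseline)."""

    ratios: dict[str, float]
    baseline_rmse: float
    n_perm: int
    seed: Optional[int]


# ---------------------------------------------------------------------------
# shared fold machinery

def _prepare(trials: Sequence[GaitTrial], prep_cfg: PrepConfig):
    prepped = []
    for tr in trials:
        if tr.grf is None:
            raise ValueError(f"trial {tr.trial_id!r} has no measured GRF")
        prepped.append(preprocess_trial(tr, prep_cfg))
    return prepped


def _features_for(tw_pairs, params: NormalizationParams,
                  drop_fs: bool) -> list[FeatureSequence]:
    seqs = []
    for trial, windows in tw_pairs:
        seq = build_features(trial, windows, params)
        if drop_fs:
            seq = drop_footstrike(seq)
        seqs.append(seq)
    return seqs


def score_prediction(pred: SignalTrace, meas: SignalTrace, *,
                     trial_id: str = "", subject: str = "", fold: str = "",
                     slope: float = np.nan, speed: float = np.nan) -> dict:
    """Boundary verdict + error metrics for one predicted/measured pair.

    Trials failing either boundary get NaN metrics (excluded from
    aggregates) but still count toward the failure rate.
    """
    verdict = check_boundaries(pred, meas)
    row = {
        "trial_id": trial_id,
        "subject": subject,
        "fold": fold,
        "slope": slope,
        "speed": speed,
        "contact_count_ok": verdict.contact_count_ok,
        "step_freq_ok": verdict.step_freq_ok,
        "passed": verdict.passed,
        "rmse_BW": np.nan,
        "rrmse_pct": np.nan,
    }
    for v in VARIABLE_NAMES:
        row[f"mape_{v}"] = np.nan
    if verdict.passed:
        row["rmse_BW"] = rmse(pred, meas)
        row["rrmse_pct"] = rrmse(pred, meas)
        buf = DEFAULT_EDGE_BUFFER_S
        kp = discrete_variables(pred, segment_stance(pred), edge_buffer_s=buf)
        km = discrete_variables(meas, segment_stance(meas), edge_buffer_s=buf)
        for v, err in mape(kp, km).items():
            row[f"mape_{v}"] = err
    return row


def score_predictions(pairs: Sequence[tuple], fold: str = "") -> "EvalReport":
    """Assemble an EvalReport from (trial_id, subject, pred, meas) tuples."""
    rows = [score_prediction(p, m, trial_id=tid, subject=sub, fold=fold)
            for tid, sub, p, m in pairs]
    return _assemble(rows, {})


def _run_fold(name: str, train_tw, test_tw, model_cfg: ModelConfig,
              drop_fs: bool) -> tuple[list[dict], FoldInfo]:
    """Train on one partition, evaluate the other; one result row per trial."""
    params = fit_normalization(train_tw, provenance=name)
    train_seqs = _features_for(train_tw, params, drop_fs)
    test_seqs = _features_for(test_tw, params, drop_fs)
    targets = [t.grf for t, _ in train_tw]
    model = build(model_cfg, train_seqs[0].n_features)
    model.norm_params = params
    train(model, train_seqs, targets)
    preds = predict_batch(model, test_seqs)

    rows = [score_prediction(pred, trial.grf, trial_id=trial.trial_id,
                             subject=trial.meta.subject_id, fold=name,
                             slope=trial.meta.slope, speed=trial.meta.speed)
            for (trial, _), pred in zip(test_tw, preds)]
    info = FoldInfo(
        name=name,
        train_subjects=tuple(sorted({t.meta.subject_id for t, _ in train_tw})),
        test_subjects=tuple(sorted({t.meta.subject_id for t, _ in test_tw})),
        train_trial_ids=tuple(t.trial_id for t, _ in train_tw),
        test_trial_ids=tuple(t.trial_id for t, _ in test_tw),
        norm_params=params,
        history=list(model.history),
    )
    return rows, info


def _assemble(rows: list[dict], folds: dict[str, FoldInfo]) -> EvalReport:
    per_trial = pd.DataFrame(rows)
    n_total = len(per_trial)
    n_failed = int((~per_trial["passed"]).sum())
    metric_cols = ["rmse_BW", "rrmse_pct"] + [f"mape_{v}" for v in VARIABLE_NAMES]
    ok = per_trial[per_trial["passed"]]
    per_subject = ok.groupby("subject")[metric_cols].agg(["mean", "std"])
    per_subject.columns = [f"{c}_{s}" for c, s in per_subject.columns]
    per_subject = per_subject.reset_index()
    summary = {
        "n_trials": n_total,
        "n_failed": n_failed,
        "failure_rate": n_failed / n_total if n_total else np.nan,
        "n_contact_count_failures": int((~per_trial["contact_count_ok"]).sum()),
        "n_step_freq_failures": int((~per_trial["step_freq_ok"]).sum()),
    }
    # grand mean = mean of per-subject means
    for col in metric_cols:
        sub_means = per_subject[f"{col}_mean"]
        summary[f"{col}_mean"] = float(sub_means.mean())
        summary[f"{col}_sd"] = float(sub_means.std(ddof=1)) \
            if len(sub_means) > 1 else 0.0
    return EvalReport(per_trial=per_trial, per_subject=per_subject,
                      summary=summary, folds=folds)


def loso(trials: Sequence[GaitTrial],
         model_cfg: Optional[ModelConfig] = None,
         prep_cfg: Optional[PrepConfig] = None,
         drop_fs: bool = False) -> EvalReport:
    """Leave-one-subject-out cross-validation.

    One fold per subject; normalization and training see only the fold's
    training subjects. Trials failing the biomechanical boundaries count
    toward the failure rate and are excluded from all metric aggregates.
    """
    model_cfg = model_cfg or ModelConfig()
    prep_cfg = prep_cfg or PrepConfig()
    subjects = sorted({t.meta.subject_id for t in trials})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    counts = {s: sum(t.meta.subject_id == s for t in trials) for s in subjects}
    empty = [s for s, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"subjects with zero trials: {empty}")
    prepped = _prepare(trials, prep_cfg)

    rows: list[dict] = []
    folds: dict[str, FoldInfo] = {}
    for held_out in subjects:
        train_tw = [p for p in prepped if p[0].meta.subject_id != held_out]
        test_tw = [p for p in prepped if p[0].meta.subject_id == held_out]
        fold_rows, info = _run_fold(f"loso_{held_out}", train_tw, test_tw,
                                    model_cfg, drop_fs)
        rows.extend(fold_rows)
        folds[f"loso_{held_out}"] = info
    return _assemble(rows, folds)


TEST_SLOPES = (-5.0, 5.0)
TRAIN_SLOPES = (-10.0, 0.0, 10.0)


def slope_split(trials: Sequence[GaitTrial],
                model_cfg: Optional[ModelConfig] = None,
                prep_cfg: Optional[PrepConfig] = None,
                drop_fs: bool = False) -> EvalReport:
    """Single-subject split by slope: train 0/±10°, test ±5°.

    Models interpolation to speed-slope combinations absent from training.
    """
    model_cfg = model_cfg or ModelConfig()
    prep_cfg = prep_cfg or PrepConfig()
    subjects = {t.meta.subject_id for t in trials}
    if len(subjects) != 1:
        raise ValueError(f"slope split expects one subject, got {sorted(subjects)}")
    slopes = {t.meta.slope for t in trials}
    missing = [s for s in TRAIN_SLOPES + TEST_SLOPES if s not in slopes]
    if missing:
        raise ValueError(f"subject lacks trials at slopes: {missing}")
    prepped = _prepare(trials, prep_cfg)
    train_tw = [p for p in prepped if p[0].meta.slope in TRAIN_SLOPES]
    test_tw = [p for p in prepped if p[0].meta.slope in TEST_SLOPES]
    rows, info = _run_fold("slope_split", train_tw, test_tw, model_cfg, drop_fs)
    return _assemble(rows, {"slope_split": info})


# ---------------------------------------------------------------------------
# permutation feature importance

def _pooled_rmse(model: TrainedModel, seqs: Sequence[FeatureSequence],
                 targets: Sequence[np.ndarray]) -> float:
    preds = predict_batch(model, seqs)
    p = np.concatenate([pr.samples for pr in preds])
    m = np.concatenate([np.asarray(t, dtype=float) for t in targets])
    return rmse(p, m)


def _permuted_seqs(seqs: Sequence[FeatureSequence], cols: Sequence[int],
                   perm: np.ndarray) -> list[FeatureSequence]:
    """Swap whole-trial content of the given columns across trials."""
    out = []
    for i, seq in enumerate(seqs):
        mat = seq.matrix.copy()
        src = seqs[int(perm[i])].matrix
        mat[:, cols] = src[:, cols]
        out.append(FeatureSequence(mat, seq.feature_names, rate=seq.rate,
                                   params=seq.params, trial_id=seq.trial_id))
    return out


def permutation_importance(model: TrainedModel,
                           seqs: Sequence[FeatureSequence],
                           targets: Sequence,
                           n_perm: int = 100,
                           rng: Optional[np.random.Generator] = None,
                           groups: Optional[dict[str, list[str]]] = None,
                           seed: Optional[int] = None) -> PFIResult:
    """Trial-level permutation feature importance.

    For each feature (or named group of feature columns) the whole-trial
    column content is shuffled across the subject's trials, predictions are
    recomputed, and the ratio of the pooled permuted RMSE to the baseline
    pooled RMSE is averaged over ``n_perm`` draws.
    """
    if len(seqs) < 2:
        raise ValueError("permutation importance needs >= 2 trials")
    if rng is None:
        rng = np.random.default_rng(seed)
    names = seqs[0].feature_names
    if groups is None:
        groups = {n: [n] for n in names}
    ys = [_samples(t) for t in targets]
    baseline = _pooled_rmse(model, seqs, ys)
    if baseline == 0:
        raise ValueError("baseline RMSE is zero; PFI undefined")
    ratios = {}
    n = len(seqs)
    for gname, gcols in groups.items():
        missing = [c for c in gcols if c not in names]
        if missing:
            raise ValueError(f"group {gname!r} references absent features {missing}")
        cols = [names.index(c) for c in gcols]
        acc = 0.0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            permuted = _permuted_seqs(seqs, cols, perm)
            acc += _pooled_rmse(model, permuted, ys) / baseline
        ratios[gname] = acc / n_perm
    return PFIResult(ratios=ratios, baseline_rmse=baseline,
                     n_perm=n_perm, seed=seed)
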