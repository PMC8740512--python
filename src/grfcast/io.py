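"""Trial/cohort CSV formats and YAML run configuration.

A trial file is a plain CSV with columns ``time_s, grf_BW, acc_v, acc_ap``
(``grf_BW`` optional at prediction time) preceded by ``# key: value`` comment
lines carrying the trial metadata. A cohort directory holds one trial file
per trial plus ``cohort.csv`` (metadata index) and ``truth.csv`` (per-step
simulator ground truth, when available).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import GaitTrial, GroundTruthKinetics, SignalTrace, TrialMeta
from .model import ModelConfig
from .preprocess import FilterSpec, PrepConfig
from .synthetic import SimConfig

__all__ = [
    "read_trial", "write_trial", "read_cohort", "write_cohort",
    "RunConfig", "load_config", "dump_config",
]

TIME_TOL_S = 1e-6

_META_FIELDS = ("subject_id", "mass", "height", "speed", "slope",
                "fs_rear", "fs_mid", "fs_fore", "step_freq_condition")


def write_trial(trial: GaitTrial, path) -> None:
    """One CSV per trial: metadata comment header + signal columns."""
    path = Path(path)
    lines = ["# grfcast trial v1"]
    for f in _META_FIELDS:
        lines.append(f"# {f}: {getattr(trial.meta, f)}")
    lines.append(f"# trial_id: {trial.trial_id}")
    lines.append("# units: time_s [s], grf_BW [BW], acc_v/acc_ap [m/s2]")
    t = trial.acc_v.times
    cols = {"time_s": t}
    if trial.grf is not None:
        cols["grf_BW"] = trial.grf.samples
    cols["acc_v"] = trial.acc_v.samples
    cols["acc_ap"] = trial.acc_ap.samples
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _parse_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_trial(path) -> GaitTrial:
    """Parse a trial CSV; the sampling rate is inferred from the time column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw_meta = _parse_meta(path)
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "acc_v", "acc_ap"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer the rate")
    dt = np.diff(t)
    bad = np.flatnonzero(np.abs(dt - dt[0]) > TIME_TOL_S)
    if len(bad):
        raise ValueError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 1} "
            f"(dt={dt[bad[0]]:.9f} s, expected {dt[0]:.9f} s)")
    rate = 1.0 / dt[0]

    kwargs = {}
    for f in _META_FIELDS:
        if f not in raw_meta:
            raise ValueError(f"{path}: metadata header missing {f!r}")
        kwargs[f] = raw_meta[f] if f in ("subject_id", "step_freq_condition") \
            else float(raw_meta[f])
    meta = TrialMeta(**kwargs)

    grf = None
    if "grf_BW" in df.columns and not df["grf_BW"].isna().all():
        grf = SignalTrace(df["grf_BW"].to_numpy(dtype=float), rate,
                          "grf_normal_BW", "BW")
    return GaitTrial(
        meta=meta,
        acc_v=SignalTrace(df["acc_v"].to_numpy(dtype=float), rate,
                          "acc_vertical", "m/s2"),
        acc_ap=SignalTrace(df["acc_ap"].to_numpy(dtype=float), rate,
                           "acc_anteroposterior", "m/s2"),
        grf=grf,
        trial_id=raw_meta.get("trial_id", path.stem),
    )


def write_cohort(trials: Sequence[GaitTrial], out_dir) -> None:
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    index_rows, truth_rows = [], []
    for trial in trials:
        fname = f"{trial.trial_id or id(trial)}.csv"
        write_trial(trial, out / "trials" / fname)
        row = {f: getattr(trial.meta, f) for f in _META_FIELDS}
        row.update(trial_id=trial.trial_id, file=f"trials/{fname}")
        index_rows.append(row)
        if trial.truth is not None:
            tr = trial.truth
            for i in range(tr.n_steps):
                truth_rows.append({
                    "trial_id": trial.trial_id, "step": i,
                    "onset_s": tr.onset_s[i], "contact_s": tr.contact_s[i],
                    "halfsine_s": tr.halfsine_s[i],
                    "active_BW": tr.active_BW[i], "impact_BW": tr.impact_BW[i],
                    "impact_frac": tr.impact_frac[i],
                    "impulse_BWs": tr.impulse_BWs[i],
                    "step_freq_hz": tr.step_freq_hz,
                })
    pd.DataFrame(index_rows).to_csv(out / "cohort.csv", index=False)
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)


def read_cohort(data_dir) -> list[GaitTrial]:
    src = Path(data_dir)
    index = pd.read_csv(src / "cohort.csv")
    truth_df = None
    if (src / "truth.csv").exists():
        truth_df = pd.read_csv(src / "truth.csv")
    trials = []
    for _, row in index.iterrows():
        trial = read_trial(src / row["file"])
        if truth_df is not None:
            sub = truth_df[truth_df["trial_id"] == row["trial_id"]]
            if len(sub):
                sub = sub.sort_values("step")
                trial = trial.replace(truth=GroundTruthKinetics(
                    onset_s=sub["onset_s"].to_numpy(),
                    contact_s=sub["contact_s"].to_numpy(),
                    halfsine_s=sub["halfsine_s"].to_numpy(),
                    active_BW=sub["active_BW"].to_numpy(),
                    impact_BW=sub["impact_BW"].to_numpy(),
                    impact_frac=sub["impact_frac"].to_numpy(),
                    impulse_BWs=sub["impulse_BWs"].to_numpy(),
                    step_freq_hz=float(sub["step_freq_hz"].iloc[0]),
                ))
        trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# run configuration

@dataclasses.dataclass
class RunConfig:
    """Typed view of the YAML config; defaults equal the published pipeline."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    prep: PrepConfig = dataclasses.field(default_factory=PrepConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    seed: Optional[int] = None


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Parse a YAML run config, rejecting unknown keys."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(doc) - {"sim", "preprocess", "features", "model", "train",
                          "evaluate", "seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = RunConfig()
    if "sim" in doc:
        sim = dict(doc["sim"] or {})
        for key in ("slopes", "speeds"):
            if key in sim:
                sim[key] = tuple(float(v) for v in sim[key])
        cfg.sim = _build_section(SimConfig, sim, "sim")
    prep = dict(doc.get("preprocess") or {})
    if prep:
        grf_cut = prep.pop("grf_cutoff_hz", None)
        acc_cut = prep.pop("acc_cutoff_hz", None)
        order = prep.pop("filter_order", 4)
        allowed = {"rate_hz", "window_frames"}
        unknown = set(prep) - allowed
        if unknown:
            raise ValueError(f"unknown keys in config section 'preprocess': {sorted(unknown)}")
        cfg.prep = PrepConfig(
            rate_hz=float(prep.get("rate_hz", 500.0)),
            grf_filter=FilterSpec(float(grf_cut) if grf_cut else 30.0, order=order),
            acc_filter=FilterSpec(float(acc_cut) if acc_cut else 20.0, order=order),
            window_frames=int(prep.get("window_frames", 6)),
        )
    if "model" in doc or "train" in doc:
        merged = dict(doc.get("model") or {})
        merged.update(doc.get("train") or {})
        if "mlp_sizes" in merged:
            merged["mlp_sizes"] = tuple(int(v) for v in merged["mlp_sizes"])
        cfg.model = _build_section(ModelConfig, merged, "model")
    if doc.get("seed") is not None:
        cfg.seed = int(doc["seed"])
        cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        cfg.model = dataclasses.replace(cfg.model, seed=cfg.seed)
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    """Write the effective config snapshot next to a run's outputs."""
    doc = {
        "seed": cfg.seed,
        "sim": dataclasses.asdict(cfg.sim),
        "preprocess": {
            "rate_hz": cfg.prep.rate_hz,
            "grf_cutoff_hz": cfg.prep.grf_filter.cutoff_hz,
            "acc_cutoff_hz": cfg.prep.acc_filter.cutoff_hz,
            "filter_order": cfg.prep.grf_filter.order,
            "window_frames": cfg.prep.window_frames,
        },
        "model": dataclasses.asdict(cfg.model),
    }
    doc["sim"]["slopes"] = list(doc["sim"]["slopes"])
    doc["sim"]["speeds"] = list(doc["sim"]["speeds"])
    doc["model"]["mlp_sizes"] = list(doc["model"]["mlp_sizes"])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
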