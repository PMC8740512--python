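"""Frame-by-frame GRF regressor: bidirectional LSTM + per-frame MLP.

Implemented directly in NumPy (forward pass, full backpropagation through
time, Adam, inverted dropout, early stopping) so the package has no deep
learning framework dependency. Gradients are verified against central finite
differences in the test suite.

Architecture (sequence in, sequence out):

    input dropout (20%)
    -> bidirectional LSTM (tanh/sigmoid gates; forward and time-reversed
       passes with elementwise-averaged full output sequences)
    -> dropout (40%)
    -> per-frame MLP, ReLU hidden layers (128, 384, 320 by default)
    -> per-frame linear scalar output
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .core import SignalTrace
from .features import FeatureSequence, NormalizationParams

__all__ = ["ModelConfig", "TrainedModel", "build", "train", "predict",
           "save_model", "load_model"]


@dataclass
class ModelConfig:
    """Architecture and optimization settings (defaults = published values)."""

    lstm_units: int = 128           # not stated in the source; configurable
    mlp_sizes: tuple[int, ...] = (128, 384, 320)
    input_dropout: float = 0.20
    post_lstm_dropout: float = 0.40
    batch_size: int = 32
    learning_rate: float = 0.001
    max_epochs: int = 1000
    early_stop_min_delta: float = 0.001
    early_stop_patience: int = 30
    seed: int = 0
    dtype: str = "float32"  # float64 available for gradient verification
    bidirectional_merge: str = "average"
    mlp_activation: str = "relu"
    output_activation: str = "linear"
    loss: str = "mse"

    def __post_init__(self) -> None:
        self.mlp_sizes = tuple(int(s) for s in self.mlp_sizes)
        if self.lstm_units < 1 or any(s < 1 for s in self.mlp_sizes):
            raise ValueError("all layer sizes must be positive")
        for p in (self.input_dropout, self.post_lstm_dropout):
            if not (0.0 <= p < 1.0):
                raise ValueError("dropout rates must lie in [0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("invalid optimizer settings")


@dataclass
class TrainedModel:
    """Parameters plus everything needed to reproduce a training run."""

    cfg: ModelConfig
    n_features: int
    params: dict
    feature_names: Optional[tuple[str, ...]] = None
    norm_params: Optional[NormalizationParams] = None
    history: list = field(default_factory=list)
    stopped_epoch: Optional[int] = None
    trained: bool = False


# ---------------------------------------------------------------------------
# parameter init

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            dtype: str) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def _init_params(cfg: ModelConfig, n_features: int,
                 rng: np.random.Generator) -> dict:
    U, dt = cfg.lstm_units, cfg.dtype
    params: dict[str, np.ndarray] = {}
    for d in ("fwd", "bwd"):
        params[f"Wx_{d}"] = _glorot(rng, n_features, 4 * U, dt)
        params[f"Wh_{d}"] = _glorot(rng, U, 4 * U, dt)
        b = np.zeros(4 * U, dtype=dt)
        b[U:2 * U] = 1.0  # forget-gate bias
        params[f"b_{d}"] = b
    sizes = (U,) + cfg.mlp_sizes + (1,)
    for i in range(len(sizes) - 1):
        params[f"W{i}"] = _glorot(rng, sizes[i], sizes[i + 1], dt)
        params[f"b{i}"] = np.zeros(sizes[i + 1], dtype=dt)
    return params


def build(cfg: ModelConfig, n_features: int) -> TrainedModel:
    """Untrained model with seeded initial weights."""
    if n_features < 1:
        raise ValueError("n_features must be positive")
    rng = np.random.default_rng(cfg.seed)
    return TrainedModel(cfg=cfg, n_features=n_features,
                        params=_init_params(cfg, n_features, rng))


# ---------------------------------------------------------------------------
# forward / backward
#
# The LSTM recurrence runs time-major: arrays are (T, B, ...) so every
# per-timestep slice is contiguous and the gate nonlinearities vectorize.

def _lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                  b: np.ndarray):
    """One-direction LSTM over time-major x (T, B, F); H (T, B, U) + caches.

    Gate cache layout matches the weight layout: Z holds the activated gates
    [i, f, g, o] per timestep.
    """
    T, B, F = x.shape
    U = Wh.shape[0]
    xz = (x.reshape(T * B, F) @ Wx).reshape(T, B, 4 * U)
    xz += b
    Z = np.empty((T, B, 4 * U), dtype=x.dtype)   # activated gates
    H = np.empty((T, B, U), dtype=x.dtype)
    C = np.empty((T, B, U), dtype=x.dtype)
    TC = np.empty((T, B, U), dtype=x.dtype)
    h = np.zeros((B, U), dtype=x.dtype)
    c = np.zeros((B, U), dtype=x.dtype)
    for t in range(T):
        z = xz[t] + h @ Wh
        zt = Z[t]
        zt[:, :2 * U] = expit(z[:, :2 * U])            # i, f
        zt[:, 2 * U:3 * U] = np.tanh(z[:, 2 * U:3 * U])  # g
        zt[:, 3 * U:] = expit(z[:, 3 * U:])            # o
        c = zt[:, U:2 * U] * c + zt[:, :U] * zt[:, 2 * U:3 * U]
        tc = np.tanh(c)
        h = zt[:, 3 * U:] * tc
        C[t] = c; TC[t] = tc; H[t] = h
    return H, (Z, C, TC)


def _lstm_backward(dH: np.ndarray, x: np.ndarray, H: np.ndarray, cache,
                   Wx: np.ndarray, Wh: np.ndarray):
    """BPTT for one direction (time-major). Returns (dWx, dWh, db)."""
    Z, C, TC = cache
    T, B, F = x.shape
    U = Wh.shape[0]
    WhT = np.ascontiguousarray(Wh.T)
    dZ = np.empty_like(Z)
    dh = np.zeros((B, U), dtype=x.dtype)
    dc = np.zeros((B, U), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        zt = Z[t]
        i, f = zt[:, :U], zt[:, U:2 * U]
        g, o = zt[:, 2 * U:3 * U], zt[:, 3 * U:]
        tc = TC[t]
        dh_t = dH[t] + dh
        dc_t = dc + dh_t * o * (1.0 - tc * tc)
        c_prev = C[t - 1] if t > 0 else 0.0
        dzt = dZ[t]
        dzt[:, :U] = dc_t * g * i * (1.0 - i)
        dzt[:, U:2 * U] = dc_t * c_prev * f * (1.0 - f)
        dzt[:, 2 * U:3 * U] = dc_t * i * (1.0 - g * g)
        dzt[:, 3 * U:] = dh_t * tc * o * (1.0 - o)
        dh = dzt @ WhT
        dc = dc_t * f
    dZ2 = dZ.reshape(T * B, 4 * U)
    dWx = x.reshape(T * B, F).T @ dZ2
    Hprev = np.concatenate(
        [np.zeros((1, B, U), dtype=x.dtype), H[:-1]], axis=0)
    dWh = Hprev.reshape(T * B, U).T @ dZ2
    db = dZ2.sum(axis=0)
    return dWx, dWh, db


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _forward(params: dict, cfg: ModelConfig, x: np.ndarray,
             masks: Optional[tuple] = None):
    """Full network forward pass; x is (B, T, F). Returns (yhat, cache).

    Internally time-major: the recurrence sees (T, B, F) so per-timestep
    slices are contiguous.
    """
    mask_in, mask_post = masks if masks is not None else (None, None)
    x_tm = np.ascontiguousarray(x.transpose(1, 0, 2))  # (T, B, F)
    if mask_in is not None:
        x_tm = x_tm * mask_in
    Hf, cache_f = _lstm_forward(x_tm, params["Wx_fwd"], params["Wh_fwd"],
                                params["b_fwd"])
    xr = np.ascontiguousarray(x_tm[::-1])
    Hb_r, cache_b = _lstm_forward(xr, params["Wx_bwd"], params["Wh_bwd"],
                                  params["b_bwd"])
    Havg = 0.5 * (Hf + Hb_r[::-1])
    Ha = Havg * mask_post if mask_post is not None else Havg
    T, B, U = Ha.shape
    a = Ha.reshape(T * B, U)
    acts = [a]
    n_hidden = len(cfg.mlp_sizes)
    for i in range(n_hidden):
        a = _relu(a @ params[f"W{i}"] + params[f"b{i}"])
        acts.append(a)
    y = a @ params[f"W{n_hidden}"] + params[f"b{n_hidden}"]
    yhat = y.reshape(T, B).T  # back to (B, T)
    cache = (x_tm, xr, Hf, cache_f, Hb_r, cache_b, acts, mask_post)
    return yhat, cache


def _loss_and_grads(params: dict, cfg: ModelConfig, x: np.ndarray,
                    y: np.ndarray, rng: Optional[np.random.Generator] = None):
    """Mean-squared-error loss and gradients for one batch.

    ``rng`` enables dropout (training mode); inference uses no masks.
    """
    masks = None
    if rng is not None and (cfg.input_dropout > 0 or cfg.post_lstm_dropout > 0):
        mask_in = mask_post = None
        B_, T_ = x.shape[0], x.shape[1]
        if cfg.input_dropout > 0:
            keep = 1.0 - cfg.input_dropout
            mask_in = (rng.random((T_, B_, x.shape[2])) < keep
                       ).astype(x.dtype) / keep
        if cfg.post_lstm_dropout > 0:
            keep = 1.0 - cfg.post_lstm_dropout
            mask_post = (rng.random((T_, B_, cfg.lstm_units)) < keep
                         ).astype(x.dtype) / keep
        masks = (mask_in, mask_post)

    yhat, cache = _forward(params, cfg, x, masks)
    x_tm, xr, Hf, cache_f, Hb_r, cache_b, acts, mask_post = cache
    B, T = yhat.shape
    U = cfg.lstm_units
    n = yhat.size
    diff = yhat - y
    loss = float(np.mean(diff * diff))

    grads: dict[str, np.ndarray] = {}
    da = (2.0 / n) * diff.T.reshape(T * B, 1)  # time-major like acts
    n_hidden = len(cfg.mlp_sizes)
    for i in range(n_hidden, -1, -1):
        a_prev = acts[i]
        grads[f"W{i}"] = a_prev.T @ da
        grads[f"b{i}"] = da.sum(axis=0)
        if i > 0:
            da = (da @ params[f"W{i}"].T) * (acts[i] > 0)
        else:
            da = da @ params[f"W{i}"].T
    dHa = da.reshape(T, B, U)
    if mask_post is not None:
        dHa = dHa * mask_post
    dHalf = 0.5 * dHa
    dWx, dWh, db = _lstm_backward(dHalf, x_tm, Hf, cache_f,
                                  params["Wx_fwd"], params["Wh_fwd"])
    grads["Wx_fwd"], grads["Wh_fwd"], grads["b_fwd"] = dWx, dWh, db
    dWx, dWh, db = _lstm_backward(dHalf[::-1], xr, Hb_r, cache_b,
                                  params["Wx_bwd"], params["Wh_bwd"])
    grads["Wx_bwd"], grads["Wh_bwd"], grads["b_bwd"] = dWx, dWh, db
    return loss, grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            params[k] -= self.lr * (self.m[k] / bc1) / \
                (np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# training / inference

def _stack_sequences(seqs: Sequence[FeatureSequence],
                     model: TrainedModel) -> np.ndarray:
    lengths = {s.n_frames for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"training sequences have unequal lengths: {sorted(lengths)}")
    names = {s.feature_names for s in seqs}
    if len(names) != 1:
        raise ValueError("training sequences have inconsistent feature names")
    feats = next(iter(names))
    if model.feature_names is None:
        if len(feats) != model.n_features:
            raise ValueError(
                f"model expects {model.n_features} features, got {len(feats)}")
        model.feature_names = feats
    elif feats != model.feature_names:
        _raise_feature_mismatch(feats, model.feature_names)
    return np.stack([s.matrix for s in seqs]).astype(model.cfg.dtype)


def _raise_feature_mismatch(got, expected) -> None:
    missing = [n for n in expected if n not in got]
    extra = [n for n in got if n not in expected]
    raise ValueError(
        f"feature mismatch: missing {missing or 'none'}, extra {extra or 'none'}")


def train(model: TrainedModel, seqs: Sequence[FeatureSequence],
          targets: Sequence, cfg: Optional[ModelConfig] = None) -> TrainedModel:
    """Fit with Adam on per-frame MSE; early-stops on the training loss.

    ``targets`` are per-trial GRF waveforms in BW (SignalTrace or array),
    one per feature sequence, all the same length as their sequences.
    """
    if cfg is not None:
        model.cfg = cfg
    c = model.cfg
    if len(seqs) == 0:
        raise ValueError("empty training set")
    if len(seqs) != len(targets):
        raise ValueError("one target waveform per feature sequence required")
    x = _stack_sequences(seqs, model)
    ys = [t.samples if isinstance(t, SignalTrace) else np.asarray(t, dtype=float)
          for t in targets]
    if any(len(yi) != x.shape[1] for yi in ys):
        raise ValueError("target length must equal sequence length")
    y = np.stack(ys).astype(c.dtype)

    rng = np.random.default_rng(c.seed)
    opt = _Adam(model.params, c.learning_rate)
    B = x.shape[0]
    best = np.inf
    wait = 0
    model.history = []
    for epoch in range(c.max_epochs):
        order = rng.permutation(B)
        total, count = 0.0, 0
        for start in range(0, B, c.batch_size):
            idx = order[start:start + c.batch_size]
            loss, grads = _loss_and_grads(model.params, c, x[idx], y[idx], rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // c.batch_size}; "
                    "try a lower learning rate")
            opt.step(model.params, grads)
            total += loss * len(idx)
            count += len(idx)
        epoch_loss = total / count
        model.history.append(epoch_loss)
        if best - epoch_loss > c.early_stop_min_delta:
            best = epoch_loss
            wait = 0
        else:
            wait += 1
            if wait >= c.early_stop_patience:
                model.stopped_epoch = epoch
                break
    else:
        model.stopped_epoch = c.max_epochs - 1
    model.trained = True
    return model


def predict(model: TrainedModel, seq: FeatureSequence) -> SignalTrace:
    """Predicted normal-GRF waveform [BW], one value per input frame."""
    if model.feature_names is not None and \
            seq.feature_names != model.feature_names:
        _raise_feature_mismatch(seq.feature_names, model.feature_names)
    if seq.n_features != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {seq.n_features}")
    x = seq.matrix[np.newaxis].astype(model.cfg.dtype)
    yhat, _ = _forward(model.params, model.cfg, x, masks=None)
    return SignalTrace(yhat[0].astype(float), rate=seq.rate,
                       axis="grf_normal_BW", units="BW")


def predict_batch(model: TrainedModel, seqs: Sequence[FeatureSequence]
                  ) -> list[SignalTrace]:
    """Vectorized prediction for equal-length sequences."""
    if not seqs:
        return []
    x = np.stack([s.matrix for s in seqs]).astype(model.cfg.dtype)
    yhat, _ = _forward(model.params, model.cfg, x, masks=None)
    return [SignalTrace(yhat[i].astype(float), rate=s.rate,
                        axis="grf_normal_BW", units="BW")
            for i, s in enumerate(seqs)]


# ---------------------------------------------------------------------------
# serialization

def save_model(model: TrainedModel, out_dir) -> None:
    """Write params (npz) plus a JSON sidecar with config and provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "params.npz", **model.params)
    meta = {
        "config": asdict(model.cfg),
        "n_features": model.n_features,
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "history": [float(v) for v in model.history],
        "stopped_epoch": model.stopped_epoch,
        "trained": model.trained,
        "norm_params": None,
    }
    if model.norm_params is not None:
        meta["norm_params"] = {
            "feature_names": list(model.norm_params.feature_names),
            "mins": model.norm_params.mins.tolist(),
            "maxs": model.norm_params.maxs.tolist(),
            "provenance": model.norm_params.provenance,
        }
    (out / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir) -> TrainedModel:
    src = Path(model_dir)
    meta = json.loads((src / "model.json").read_text())
    cfg_kw = dict(meta["config"])
    cfg_kw["mlp_sizes"] = tuple(cfg_kw["mlp_sizes"])
    cfg = ModelConfig(**cfg_kw)
    with np.load(src / "params.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    norm = None
    if meta.get("norm_params"):
        np_meta = meta["norm_params"]
        norm = NormalizationParams(
            tuple(np_meta["feature_names"]),
            np.array(np_meta["mins"]), np.array(np_meta["maxs"]),
            provenance=np_meta.get("provenance", ""))
    return TrainedModel(
        cfg=cfg, n_features=meta["n_features"], params=params,
        feature_names=tuple(meta["feature_names"]) if meta["feature_names"] else None,
        norm_params=norm, history=meta["history"],
        stopped_epoch=meta["stopped_epoch"], trained=meta["trained"])
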