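# grfcast

Prediction of continuous **normal (surface-perpendicular) ground reaction
force waveforms** from biaxial sacral accelerometry across running speeds
(2.5–4.17 m/s) and slopes (0°, ±5°, ±10°), with the full training/validation
machinery and a synthetic gait simulator so the entire pipeline is buildable
and testable without any external data.

## What's inside

| Module | Purpose |
| --- | --- |
| `grfcast.synthetic` | Physically consistent paired GRF/accelerometer trial generator (half-sine stance + slope/foot-strike-dependent impact transient; acceleration from whole-body dynamics) with closed-form per-step ground truth. |
| `grfcast.preprocess` | Downsampling to 500 Hz, zero-phase 4th-order Butterworth filtering (30 Hz GRF / 20 Hz acceleration), bodyweight normalization, negative-clipping of vertical acceleration, and overlapping 6-frame (12 ms) windows — one window per GRF frame via asymmetric (3 lead / 2 trail) edge padding. |
| `grfcast.features` | The 13 per-frame input features (mean/SD/range of both acceleration axes per window + mass, height, speed, slope, foot-strike percentages), min–max scaled on training frames only. |
| `grfcast.model` | Sequence-to-sequence regressor: input dropout 20% → bidirectional LSTM (outputs averaged) → dropout 40% → per-frame MLP 128/384/320 (ReLU) → linear scalar. Implemented directly in NumPy (forward, BPTT, Adam, early stopping); gradients are verified against finite differences in the test suite. |
| `grfcast.kinetics` | 5% BW stance segmentation (with configurable debounce), active peak (40–60% of stance), impulse, loading rate (secant over first 25 ms), contact time, step frequency, and the two biomechanical boundary criteria. |
| `grfcast.evaluation` | RMSE / relative RMSE / MAPE, leave-one-subject-out cross-validation, single-subject slope split (train 0°/±10°, test ±5°), foot-strike ablation, and trial-level permutation feature importance. |
| `grfcast.io` / `grfcast.cli` | CSV trial/cohort formats, YAML run configuration (defaults = published pipeline values), and the `grfcast` command line. |

## CLI

```bash
grfcast simulate --config sim.yaml --out data/        # synthetic cohort
grfcast preprocess --trial data/trials/T.csv --out T500.csv
grfcast train --data data/ --config cfg.yaml --out model/ [--no-footstrike]
grfcast predict --model model/ --trial data/trials/T.csv --out pred.csv
grfcast kinetics --grf pred.csv --out vars.csv
grfcast loso --data data/ --config cfg.yaml --out report/
grfcast slope-split --data data/ --subject S01 --out report/
grfcast pfi --model model/ --data data/ --subject S01 --n-perm 100 --out pfi.json
grfcast evaluate --pred pred.csv --measured meas.csv --out metrics.json
```

Example YAML config:

```yaml
seed: 1
sim:        {n_subjects: 8, duration_s: 5.0, rate_hz: 2000}
preprocess: {rate_hz: 500, grf_cutoff_hz: 30, acc_cutoff_hz: 20, window_frames: 6}
model:      {lstm_units: 128, mlp_sizes: [128, 384, 320], batch_size: 32,
             learning_rate: 0.001, max_epochs: 1000}
```

## Notes and documented choices

- No deep-learning framework is required: the BiLSTM+MLP and its training
  loop are pure NumPy (float32 by default; float64 available via
  `ModelConfig(dtype=...)` and used by the gradient-check tests).
- The LSTM hidden width is not fixed by the published architecture; it
  defaults to 128 and is configurable.
- Normalization parameters are fitted per cross-validation fold on training
  subjects only (leak-free).
- Contact counting for the boundary criteria uses observed onsets away from
  the window edges (default 100 ms buffer), making verdicts robust to
  frame-level onset timing error at the trace boundaries; per-contact
  variables are computed on complete (non-truncated) contacts.
- Stance segmentation debounce (25 ms minimum contact, 10 ms minimum aerial
  gap) is configurable and can be disabled.
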