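import numpy as np
import pytest

from grfcast.evaluation import (PAPER_GROUPS, _permuted_seqs, _pooled_rmse,
                                loso, mape, permutation_importance, rmse,
                                rrmse, score_predictions, slope_split)
from grfcast.features import FEATURE_NAMES, FeatureSequence
from grfcast.kinetics import discrete_variables, segment_stance
from grfcast.model import ModelConfig, build, train
from grfcast.preprocess import PrepConfig
from grfcast.synthetic import SimConfig, simulate_cohort
from .conftest import make_trace

TINY_MODEL = ModelConfig(lstm_units=4, mlp_sizes=(8,), batch_size=8,
                         max_epochs=2, seed=0)
FAST_PREP = PrepConfig()


def _tiny_cohort(n_subjects=2, slopes=(-10.0, -5.0, 0.0, 5.0, 10.0),
                 speeds=(3.33,), duration=1.0, seed=0):
    cfg = SimConfig(n_subjects=n_subjects, slopes=slopes, speeds=speeds,
                    include_sf_conditions=False, duration_s=duration,
                    seed=seed)
    return simulate_cohort(cfg)


class TestRMSE:
    def test_identical(self, rng):
        x = make_trace(rng.random(100))
        assert rmse(x, x) == 0.0

    def test_constant_offset(self, rng):
        x = rng.random(100)
        assert rmse(make_trace(x + 0.1), make_trace(x)) == \
            pytest.approx(0.1, abs=1e-12)

    def test_brute_force(self, rng):
        for _ in range(20):
            a, b = rng.random(50), rng.random(50)
            expected = np.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / 50)
            assert rmse(make_trace(a), make_trace(b)) == \
                pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            rmse(make_trace(np.zeros(5)), make_trace(np.zeros(6)))


class TestRRMSE:
    def test_five_percent(self):
        # RMSE exactly 0.1 with both ranges exactly 0..2 -> 5%
        a = 0.1 * np.sqrt(2)
        meas = make_trace([0.0, 2.0, 1.0, 1.0])
        pred = make_trace([0.0, 2.0, 1.0 + a, 1.0 - a])
        assert rmse(pred, meas) == pytest.approx(0.1, abs=1e-15)
        assert rrmse(pred, meas) == pytest.approx(5.0, abs=1e-12)

    def test_identical_zero(self, rng):
        x = make_trace(rng.random(100))
        assert rrmse(x, x) == 0.0

    def test_mixed_ranges(self):
        # pred range 1, meas range 3, RMSE 0.2 -> 0.2 / 2 * 100 = 10%
        pred = make_trace([0.0, 1.0])
        meas = make_trace([0.2, 3.2])
        expected = rmse(pred, meas) / (0.5 * (1 + 3)) * 100
        assert rrmse(pred, meas) == pytest.approx(expected, abs=1e-12)

    def test_zero_range_undefined(self):
        with pytest.raises(ValueError):
            rrmse(make_trace(np.ones(10)), make_trace(np.ones(10)))


class TestMAPE:
    def _vars(self, trace):
        return discrete_variables(trace, segment_stance(trace))

    def test_identical(self):
        from .test_kinetics import _halfsine_train
        trace = _halfsine_train()
        out = mape(self._vars(trace), self._vars(trace))
        for v in out.values():
            assert v == 0.0

    def test_contact_time_five_percent(self):
        out = mape({"contact_time": 210.0}, {"contact_time": 200.0})
        assert out["contact_time"] == pytest.approx(5.0)

    def test_zero_measured_excluded(self):
        out = mape({"impulse": 1.0}, {"impulse": 0.0})
        assert np.isnan(out["impulse"])

    def test_brute_force(self, rng):
        from grfcast.kinetics import VARIABLE_NAMES
        p = {v: rng.random() + 0.5 for v in VARIABLE_NAMES}
        m = {v: rng.random() + 0.5 for v in VARIABLE_NAMES}
        out = mape(p, m)
        for v in VARIABLE_NAMES:
            assert out[v] == pytest.approx(abs(p[v] - m[v]) / m[v] * 100,
                                           abs=1e-12)


class TestScorePredictions:
    def test_failure_bookkeeping(self):
        from .test_kinetics import _halfsine_train
        good = _halfsine_train(n_steps=6)
        missing = _halfsine_train(n_steps=6)
        seg = segment_stance(missing)
        s, e = seg.intervals[2]
        missing.samples[s:e] = 0.0  # one fewer contact
        fast = _halfsine_train(n_steps=12, period=0.22, tc=0.15, lead=0.05)
        fast_meas = _halfsine_train(n_steps=12, period=0.22, tc=0.15,
                                    lead=0.05)
        pairs = []
        for i in range(10):
            if i < 2:
                pairs.append((f"t{i}", "S1", missing, good))
            elif i < 3:
                pairs.append((f"t{i}", "S1", fast, fast_meas))
            else:
                pairs.append((f"t{i}", "S1", good, good))
        report = score_predictions(pairs)
        assert report.summary["failure_rate"] == pytest.approx(3 / 10)
        failed = set(report.per_trial[~report.per_trial.passed].trial_id)
        assert failed == {"t0", "t1", "t2"}
        assert report.per_trial[~report.per_trial.passed]["rmse_BW"].isna().all()


class TestLOSO:
    def test_partition(self):
        trials = _tiny_cohort(n_subjects=3)
        report = loso(trials, TINY_MODEL, FAST_PREP)
        assert len(report.folds) == 3
        tested = []
        for info in report.folds.values():
            assert set(info.test_subjects).isdisjoint(info.train_subjects)
            assert len(info.test_subjects) == 1
            tested.extend(info.test_subjects)
        assert sorted(tested) == ["S01", "S02", "S03"]
        # no trial in both train and test of any fold
        for info in report.folds.values():
            assert set(info.train_trial_ids).isdisjoint(info.test_trial_ids)

    def test_two_subject_swap(self):
        trials = _tiny_cohort(n_subjects=2)
        report = loso(trials, TINY_MODEL, FAST_PREP)
        infos = list(report.folds.values())
        assert infos[0].test_subjects == infos[1].train_subjects
        assert infos[1].test_subjects == infos[0].train_subjects

    def test_single_subject_rejected(self):
        trials = _tiny_cohort(n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            loso(trials, TINY_MODEL, FAST_PREP)

    def test_normalization_leakfree(self):
        from grfcast.evaluation import _prepare
        from grfcast.features import raw_features
        trials = _tiny_cohort(n_subjects=2)
        report = loso(trials, TINY_MODEL, FAST_PREP)
        prepped = {t.trial_id: p for t, p in
                   [(p[0], p) for p in _prepare(trials, FAST_PREP)]}
        for info in report.folds.values():
            params = info.norm_params
            pooled = np.vstack([raw_features(*prepped[tid])
                                for tid in info.train_trial_ids])
            scaled = params.transform(pooled)
            span = params.maxs - params.mins
            assert scaled[:, span > 0].max() == pytest.approx(1.0)
            assert scaled[:, span > 0].min() == pytest.approx(0.0)


class TestSlopeSplit:
    def test_partition(self):
        trials = [t for t in _tiny_cohort(n_subjects=1,
                                          speeds=(2.5, 3.33, 4.17))]
        report = slope_split(trials, TINY_MODEL, FAST_PREP)
        info = report.folds["slope_split"]
        assert len(info.test_trial_ids) == 6   # +-5 deg x 3 speeds
        assert len(info.train_trial_ids) == 9  # 0/+-10 deg x 3 speeds
        test_slopes = {t.meta.slope for t in trials
                       if t.trial_id in info.test_trial_ids}
        assert test_slopes == {-5.0, 5.0}

    def test_missing_slope_rejected(self):
        trials = [t for t in _tiny_cohort(n_subjects=1)
                  if t.meta.slope != 5.0]
        with pytest.raises(ValueError, match="slopes"):
            slope_split(trials, TINY_MODEL, FAST_PREP)

    def test_multi_subject_rejected(self):
        with pytest.raises(ValueError, match="one subject"):
            slope_split(_tiny_cohort(n_subjects=2), TINY_MODEL, FAST_PREP)

    def test_personalized_beats_loso_for_same_subject(self):
        """Single-subject slope interpolation outperforms cross-subject
        generalization (stochastic sanity check; ~2 min)."""
        from grfcast.evaluation import _assemble, _prepare, _run_fold
        sim = SimConfig(n_subjects=8, include_sf_conditions=False,
                        duration_s=2.5, sensor_noise_sd=0.1, ringing_amp=1.0,
                        orientation_jitter_deg=0.5, step_var=0.01,
                        subject_var=0.4, fs_profile=(80.0, 15.0, 5.0),
                        seed=42)
        trials = simulate_cohort(sim)
        mc = ModelConfig(lstm_units=32, mlp_sizes=(32, 32), batch_size=64,
                         learning_rate=0.003, max_epochs=40,
                         early_stop_min_delta=1e-4, early_stop_patience=12,
                         seed=0)
        prepped = _prepare(trials, PrepConfig())
        train_tw = [p for p in prepped if p[0].meta.subject_id != "S01"]
        test_tw = [p for p in prepped if p[0].meta.subject_id == "S01"]
        rows, info = _run_fold("loso_S01", train_tw, test_tw, mc, False)
        loso_fold = _assemble(rows, {"loso_S01": info})
        s01 = [t for t in trials if t.meta.subject_id == "S01"]
        split = slope_split(s01, mc)
        assert split.summary["rrmse_pct_mean"] < \
            loso_fold.summary["rrmse_pct_mean"]


def _pfi_setup(n_trials=4, T=60, seed=0):
    rng = np.random.default_rng(seed)
    seqs, targets = [], []
    for _ in range(n_trials):
        mat = rng.random((T, 13))
        mat[:, FEATURE_NAMES.index("mass")] = rng.random()  # static per trial
        seqs.append(FeatureSequence(mat, FEATURE_NAMES, rate=500.0))
        targets.append(2.0 * mat[:, 0] + 0.1)
    cfg = ModelConfig(lstm_units=8, mlp_sizes=(8,), input_dropout=0.0,
                      post_lstm_dropout=0.0, batch_size=4,
                      learning_rate=0.01, max_epochs=60,
                      early_stop_patience=60, seed=0)
    model = train(build(cfg, 13), seqs, targets)
    return model, seqs, targets


class TestPFI:
    def test_identity_permutation_ratio_one(self):
        model, seqs, targets = _pfi_setup()
        base = _pooled_rmse(model, seqs, [np.asarray(t) for t in targets])
        identity = np.arange(len(seqs))
        permuted = _permuted_seqs(seqs, [0], identity)
        assert _pooled_rmse(model, permuted,
                            [np.asarray(t) for t in targets]) == base

    def test_constant_feature_ratio_one(self):
        model, seqs, targets = _pfi_setup()
        idx = FEATURE_NAMES.index("slope")
        for s in seqs:
            s.matrix[:, idx] = 0.5  # identical across trials
        res = permutation_importance(model, seqs, targets, n_perm=5,
                                     seed=0, groups={"slope": ["slope"]})
        assert res.ratios["slope"] == pytest.approx(1.0, abs=1e-12)

    def test_acceleration_beats_static(self):
        model, seqs, targets = _pfi_setup()
        res = permutation_importance(
            model, seqs, targets, n_perm=10, seed=1,
            groups={"mean_v": ["mean_v"], "mass": ["mass"]})
        assert res.ratios["mean_v"] > res.ratios["mass"]

    def test_single_trial_rejected(self):
        model, seqs, targets = _pfi_setup()
        with pytest.raises(ValueError, match="2 trials"):
            permutation_importance(model, seqs[:1], targets[:1], n_perm=2)

    def test_paper_groups_cover_features(self):
        cols = [c for g in PAPER_GROUPS.values() for c in g]
        assert sorted(cols) == sorted(FEATURE_NAMES)
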