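"""Stacked ensembles: base forests, meta-learner, thresholds, LOPO-CV."""

import numpy as np
import pandas as pd
import pytest

from sozloc.evaluate import roc_auc
from sozloc.spectral import BAND_NAMES
from sozloc.srfe import (
    ElectrodeFeatures,
    OutcomeFeatures,
    SRFEConfig,
    averaged_rf_baseline,
    fit_srfe,
    lopo_cv,
    majority_vote,
    outcome_lopo_cv,
    simple_rf_baseline,
    srfe_probabilities,
    train_band_rf,
    train_srfe,
    tune_threshold_accuracy,
    tune_threshold_ppv,
)

rng = np.random.default_rng(7)


def separable_toy(n=60, w=8, seed=0):
    r = np.random.default_rng(seed)
    y = np.array([1] * (n // 3) + [0] * (n - n // 3))
    X = r.gamma(2.0, 1.0, size=(n, w))
    X[y == 1] *= 10.0
    return X, y


def toy_band_features(n_rows, w=6, informative="beta", seed=0, n_patients=5):
    """Six-band features where only one band separates the classes."""
    r = np.random.default_rng(seed)
    y = r.integers(0, 2, size=n_rows)
    X = {}
    for b in BAND_NAMES:
        base = r.normal(0, 1, size=(n_rows, w))
        if b == informative:
            base[y == 1] += 3.0
        X[b] = base
    meta = pd.DataFrame(
        {
            "patient_id": [f"p{i % n_patients}" for i in range(n_rows)],
            "seizure_id": [f"s{i % 2}" for i in range(n_rows)],
            "electrode": [f"e{i}" for i in range(n_rows)],
            "label": y,
        }
    )
    return ElectrodeFeatures(X=X, meta=meta), y


class TestBandRF:
    def test_separable_toy_training_auc_is_one(self):
        X, y = separable_toy()
        rf = train_band_rf(X, y, seed=0)
        assert roc_auc(rf.predict_proba(X)[:, 1], y) == 1.0

    def test_shuffled_labels_give_chance_cv_auc(self):
        from sklearn.model_selection import StratifiedKFold, cross_val_predict
        from sklearn.ensemble import RandomForestClassifier

        r = np.random.default_rng(1)
        X = r.normal(size=(200, 10))
        y = r.permutation([0] * 100 + [1] * 100)
        rf = RandomForestClassifier(n_estimators=100, random_state=0)
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        probs = cross_val_predict(rf, X, y, cv=cv, method="predict_proba")[:, 1]
        assert 0.3 <= roc_auc(probs, y) <= 0.7

    def test_deterministic_under_seed(self):
        X, y = separable_toy(seed=3)
        p1 = train_band_rf(X, y, seed=11).predict_proba(X)
        p2 = train_band_rf(X, y, seed=11).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_band_rf(np.zeros((5, 3)), np.ones(5), seed=0)


class TestMetaLearner:
    def test_informative_base_model_gets_largest_coefficient(self):
        r = np.random.default_rng(2)
        y = r.integers(0, 2, size=300)
        meta_X = r.uniform(0, 1, size=(300, 6))
        meta_X[:, 2] = 0.8 * y + 0.1 * r.uniform(size=300)  # informative column
        models = {b: None for b in BAND_NAMES}
        model = train_srfe(models, meta_X, y, SRFEConfig.electrode())
        coefs = np.abs(np.ravel(model.meta.coef_))
        assert np.argmax(coefs) == 2

    def test_identical_base_models_share_weight_under_ridge(self):
        r = np.random.default_rng(3)
        y = r.integers(0, 2, size=200)
        col = 0.7 * y + 0.15 * r.uniform(size=200)
        meta_X = np.tile(col[:, None], (1, 6))
        model = train_srfe({b: None for b in BAND_NAMES}, meta_X, y,
                           SRFEConfig.electrode())
        coefs = np.ravel(model.meta.coef_)
        assert coefs.max() / coefs.min() < 1.5

    def test_ensemble_probabilities_in_unit_interval(self):
        feats, y = toy_band_features(100, seed=4)
        model, oof = fit_srfe(feats.X, y, SRFEConfig.electrode())
        probs = srfe_probabilities(model, feats.X)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.all((oof >= 0) & (oof <= 1))


def ppv_oracle(probs, labels, ppv_min):
    """Exhaustive search over all candidate thresholds."""
    cands = np.unique(probs)
    cands = np.append(cands, np.nextafter(cands[-1], np.inf))
    best = None
    for theta in cands:
        pred = probs >= theta
        pos = pred.sum()
        if pos == 0:
            continue
        tp = int((pred & (labels == 1)).sum())
        if tp / pos >= ppv_min and (best is None or tp > best[1]):
            best = (theta, tp)
    return best


def accuracy_oracle(probs, labels):
    cands = np.unique(probs)
    cands = np.append(cands, np.nextafter(cands[-1], np.inf))
    best = None
    for theta in cands:
        acc = np.mean((probs >= theta).astype(int) == labels)
        if best is None or acc > best[1]:
            best = (theta, acc)
    return best


class TestThresholds:
    def test_ppv_worked_example(self):
        res = tune_threshold_ppv([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 1], 0.95)
        assert res.theta == 0.8 and res.tp == 2 and res.feasible

    def test_ppv_all_positive(self):
        res = tune_threshold_ppv([0.3, 0.9, 0.5], [1, 1, 1], 0.95)
        assert res.theta == 0.3 and res.tp == 3

    def test_ppv_all_negative_flags_infeasible(self):
        res = tune_threshold_ppv([0.3, 0.9], [0, 0], 0.95)
        assert not res.feasible
        assert res.theta > 0.9  # sentinel: nothing labelled positive

    def test_ppv_empty_rejected(self):
        with pytest.raises(ValueError):
            tune_threshold_ppv([], [], 0.95)

    def test_accuracy_worked_example(self):
        res = tune_threshold_accuracy([0.9, 0.2], [1, 0])
        assert res.theta == 0.9 and res.objective == 1.0

    def test_accuracy_all_positive(self):
        res = tune_threshold_accuracy([0.4, 0.6, 0.5], [1, 1, 1])
        assert res.theta == 0.4

    @pytest.mark.parametrize("mode", ["ppv", "accuracy"])
    def test_matches_exhaustive_oracle(self, mode):
        r = np.random.default_rng(5)
        for trial in range(100):
            n = int(r.integers(3, 40))
            probs = np.round(r.uniform(size=n), 2)  # rounding forces ties
            labels = r.integers(0, 2, size=n)
            if mode == "ppv":
                if labels.sum() == 0:
                    labels[0] = 1
                res = tune_threshold_ppv(probs, labels, 0.95)
                oracle = ppv_oracle(probs, labels, 0.95)
                if oracle is None:
                    assert not res.feasible
                else:
                    assert res.feasible
                    assert (res.theta, res.tp) == oracle
            else:
                res = tune_threshold_accuracy(probs, labels)
                theta, acc = accuracy_oracle(probs, labels)
                assert res.theta == theta
                assert res.objective == pytest.approx(acc)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes,expect",
        [((1, 1, 0, 0), 1), ((1, 0, 0), 0), ((0,), 0), ((1,), 1)],
    )
    def test_vote(self, votes, expect):
        assert majority_vote(votes) == expect

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestLOPO:
    def test_fold_structure_and_no_leakage(self):
        feats, _ = toy_band_features(100, seed=6, n_patients=5)
        res = lopo_cv(feats, SRFEConfig.electrode(rf_seed=0))
        assert set(res.fold_models) == {f"p{i}" for i in range(5)}
        for pid in res.fold_models:
            fold_rows = res.rows[res.rows["fold"] == pid]
            assert set(fold_rows["patient_id"]) == {pid}

    def test_duplicated_patient_rows_do_not_leak(self):
        feats, _ = toy_band_features(60, seed=7, n_patients=3)
        dup = ElectrodeFeatures(
            X={b: np.vstack([x, x]) for b, x in feats.X.items()},
            meta=pd.concat(
                [feats.meta, feats.meta.assign(patient_id="p_dup")],
                ignore_index=True,
            ),
        )
        res = lopo_cv(dup, SRFEConfig.electrode(rf_seed=0))
        for pid, fold_rows in res.rows.groupby("fold"):
            assert set(fold_rows["patient_id"]) == {pid}

    def test_baselines_on_separable_features(self):
        feats, y = toy_band_features(120, seed=8, n_patients=4)
        cfg = SRFEConfig.electrode(rf_seed=0)
        rf, oof = simple_rf_baseline(feats.X, y, cfg)
        Xc = np.hstack([feats.X[b] for b in feats.X])
        assert roc_auc(rf.predict_proba(Xc)[:, 1], y) == 1.0
        band_models = {
            b: train_band_rf(feats.X[b], y, 100, i) for i, b in enumerate(feats.X)
        }
        avg = averaged_rf_baseline(band_models, feats.X)
        per_band = np.column_stack(
            [band_models[b].predict_proba(feats.X[b])[:, 1] for b in band_models]
        )
        assert np.allclose(avg, per_band.mean(axis=1))

    def test_averaged_of_identical_outputs_is_identity(self):
        class Fixed:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([1 - self.p, self.p])

        p = rng.uniform(size=9)
        models = {b: Fixed(p) for b in BAND_NAMES}
        X = {b: np.zeros((9, 2)) for b in BAND_NAMES}
        assert np.allclose(averaged_rf_baseline(models, X), p)
        alternating = {
            b: Fixed(np.full(9, float(i % 2))) for i, b in enumerate(BAND_NAMES)
        }
        assert np.allclose(averaged_rf_baseline(alternating, X), 0.5)


class TestOutcomeCV:
    def make_outcome_features(self, ratios_by_patient, n_seizures=2, w=4):
        rows, X = [], {b: [] for b in BAND_NAMES}
        r = np.random.default_rng(0)
        for pid, (gamma_ratio, label) in ratios_by_patient.items():
            for s in range(n_seizures):
                for b in BAND_NAMES:
                    level = gamma_ratio if b == "gamma" else 1.0
                    X[b].append(level + 0.05 * r.normal(size=10 * w))
                rows.append({"patient_id": pid, "seizure_id": f"s{s}", "label": label})
        return OutcomeFeatures(
            X={b: np.vstack(v) for b, v in X.items()}, meta=pd.DataFrame(rows)
        )

    def test_constructed_separation_gives_perfect_accuracy(self):
        feats = self.make_outcome_features(
            {f"sf{i}": (5.0, 1) for i in range(3)}
            | {f"nsf{i}": (1.0, 0) for i in range(3)}
        )
        res = outcome_lopo_cv(feats, SRFEConfig.outcome(rf_seed=0))
        assert (res.voted["pred"] == res.voted["label"]).all()
        assert not res.flagged_folds

    def test_identical_features_give_constant_predictions(self):
        # majority-positive cohort: every training fold shares the majority
        labels = [1, 1, 1, 1, 0, 0]
        feats = self.make_outcome_features(
            {f"a{i}": (1.0, lab) for i, lab in enumerate(labels)}
        )
        for b in feats.X:
            feats.X[b][:] = 1.0
        res = outcome_lopo_cv(feats, SRFEConfig.outcome(rf_seed=0))
        assert res.voted["pred"].nunique() == 1
        acc = float((res.voted["pred"] == res.voted["label"]).mean())
        assert acc == pytest.approx(4 / 6)

    def test_single_class_training_fold_flagged(self):
        feats = self.make_outcome_features({"a": (5.0, 1), "b": (1.0, 1), "c": (2.0, 0)})
        # holding out "c" leaves a single-class training fold
        res = outcome_lopo_cv(feats, SRFEConfig.outcome(rf_seed=0))
        assert "c" in res.flagged_folds

    def test_deterministic_under_seed(self):
        feats = self.make_outcome_features(
            {f"sf{i}": (5.0, 1) for i in range(3)}
            | {f"nsf{i}": (1.0, 0) for i in range(3)}
        )
        r1 = outcome_lopo_cv(feats, SRFEConfig.outcome(rf_seed=1))
        r2 = outcome_lopo_cv(feats, SRFEConfig.outcome(rf_seed=1))
        assert np.allclose(r1.rows["prob"], r2.rows["prob"])
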