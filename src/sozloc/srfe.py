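"""Stacked random-forest ensembles for SOZ labelling and outcome prediction.

Two classifiers share one architecture: six random forests (100 trees each),
one per frequency band, combined by a penalized logistic (GLM) meta-learner
on the six base-model probabilities — a stacked random forest ensemble
(SRFE).

* SRFE-electrode labels individual electrodes as SOZ / non-SOZ from their
  raw ictal band-power time series (one feature per analysis window per
  band). Meta-learner: ridge (mixing 0) with the penalty strength chosen by
  internal cross-validated search. The decision threshold maximizes true
  positives subject to PPV >= 0.95, prioritizing specificity so that a
  positive call rarely mislabels resectable tissue.
* SRFE-outcome predicts post-operative seizure freedom from per-seizure
  SOZ/non-SOZ decile-ratio features. Meta-learner: elastic net with mixing
  0.5 and fixed strength 0.1; threshold maximizes accuracy.

Stacking hygiene: the meta-learner is always trained on out-of-fold base
probabilities (internal stratified K-fold within each training set), never
on in-sample fits, and leave-one-patient-out cross-validation keeps every
row of the held-out patient away from base training, meta training and
threshold tuning. Per-seizure binary calls are combined per patient (or per
electrode) by majority vote, with exactly 50% voting positive.

Penalty strengths follow the glmnet convention (average per-observation
loss); they map to scikit-learn's ``C`` as ``C = 1/(n_samples * lambda)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .group_stats import decile_ratio_features, decile_table
from .spectral import BandPowerTensor

__all__ = [
    "SRFEConfig",
    "SRFEModel",
    "ThresholdResult",
    "ElectrodeFeatures",
    "OutcomeFeatures",
    "CVResult",
    "train_band_rf",
    "train_srfe",
    "fit_srfe",
    "srfe_probabilities",
    "tune_threshold_ppv",
    "tune_threshold_accuracy",
    "majority_vote",
    "lopo_cv",
    "outcome_lopo_cv",
    "simple_rf_baseline",
    "averaged_rf_baseline",
    "build_electrode_features",
    "build_outcome_features",
]


@dataclass(frozen=True)
class SRFEConfig:
    """Hyperparameters shared by both ensembles.

    meta_alpha is the elastic-net mixing (0 = ridge, 1 = lasso); meta_lambda
    the penalty strength in the glmnet convention, or "search" for an
    internal cross-validated search. electrode/outcome factory methods give
    the two published configurations.
    """

    n_trees: int = 100
    meta_alpha: float = 0.0
    meta_lambda: float | str = "search"
    rf_seed: int = 0
    internal_cv: int = 5
    ppv_min: float = 0.95
    threshold_mode: str = "ppv"  # "ppv" | "accuracy"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 <= self.meta_alpha <= 1:
            raise ValueError("meta_alpha must lie in [0, 1]")
        if self.meta_lambda != "search" and float(self.meta_lambda) < 0:
            raise ValueError('meta_lambda must be >= 0 or "search"')
        if self.threshold_mode not in ("ppv", "accuracy"):
            raise ValueError('threshold_mode must be "ppv" or "accuracy"')

    @classmethod
    def electrode(cls, rf_seed: int = 0, **kw) -> "SRFEConfig":
        return cls(meta_alpha=0.0, meta_lambda="search", rf_seed=rf_seed,
                   threshold_mode="ppv", **kw)

    @classmethod
    def outcome(cls, rf_seed: int = 0, **kw) -> "SRFEConfig":
        return cls(meta_alpha=0.5, meta_lambda=0.1, rf_seed=rf_seed,
                   threshold_mode="accuracy", **kw)


@dataclass
class ThresholdResult:
    theta: float
    feasible: bool
    tp: int = 0
    objective: float = 0.0


@dataclass
class SRFEModel:
    """Six per-band forests + logistic meta-learner + decision threshold."""

    band_models: dict[str, RandomForestClassifier]
    meta: LogisticRegression
    config: SRFEConfig
    threshold: float = 0.5
    threshold_feasible: bool = True

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.band_models)

    @property
    def meta_coefficients(self) -> dict[str, float]:
        coefs = np.ravel(self.meta.coef_)
        return dict(zip(self.band_names, coefs.tolist()))


@dataclass
class ElectrodeFeatures:
    """One row per electrode × seizure; per-band W-window power features."""

    X: dict[str, np.ndarray]  # band -> (n_rows, W)
    meta: pd.DataFrame  # patient_id, seizure_id, electrode, label

    def subset(self, mask: np.ndarray) -> "ElectrodeFeatures":
        return ElectrodeFeatures(
            X={b: x[mask] for b, x in self.X.items()},
            meta=self.meta.loc[mask].reset_index(drop=True),
        )


@dataclass
class OutcomeFeatures:
    """One row per seizure; per-band 10-decile × W-window ratio features."""

    X: dict[str, np.ndarray]  # band -> (n_rows, 10*W)
    meta: pd.DataFrame  # patient_id, seizure_id, label

    def subset(self, mask: np.ndarray) -> "OutcomeFeatures":
        return OutcomeFeatures(
            X={b: x[mask] for b, x in self.X.items()},
            meta=self.meta.loc[mask].reset_index(drop=True),
        )


@dataclass
class CVResult:
    """Leave-one-patient-out predictions plus per-fold models."""

    rows: pd.DataFrame  # per unit × seizure: prob, pred, fold
    voted: pd.DataFrame  # per final unit after majority voting
    fold_models: dict[str, object]
    thresholds: dict[str, ThresholdResult]
    flagged_folds: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# base and meta learners
# ---------------------------------------------------------------------------


def train_band_rf(
    X: np.ndarray, y: np.ndarray, n_trees: int = 100, seed: int = 0
) -> RandomForestClassifier:
    """Fit one per-band classification forest."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(np.asarray(X, dtype=float), y)
    return rf


def _internal_cv(y: np.ndarray, n_splits: int, seed: int) -> StratifiedKFold:
    counts = np.bincount(np.asarray(y, dtype=int))
    k = int(min(n_splits, counts[counts > 0].min()))
    if k < 2:
        raise ValueError("too few samples per class for internal cross-validation")
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def oof_band_probabilities(
    X: np.ndarray, y: np.ndarray, cfg: SRFEConfig, seed_offset: int = 0
) -> np.ndarray:
    """Out-of-fold positive-class probabilities for one band's forest."""
    seed = cfg.rf_seed + seed_offset
    rf = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed, n_jobs=1)
    cv = _internal_cv(y, cfg.internal_cv, seed)
    probs = cross_val_predict(rf, X, y, cv=cv, method="predict_proba")
    return probs[:, 1]


def _lambda_to_C(lam: float, n: int) -> float:
    return 1.0 / (max(n, 1) * lam) if lam > 0 else 1e12


def _fit_meta(meta_X: np.ndarray, y: np.ndarray, cfg: SRFEConfig) -> LogisticRegression:
    n = len(y)
    if cfg.meta_lambda == "search":
        cv = _internal_cv(y, cfg.internal_cv, cfg.rf_seed)
        model = LogisticRegressionCV(
            Cs=np.logspace(-3, 5, 17),
            cv=cv,
            penalty="l2",
            scoring="neg_log_loss",
            max_iter=10000,
            random_state=cfg.rf_seed,
        )
    else:
        C = _lambda_to_C(float(cfg.meta_lambda), n)
        if cfg.meta_alpha == 0:
            model = LogisticRegression(penalty="l2", C=C, max_iter=10000)
        elif cfg.meta_alpha == 1:
            model = LogisticRegression(
                penalty="l1", C=C, solver="saga", max_iter=10000,
                tol=1e-8, random_state=cfg.rf_seed,
            )
        else:
            model = LogisticRegression(
                penalty="elasticnet",
                l1_ratio=cfg.meta_alpha,
                C=C,
                solver="saga",
                max_iter=10000,
                tol=1e-8,
                random_state=cfg.rf_seed,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence chatter on tiny folds
        model.fit(meta_X, y)
    return model


def train_srfe(
    band_models: dict[str, RandomForestClassifier],
    meta_X: np.ndarray,
    y: np.ndarray,
    cfg: SRFEConfig,
) -> SRFEModel:
    """Combine fitted per-band forests with a penalized logistic meta-learner.

    ``meta_X`` must hold *out-of-fold* base probabilities, one column per
    band in the order of ``band_models`` — in-sample base fits would let the
    meta-learner reward overfit forests.
    """
    if meta_X.shape[1] != len(band_models):
        raise ValueError("meta feature columns must align with the base models")
    meta = _fit_meta(np.asarray(meta_X, dtype=float), np.asarray(y, dtype=int), cfg)
    return SRFEModel(band_models=dict(band_models), meta=meta, config=cfg)


def fit_srfe(
    X: dict[str, np.ndarray], y: np.ndarray, cfg: SRFEConfig
) -> tuple[SRFEModel, np.ndarray]:
    """Full stacked fit on one training set.

    Returns the model (threshold tuned on the cross-validated ensemble
    probabilities) and those out-of-fold ensemble probabilities.
    """
    y = np.asarray(y, dtype=int)
    band_names = list(X)
    oof = np.column_stack(
        [oof_band_probabilities(X[b], y, cfg, seed_offset=i)
         for i, b in enumerate(band_names)]
    )
    band_models = {
        b: train_band_rf(X[b], y, n_trees=cfg.n_trees, seed=cfg.rf_seed + i)
        for i, b in enumerate(band_names)
    }
    model = train_srfe(band_models, oof, y, cfg)
    oof_probs = model.meta.predict_proba(oof)[:, 1]
    tune = (
        tune_threshold_ppv(oof_probs, y, cfg.ppv_min)
        if cfg.threshold_mode == "ppv"
        else tune_threshold_accuracy(oof_probs, y)
    )
    model.threshold = tune.theta
    model.threshold_feasible = tune.feasible
    return model, oof_probs


def srfe_probabilities(model: SRFEModel, X: dict[str, np.ndarray]) -> np.ndarray:
    """Ensemble probability for new rows (base probs → meta-learner)."""
    base = np.column_stack(
        [model.band_models[b].predict_proba(X[b])[:, 1] for b in model.band_names]
    )
    return model.meta.predict_proba(base)[:, 1]


# ---------------------------------------------------------------------------
# threshold tuning and voting
# ---------------------------------------------------------------------------


def _candidate_thresholds(probs: np.ndarray) -> np.ndarray:
    cands = np.unique(probs)
    sentinel = np.nextafter(cands[-1], np.inf)  # "label nothing positive"
    return np.append(cands, sentinel)


def tune_threshold_ppv(
    probs: Sequence[float], labels: Sequence[int], ppv_min: float = 0.95
) -> ThresholdResult:
    """Maximize true positives subject to PPV >= ppv_min.

    Candidates are the sorted unique probabilities (plus a sentinel above the
    maximum); a unit is called positive when its probability >= theta. Ties
    in TP are broken toward the lower threshold. If no candidate satisfies
    the constraint the sentinel is returned with ``feasible=False`` (nothing
    labelled positive).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    best: ThresholdResult | None = None
    for theta in _candidate_thresholds(probs):
        pred = probs >= theta
        tp = int(np.sum(pred & (labels == 1)))
        pos = int(pred.sum())
        if pos == 0:
            continue
        ppv = tp / pos
        if ppv >= ppv_min and (best is None or tp > best.tp):
            best = ThresholdResult(float(theta), True, tp=tp, objective=ppv)
    if best is None:
        sentinel = float(_candidate_thresholds(probs)[-1])
        return ThresholdResult(sentinel, False, tp=0, objective=0.0)
    return best


def tune_threshold_accuracy(
    probs: Sequence[float], labels: Sequence[int]
) -> ThresholdResult:
    """Maximize accuracy over the candidate threshold grid; ties → lower theta."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    best: ThresholdResult | None = None
    for theta in _candidate_thresholds(probs):
        pred = (probs >= theta).astype(int)
        acc = float(np.mean(pred == labels))
        if best is None or acc > best.objective:
            best = ThresholdResult(
                float(theta), True,
                tp=int(np.sum((pred == 1) & (labels == 1))), objective=acc,
            )
    return best


def majority_vote(votes: Sequence[int]) -> int:
    """1 iff at least half of the per-seizure calls are positive."""
    votes = np.asarray(list(votes), dtype=float)
    if votes.size == 0:
        raise ValueError("majority vote over an empty list")
    return int(votes.mean() >= 0.5)


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------


def build_electrode_features(
    entries: list[tuple[BandPowerTensor, np.ndarray]],
    log10: bool = False,
) -> ElectrodeFeatures:
    """Assemble electrode × seizure rows from ictal band-power tensors.

    ``entries`` pairs each seizure's BandPowerTensor with its labelled-SOZ
    boolean vector. Features are raw ictal band power per analysis window
    (optionally log10-transformed).
    """
    band_names = entries[0][0].band_names
    X: dict[str, list[np.ndarray]] = {b: [] for b in band_names}
    rows = []
    for bp, soz in entries:
        soz = np.asarray(soz, dtype=bool)
        if soz.shape != (bp.n_electrodes,):
            raise ValueError("label vector misaligned with electrodes")
        vals = np.log10(np.maximum(bp.values, 1e-12)) if log10 else bp.values
        for b, band in enumerate(band_names):
            X[band].append(vals[:, b, :])
        labels = bp.channel_labels or [f"ch{i:03d}" for i in range(bp.n_electrodes)]
        for e in range(bp.n_electrodes):
            rows.append(
                {
                    "patient_id": bp.patient_id,
                    "seizure_id": bp.seizure_id,
                    "electrode": labels[e],
                    "label": int(soz[e]),
                }
            )
    return ElectrodeFeatures(
        X={b: np.vstack(chunks) for b, chunks in X.items()},
        meta=pd.DataFrame(rows),
    )


def build_outcome_features(
    entries: list[tuple[BandPowerTensor, np.ndarray, int]],
) -> OutcomeFeatures:
    """Per-seizure decile-ratio feature rows for outcome prediction.

    ``entries`` are (ictal BandPowerTensor, labelled-SOZ vector, outcome).
    Each seizure contributes, per band, the 10 × W matrix of SOZ/non-SOZ
    normalized-decile ratios flattened to one row.
    """
    band_names = entries[0][0].band_names
    X: dict[str, list[np.ndarray]] = {b: [] for b in band_names}
    rows = []
    for bp, soz, outcome in entries:
        ratios = decile_ratio_features(decile_table(bp, soz))  # (bands, W, 10)
        for b, band in enumerate(band_names):
            X[band].append(ratios[b].ravel())
        rows.append(
            {
                "patient_id": bp.patient_id,
                "seizure_id": bp.seizure_id,
                "label": int(outcome),
            }
        )
    return OutcomeFeatures(
        X={b: np.vstack(chunks) for b, chunks in X.items()},
        meta=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def simple_rf_baseline(
    X: dict[str, np.ndarray], y: np.ndarray, cfg: SRFEConfig
) -> tuple[RandomForestClassifier, np.ndarray]:
    """Single forest on all bands' features concatenated; returns (model, OOF probs)."""
    Xc = np.hstack([X[b] for b in X])
    y = np.asarray(y, dtype=int)
    rf = train_band_rf(Xc, y, n_trees=cfg.n_trees, seed=cfg.rf_seed)
    cv = _internal_cv(y, cfg.internal_cv, cfg.rf_seed)
    ref = RandomForestClassifier(
        n_estimators=cfg.n_trees, random_state=cfg.rf_seed, n_jobs=1
    )
    oof = cross_val_predict(ref, Xc, y, cv=cv, method="predict_proba")[:, 1]
    return rf, oof


def averaged_rf_baseline(
    band_models: dict[str, RandomForestClassifier], X: dict[str, np.ndarray]
) -> np.ndarray:
    """Unweighted mean of the six per-band probabilities (no meta-learner)."""
    probs = np.column_stack(
        [band_models[b].predict_proba(X[b])[:, 1] for b in band_models]
    )
    return probs.mean(axis=1)


# ---------------------------------------------------------------------------
# leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------


def _audit_no_leakage(train_ids: set, test_ids: set) -> None:
    leaked = train_ids & test_ids
    if leaked:
        raise AssertionError(f"patient leakage across folds: {sorted(leaked)}")


def _tune(probs: np.ndarray, y: np.ndarray, cfg: SRFEConfig) -> ThresholdResult:
    if cfg.threshold_mode == "ppv":
        return tune_threshold_ppv(probs, y, cfg.ppv_min)
    return tune_threshold_accuracy(probs, y)


def lopo_cv(
    features: ElectrodeFeatures,
    cfg: SRFEConfig | None = None,
    model: str = "srfe",
) -> CVResult:
    """Leave-one-patient-out CV of the electrode classifier.

    model: "srfe" (stacked), "simple" (one pooled forest) or "averaged"
    (mean of per-band probabilities). Per-seizure binary calls are majority
    voted per (patient, electrode) to give the final labelling.
    """
    cfg = cfg or SRFEConfig.electrode()
    if model not in ("srfe", "simple", "averaged"):
        raise ValueError(f"unknown model {model!r}")
    meta = features.meta
    patients = list(dict.fromkeys(meta["patient_id"]))
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out CV needs >= 2 patients")
    rows = []
    fold_models: dict[str, object] = {}
    thresholds: dict[str, ThresholdResult] = {}
    for pid in patients:
        test_mask = (meta["patient_id"] == pid).to_numpy()
        if not test_mask.any():
            raise ValueError(f"patient {pid} has no rows")
        train = features.subset(~test_mask)
        test = features.subset(test_mask)
        _audit_no_leakage(
            set(train.meta["patient_id"]), set(test.meta["patient_id"])
        )
        y_train = train.meta["label"].to_numpy()
        if model == "srfe":
            fitted, _ = fit_srfe(train.X, y_train, cfg)
            tune = ThresholdResult(fitted.threshold, fitted.threshold_feasible)
            test_probs = srfe_probabilities(fitted, test.X)
        elif model == "simple":
            fitted, oof = simple_rf_baseline(train.X, y_train, cfg)
            tune = _tune(oof, y_train, cfg)
            Xc = np.hstack([test.X[b] for b in test.X])
            test_probs = fitted.predict_proba(Xc)[:, 1]
        else:  # averaged
            band_models = {
                b: train_band_rf(train.X[b], y_train, cfg.n_trees, cfg.rf_seed + i)
                for i, b in enumerate(train.X)
            }
            oof = np.column_stack(
                [oof_band_probabilities(train.X[b], y_train, cfg, i)
                 for i, b in enumerate(train.X)]
            ).mean(axis=1)
            tune = _tune(oof, y_train, cfg)
            fitted = band_models
            test_probs = averaged_rf_baseline(band_models, test.X)
        fold_models[pid] = fitted
        thresholds[pid] = tune
        out = test.meta.copy()
        out["prob"] = test_probs
        out["pred"] = (test_probs >= tune.theta).astype(int)
        out["fold"] = pid
        rows.append(out)
    rows_df = pd.concat(rows, ignore_index=True)
    voted = (
        rows_df.groupby(["patient_id", "electrode"], sort=False)
        .agg(label=("label", "max"), pred=("pred", lambda v: majority_vote(list(v))),
             prob=("prob", "mean"))
        .reset_index()
    )
    return CVResult(rows=rows_df, voted=voted, fold_models=fold_models,
                    thresholds=thresholds)


def outcome_lopo_cv(
    features: OutcomeFeatures, cfg: SRFEConfig | None = None
) -> CVResult:
    """Leave-one-patient-out CV of the outcome classifier (per-seizure rows).

    A training fold missing one outcome class is flagged and predicted with
    the training majority class rather than crashing the whole CV.
    """
    cfg = cfg or SRFEConfig.outcome()
    meta = features.meta
    patients = list(dict.fromkeys(meta["patient_id"]))
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out CV needs >= 2 patients")
    rows = []
    fold_models: dict[str, object] = {}
    thresholds: dict[str, ThresholdResult] = {}
    flagged: list[str] = []
    for pid in patients:
        test_mask = (meta["patient_id"] == pid).to_numpy()
        train = features.subset(~test_mask)
        test = features.subset(test_mask)
        _audit_no_leakage(set(train.meta["patient_id"]), set(test.meta["patient_id"]))
        y_train = train.meta["label"].to_numpy()
        if len(np.unique(y_train)) < 2:
            flagged.append(pid)
            maj = int(np.round(y_train.mean()))
            out = test.meta.copy()
            out["prob"] = float(y_train.mean())
            out["pred"] = maj
            out["fold"] = pid
            rows.append(out)
            continue
        fitted, _ = fit_srfe(train.X, y_train, cfg)
        tune = ThresholdResult(fitted.threshold, fitted.threshold_feasible)
        test_probs = srfe_probabilities(fitted, test.X)
        fold_models[pid] = fitted
        thresholds[pid] = tune
        out = test.meta.copy()
        out["prob"] = test_probs
        out["pred"] = (test_probs >= tune.theta).astype(int)
        out["fold"] = pid
        rows.append(out)
    rows_df = pd.concat(rows, ignore_index=True)
    voted = (
        rows_df.groupby("patient_id", sort=False)
        .agg(label=("label", "max"), pred=("pred", lambda v: majority_vote(list(v))),
             prob=("prob", "mean"))
        .reset_index()
    )
    return CVResult(rows=rows_df, voted=voted, fold_models=fold_models,
                    thresholds=thresholds, flagged_folds=flagged)
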