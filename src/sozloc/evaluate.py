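"""Confusion metrics, ROC AUC, and ensemble interpretability summaries.

Confusion metrics are computed with exact rational arithmetic; a metric with
a zero denominator is reported as undefined (None) rather than silently 0.
Percentages round to one decimal, half away from zero.

Interpretability exports: the meta-learner's per-band coefficients
(mean ± sd across cross-validation folds) rank how much each frequency band
contributes to the stacked decision, and each base forest's per-window
impurity-decrease importances (normalized to sum 1 within the band) show
*when* after onset that band is informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import BandPowerTensor
from .srfe import SRFEModel

__all__ = [
    "ConfusionMetrics",
    "ImportanceOverTime",
    "confusion_metrics",
    "roc_auc",
    "band_importance",
    "varimp_over_time",
    "heatmap_export",
    "round_pct",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None

    def as_dict(self) -> dict:
        return dict(
            tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn,
            accuracy=self.accuracy, ppv=self.ppv, npv=self.npv,
            sensitivity=self.sensitivity, specificity=self.specificity,
        )


def _ratio(num: int, den: int) -> float | None:
    return float(Fraction(num, den)) if den > 0 else None


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Accuracy, PPV, NPV, sensitivity and specificity from raw counts."""
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all counts are zero")
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=float(Fraction(tp + tn, total)),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
    )


def round_pct(fraction: float, ndigits: int = 1) -> float:
    """Fraction → percentage at fixed precision, rounding half away from zero."""
    q = Decimal(10) ** -ndigits
    d = Decimal(repr(fraction * 100)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_sign(Decimal(repr(fraction))))


def roc_auc(probs, labels) -> float:
    """Rank-based (Mann–Whitney) ROC area with midrank tie handling."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes")
    ranks = stats.rankdata(probs, method="average")
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ImportanceOverTime:
    """Per-band per-window forest importances, normalized to sum 1 per band."""

    matrix: np.ndarray  # (bands, W)
    band_names: tuple[str, ...]
    window_centers_s: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        centers = (
            self.window_centers_s
            if self.window_centers_s is not None
            else np.arange(self.matrix.shape[1], dtype=float)
        )
        rows = [
            (band, float(centers[w]), float(self.matrix[b, w]))
            for b, band in enumerate(self.band_names)
            for w in range(self.matrix.shape[1])
        ]
        return pd.DataFrame(rows, columns=["band", "window_center_s", "importance"])


def band_importance(fold_models: list[SRFEModel]) -> pd.DataFrame:
    """Meta-learner coefficient per band, mean ± sd across folds, ranked."""
    if not fold_models:
        raise ValueError("no fitted models supplied")
    band_names = fold_models[0].band_names
    coefs = np.array(
        [[m.meta_coefficients[b] for b in band_names] for m in fold_models]
    )
    frame = pd.DataFrame(
        {
            "band": band_names,
            "coef_mean": coefs.mean(axis=0),
            "coef_sd": coefs.std(axis=0, ddof=1) if len(fold_models) > 1
            else np.zeros(len(band_names)),
        }
    )
    return frame.sort_values("coef_mean", ascending=False, ignore_index=True)


def varimp_over_time(
    band_models: dict, window_centers_s: np.ndarray | None = None
) -> ImportanceOverTime:
    """Impurity-decrease importance per analysis window for each band's forest."""
    band_names = tuple(band_models)
    mats = []
    for b in band_names:
        imp = np.asarray(band_models[b].feature_importances_, dtype=float)
        s = imp.sum()
        mats.append(imp / s if s > 0 else np.full_like(imp, 1.0 / imp.size))
    return ImportanceOverTime(
        matrix=np.vstack(mats),
        band_names=band_names,
        window_centers_s=window_centers_s,
    )


def heatmap_export(
    bp: BandPowerTensor, soz, predicted
) -> pd.DataFrame:
    """Long-format power table with SOZ-labelled channels grouped last.

    Row order puts non-SOZ channels first and (labelled) SOZ channels at the
    bottom, matching the heatmap layout convention; predicted-SOZ channels
    carry a flag column. Power values pass through unchanged.
    """
    soz = np.asarray(soz, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if soz.shape != (bp.n_electrodes,) or predicted.shape != (bp.n_electrodes,):
        raise ValueError("label vectors misaligned with electrodes")
    labels = bp.channel_labels or [f"ch{i:03d}" for i in range(bp.n_electrodes)]
    order = np.argsort(soz, kind="stable")  # False (non-SOZ) first, SOZ last
    rows = []
    for pos, e in enumerate(order):
        for b, band in enumerate(bp.band_names):
            for w, c in enumerate(bp.window_centers_s):
                rows.append(
                    (
                        pos, labels[e], bool(soz[e]), bool(predicted[e]),
                        band, float(c), float(bp.values[e, b, w]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "row", "electrode", "soz", "predicted_soz",
            "band", "window_center_s", "power_uv2_per_hz",
        ],
    )
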