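"""Group statistics: SOZ vs non-SOZ power summaries, AUC contrasts, deciles.

For each seizure the electrodes are split into the labelled-SOZ and non-SOZ
populations. Per band the mean power time series and its SEM are computed
over each population; the area under the mean-power curve (trapezoidal
integral over the window-center grid, μV²/Hz·s) summarizes the early ictal
epoch in a single number per (seizure, group, band). AUC distributions are
contrasted across the four group pairs formed by surgical outcome
(seizure-free SF / not-seizure-free NSF) and electrode group, with Welch
two-sample t-tests Bonferroni-corrected for the 24 comparisons
(6 bands × 4 pairs).

Decile tables rank each population's electrode power into the 10th…100th
percentiles per (band, window); the outcome classifier consumes the ratio of
min–max normalized (to [1, 10]) SOZ over non-SOZ deciles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import BandPowerTensor

__all__ = [
    "GroupPowerSummary",
    "AUCRecord",
    "ComparisonResult",
    "DecileTable",
    "group_mean_sem",
    "auc_over_time",
    "auc_records_for_seizure",
    "compare_auc_groups",
    "welch_from_summary",
    "decile_table",
    "decile_ratio_features",
    "GROUP_PAIRS",
    "N_COMPARISONS",
]

DECILES = np.arange(10, 101, 10)

#: the four outcome × electrode-group contrasts
GROUP_PAIRS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("SF", "SOZ"), ("SF", "nonSOZ")),
    (("NSF", "SOZ"), ("NSF", "nonSOZ")),
    (("SF", "SOZ"), ("NSF", "SOZ")),
    (("SF", "nonSOZ"), ("NSF", "nonSOZ")),
)
N_COMPARISONS = 24  # 6 bands × 4 pairs


@dataclass
class GroupPowerSummary:
    """Mean ± SEM power over time for the SOZ and non-SOZ populations."""

    mean: dict[str, np.ndarray]  # group -> (bands, W)
    sem: dict[str, np.ndarray]
    n: dict[str, int]
    band_names: tuple[str, ...]
    window_centers_s: np.ndarray
    patient_id: str = ""
    seizure_id: str = ""


@dataclass(frozen=True)
class AUCRecord:
    seizure_id: str
    outcome_group: str  # "SF" | "NSF"
    electrode_group: str  # "SOZ" | "nonSOZ"
    band: str
    auc: float


@dataclass
class ComparisonResult:
    band: str
    pair: str
    t: float
    df: float
    p_raw: float
    p_adj: float
    n1: int
    n2: int
    degenerate: bool = False


@dataclass
class DecileTable:
    """10th…100th percentiles of electrode power per (band, group, window)."""

    deciles: dict[str, np.ndarray]  # group -> (bands, W, 10)
    band_names: tuple[str, ...]
    window_centers_s: np.ndarray
    patient_id: str = ""
    seizure_id: str = ""


def _split_groups(bp: BandPowerTensor, soz: np.ndarray) -> dict[str, np.ndarray]:
    soz = np.asarray(soz, dtype=bool)
    if soz.shape != (bp.n_electrodes,):
        raise ValueError("SOZ label vector must align with electrodes")
    groups = {"SOZ": bp.values[soz], "nonSOZ": bp.values[~soz]}
    for name, vals in groups.items():
        if vals.shape[0] == 0:
            raise ValueError(f"group {name} has no electrodes")
    return groups


def group_mean_sem(bp: BandPowerTensor, soz: np.ndarray) -> GroupPowerSummary:
    """Per-window arithmetic mean and SEM over each electrode population.

    SEM uses the sample standard deviation (ddof=1); a single-electrode group
    has SEM defined as 0.
    """
    groups = _split_groups(bp, soz)
    mean, sem, n = {}, {}, {}
    for g, vals in groups.items():
        n[g] = vals.shape[0]
        mean[g] = vals.mean(axis=0)
        if n[g] > 1:
            sem[g] = vals.std(axis=0, ddof=1) / math.sqrt(n[g])
        else:
            sem[g] = np.zeros_like(mean[g])
    return GroupPowerSummary(
        mean=mean,
        sem=sem,
        n=n,
        band_names=bp.band_names,
        window_centers_s=bp.window_centers_s,
        patient_id=bp.patient_id,
        seizure_id=bp.seizure_id,
    )


def auc_over_time(series: np.ndarray, centers: np.ndarray) -> float:
    """Trapezoidal area under a power time series (μV²/Hz·s)."""
    series = np.asarray(series, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if series.shape != centers.shape or series.size < 2:
        raise ValueError("need >= 2 aligned (value, time) points")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be strictly increasing")
    return float(np.trapezoid(series, centers))


def auc_records_for_seizure(
    bp: BandPowerTensor, soz: np.ndarray, seizure_free: bool
) -> list[AUCRecord]:
    """AUC of the group-mean power series, per band and electrode group."""
    summary = group_mean_sem(bp, soz)
    outcome = "SF" if seizure_free else "NSF"
    sid = f"{bp.patient_id}:{bp.seizure_id}"
    records = []
    for b, band in enumerate(summary.band_names):
        for g in ("SOZ", "nonSOZ"):
            records.append(
                AUCRecord(
                    seizure_id=sid,
                    outcome_group=outcome,
                    electrode_group=g,
                    band=band,
                    auc=auc_over_time(summary.mean[g][b], summary.window_centers_s),
                )
            )
    return records


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t-test from summary statistics → (t, df, p two-sided).

    Degenerate zero-variance inputs: equal means give (0, df, 1); unequal
    means give (±inf, df, 0).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        df = float(n1 + n2 - 2)
        if mean1 == mean2:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean1 - mean2), df, 0.0
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def compare_auc_groups(
    records: list[AUCRecord], m: int = N_COMPARISONS
) -> list[ComparisonResult]:
    """Welch t-tests over the 4 outcome × electrode-group pairs per band.

    Bonferroni correction uses m = 24 (6 bands × 4 pairs). Cells with fewer
    than 2 observations flag the contrast as degenerate rather than dropping
    it silently.
    """
    frame = pd.DataFrame([r.__dict__ for r in records])
    bands = list(dict.fromkeys(frame["band"]))
    results = []
    for band in bands:
        sub = frame[frame["band"] == band]
        for (o1, g1), (o2, g2) in GROUP_PAIRS:
            a = sub[(sub.outcome_group == o1) & (sub.electrode_group == g1)]["auc"]
            b = sub[(sub.outcome_group == o2) & (sub.electrode_group == g2)]["auc"]
            pair = f"{o1}-{g1} vs {o2}-{g2}"
            if len(a) < 2 or len(b) < 2:
                results.append(
                    ComparisonResult(
                        band=band, pair=pair, t=float("nan"), df=float("nan"),
                        p_raw=float("nan"), p_adj=float("nan"),
                        n1=len(a), n2=len(b), degenerate=True,
                    )
                )
                continue
            t, df, p = welch_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            results.append(
                ComparisonResult(
                    band=band, pair=pair, t=t, df=df, p_raw=p,
                    p_adj=min(1.0, m * p), n1=len(a), n2=len(b),
                )
            )
    return results


def decile_table(bp: BandPowerTensor, soz: np.ndarray) -> DecileTable:
    """Rank each population's electrode power into deciles 10…100.

    Percentiles use the linear-interpolation convention, so the 100th decile
    equals the group maximum.
    """
    groups = _split_groups(bp, soz)
    deciles = {
        g: np.moveaxis(
            np.percentile(vals, DECILES, axis=0, method="linear"), 0, -1
        )  # (bands, W, 10)
        for g, vals in groups.items()
    }
    return DecileTable(
        deciles=deciles,
        band_names=bp.band_names,
        window_centers_s=bp.window_centers_s,
        patient_id=bp.patient_id,
        seizure_id=bp.seizure_id,
    )


def _minmax_1_to_10(v: np.ndarray) -> np.ndarray:
    """Map the last axis to [1, 10]; a constant vector maps to all ones."""
    lo = v.min(axis=-1, keepdims=True)
    hi = v.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.ones_like(v)
    nz = np.broadcast_to(span > 0, v.shape)
    scaled = 1.0 + 9.0 * (v - lo) / np.where(span == 0, 1.0, span)
    out[nz] = scaled[nz]
    return out


def decile_ratio_features(dt: DecileTable) -> np.ndarray:
    """SOZ / non-SOZ ratio of min–max normalized deciles.

    Within each (band, group, window) the 10 decile values are mapped to
    [1, 10]; the feature is the elementwise SOZ/nonSOZ ratio, shape
    ``(bands, W, 10)`` with every entry in [0.1, 10].
    """
    soz = _minmax_1_to_10(dt.deciles["SOZ"])
    non = _minmax_1_to_10(dt.deciles["nonSOZ"])
    return soz / non
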