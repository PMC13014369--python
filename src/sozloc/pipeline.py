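"""End-to-end glue: synthetic cohort → preprocessing → band power → features.

These helpers wire the modules together for the CLI, the worked example and
the test suite; each stage remains individually usable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_stats import AUCRecord, auc_records_for_seizure
from .preprocess import epoch, preprocess_chain
from .recording import Recording
from .spectral import BandPowerTensor, SpectralConfig, compute_band_power
from .srfe import (
    ElectrodeFeatures,
    OutcomeFeatures,
    build_electrode_features,
    build_outcome_features,
)
from .synthetic import CohortLabels

__all__ = [
    "ictal_band_power",
    "cohort_band_power",
    "cohort_electrode_features",
    "cohort_outcome_features",
    "cohort_auc_records",
]


def ictal_band_power(
    rec: Recording,
    cfg: SpectralConfig | None = None,
    *,
    notch: bool = True,
    line_hz: float = 60.0,
    which: str = "ictal",
) -> BandPowerTensor:
    """Preprocess one recording and return band power for one epoch.

    Chain: notch (optional) → common average reference → epoch at the first
    annotated seizure onset → multitaper band power.
    """
    if not rec.events:
        raise ValueError("recording has no seizure onset events")
    pre = preprocess_chain(rec, notch=notch, line_hz=line_hz)
    pair = epoch(pre, rec.events[0][0])
    segment = pair.ictal if which == "ictal" else pair.baseline
    return compute_band_power(
        segment,
        rec.fs,
        cfg,
        channel_labels=rec.channel_labels,
        patient_id=rec.patient_id,
        seizure_id=rec.seizure_id,
        epoch=which,
    )


def cohort_band_power(
    recordings: list[Recording],
    cfg: SpectralConfig | None = None,
    **kw,
) -> list[tuple[BandPowerTensor, np.ndarray]]:
    """Ictal band power plus the labelled-SOZ vector for every recording."""
    return [(ictal_band_power(rec, cfg, **kw), rec.soz_label.copy())
            for rec in recordings]


def cohort_electrode_features(
    recordings: list[Recording],
    cfg: SpectralConfig | None = None,
    **kw,
) -> ElectrodeFeatures:
    return build_electrode_features(cohort_band_power(recordings, cfg, **kw))


def _outcome_map(labels: CohortLabels) -> dict[str, int]:
    return dict(zip(labels.patients["patient_id"], labels.patients["outcome"]))


def cohort_outcome_features(
    recordings: list[Recording],
    labels: CohortLabels,
    cfg: SpectralConfig | None = None,
    **kw,
) -> OutcomeFeatures:
    outcomes = _outcome_map(labels)
    entries = [
        (bp, soz, outcomes[bp.patient_id])
        for bp, soz in cohort_band_power(recordings, cfg, **kw)
    ]
    return build_outcome_features(entries)


def cohort_auc_records(
    recordings: list[Recording],
    labels: CohortLabels,
    cfg: SpectralConfig | None = None,
    **kw,
) -> list[AUCRecord]:
    """Per-seizure group-mean AUC records for the four-group contrasts."""
    outcomes = _outcome_map(labels)
    records: list[AUCRecord] = []
    for bp, soz in cohort_band_power(recordings, cfg, **kw):
        records.extend(
            auc_records_for_seizure(bp, soz, seizure_free=bool(outcomes[bp.patient_id]))
        )
    return records


def auc_records_to_frame(records: list[AUCRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
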