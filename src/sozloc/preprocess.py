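"""Preprocessing chain: artifact-channel removal, notch, CAR, epoching.

The fixed order is drop → notch → common average reference → epoch. The
common average reference (CAR) is computed after artifact channels are
removed so that artifacts do not contaminate the reference.

Epochs follow the analysis convention: the ictal epoch covers the first 20 s
after seizure onset and the baseline epoch the 10 s interval starting 30 s
before onset. Time→sample mapping is ``floor(t·fs)`` with half-open
``[start, end)`` windows, so epoch lengths are exact in samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "EpochPair",
    "drop_artifact_channels",
    "notch_filter",
    "common_average_reference",
    "epoch",
    "preprocess_chain",
    "ICTAL_DURATION_S",
    "BASELINE_DURATION_S",
    "BASELINE_OFFSET_S",
]

ICTAL_DURATION_S = 20.0
BASELINE_DURATION_S = 10.0
BASELINE_OFFSET_S = 30.0  # baseline starts this many seconds before onset


@dataclass
class EpochPair:
    """Ictal ([onset, onset+20 s)) and baseline ([onset−30, onset−20 s)) segments."""

    ictal: np.ndarray  # channels × samples
    baseline: np.ndarray
    fs: float
    patient_id: str = ""
    seizure_id: str = ""


def drop_artifact_channels(rec: Recording, bad: Iterable[str]) -> Recording:
    """Remove artifact channels by label; SOZ labels stay aligned.

    Unknown labels are an error: silently dropping them could mask a
    misaligned exclusion list and corrupt label/channel alignment.
    """
    bad = set(bad)
    unknown = bad - set(rec.channel_labels)
    if unknown:
        raise KeyError(f"unknown channel label(s): {sorted(unknown)}")
    keep = [i for i, name in enumerate(rec.channel_labels) if name not in bad]
    out = rec.copy()
    out.signal = rec.signal[keep]
    out.channel_labels = [rec.channel_labels[i] for i in keep]
    out.soz_label = rec.soz_label[keep]
    return out


def notch_filter(
    rec: Recording,
    line_hz: float = 60.0,
    n_harmonics: int = 3,
    bw_hz: float = 2.0,
) -> Recording:
    """Zero-phase IIR band-stop at the mains frequency and its harmonics.

    Each notch is a second-order IIR notch applied forward-backward
    (``filtfilt``), which doubles the stop-band attenuation and preserves
    onset timing (no group delay).
    """
    nyquist = rec.fs / 2.0
    freqs = [line_hz * (k + 1) for k in range(n_harmonics)]
    if any(f >= nyquist for f in freqs):
        raise ValueError(
            f"notch frequency {max(freqs):g} Hz is at or above Nyquist ({nyquist:g} Hz)"
        )
    out = rec.copy()
    x = out.signal
    for f0 in freqs:
        b, a = sps.iirnotch(w0=f0, Q=f0 / bw_hz, fs=rec.fs)
        x = sps.filtfilt(b, a, x, axis=1)
    out.signal = x
    return out


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    out = rec.copy()
    out.signal = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return out


def epoch(rec: Recording, onset_s: float) -> EpochPair:
    """Cut the ictal and baseline epochs around one seizure onset."""
    if onset_s < BASELINE_OFFSET_S:
        raise ValueError(
            f"onset at {onset_s:g} s: need >= {BASELINE_OFFSET_S:g} s of "
            "pre-onset data for the baseline epoch"
        )
    if onset_s + ICTAL_DURATION_S > rec.duration_s:
        raise ValueError(
            f"onset at {onset_s:g} s: need >= {ICTAL_DURATION_S:g} s of "
            "post-onset data for the ictal epoch"
        )
    fs = rec.fs
    i0 = int(np.floor(onset_s * fs))
    ictal = rec.signal[:, i0 : i0 + int(round(ICTAL_DURATION_S * fs))]
    b0 = int(np.floor((onset_s - BASELINE_OFFSET_S) * fs))
    baseline = rec.signal[:, b0 : b0 + int(round(BASELINE_DURATION_S * fs))]
    return EpochPair(
        ictal=ictal,
        baseline=baseline,
        fs=fs,
        patient_id=rec.patient_id,
        seizure_id=rec.seizure_id,
    )


def preprocess_chain(
    rec: Recording,
    bad: Iterable[str] = (),
    line_hz: float = 60.0,
    n_harmonics: int = 3,
    bw_hz: float = 2.0,
    notch: bool = True,
) -> Recording:
    """Apply drop → notch → CAR in the fixed order."""
    out = drop_artifact_channels(rec, bad)
    if notch:
        out = notch_filter(out, line_hz=line_hz, n_harmonics=n_harmonics, bw_hz=bw_hz)
    return common_average_reference(out)
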