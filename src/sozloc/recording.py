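"""In-memory container and on-disk dialect for multichannel iEEG recordings.

A :class:`Recording` holds a channels × samples signal matrix in microvolts,
its sampling rate, channel names, a per-channel SOZ (seizure onset zone)
label, and seizure onset/offset events in seconds.

On disk a recording is a plain numeric matrix (binary float32 or a
tab-separated text matrix), a JSON sidecar with the sampling rate, channel
labels and units, and a BIDS-style ``*_events.tsv`` with columns
``onset``/``duration``/``trial_type`` (seizure onsets use trial_type
``sz_onset``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Recording", "write_recording", "read_recording"]

#: minimum pre-onset context (s) required for a baseline epoch
PRE_ONSET_MARGIN_S = 30.0
#: minimum post-onset context (s) required for an ictal epoch
POST_ONSET_MARGIN_S = 20.0


@dataclass
class Recording:
    """Multichannel iEEG recording.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One name per channel.
    soz_label
        Boolean per channel; True marks a (labelled) SOZ channel.
    events
        List of ``(onset_s, offset_s)`` seizure annotations, seconds from
        record start.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    soz_label: np.ndarray
    events: list[tuple[float, float]] = field(default_factory=list)
    patient_id: str = ""
    seizure_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels × samples array")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        self.soz_label = np.asarray(self.soz_label, dtype=bool)
        n = self.signal.shape[0]
        if len(self.channel_labels) != n or self.soz_label.shape != (n,):
            raise ValueError(
                "channel_labels and soz_label must match the channel count"
            )
        self.events = [(float(a), float(b)) for a, b in self.events]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate_event_margins(self) -> None:
        """Check every onset leaves room for a full baseline and ictal epoch."""
        for onset, _ in self.events:
            if onset < PRE_ONSET_MARGIN_S:
                raise ValueError(
                    f"onset at {onset:g} s leaves less than "
                    f"{PRE_ONSET_MARGIN_S:g} s of pre-onset baseline"
                )
            if onset + POST_ONSET_MARGIN_S > self.duration_s:
                raise ValueError(
                    f"onset at {onset:g} s leaves less than "
                    f"{POST_ONSET_MARGIN_S:g} s of post-onset data"
                )

    def copy(self) -> "Recording":
        return replace(
            self,
            signal=self.signal.copy(),
            channel_labels=list(self.channel_labels),
            soz_label=self.soz_label.copy(),
            events=list(self.events),
        )


def _stem(rec: Recording) -> str:
    pid = rec.patient_id or "rec"
    sid = rec.seizure_id or "01"
    return f"{pid}_{sid}"


def write_recording(rec: Recording, outdir: str | Path, fmt: str = "binary") -> Path:
    """Write a recording in the plain dialect.

    ``fmt='binary'`` stores the matrix as little-endian float32 (row-major,
    channels × samples); ``fmt='text'`` stores a TSV matrix. Events go to a
    BIDS-style events.tsv. Returns the sidecar path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = _stem(rec)
    if fmt == "binary":
        data_path = outdir / f"{stem}_ieeg.dat"
        rec.signal.astype("<f4").tofile(data_path)
    elif fmt == "text":
        data_path = outdir / f"{stem}_ieeg.tsv"
        np.savetxt(data_path, rec.signal, delimiter="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "units": "uV",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "format": fmt,
        "data_file": data_path.name,
        "patient_id": rec.patient_id,
        "seizure_id": rec.seizure_id,
        "soz_label": [int(x) for x in rec.soz_label],
    }
    sidecar_path = outdir / f"{stem}_ieeg.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    events = pd.DataFrame(
        {
            "onset": [a for a, _ in rec.events],
            "duration": [b - a for a, b in rec.events],
            "trial_type": ["sz_onset"] * len(rec.events),
        }
    )
    events.to_csv(outdir / f"{stem}_events.tsv", sep="\t", index=False)
    return sidecar_path


def read_recording(sidecar_path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    data_path = sidecar_path.parent / meta["data_file"]
    shape = (meta["n_channels"], meta["n_samples"])
    if meta["format"] == "binary":
        signal = np.fromfile(data_path, dtype="<f4").reshape(shape).astype(float)
    else:
        signal = np.loadtxt(data_path, delimiter="\t").reshape(shape)
    events_path = sidecar_path.parent / sidecar_path.name.replace(
        "_ieeg.json", "_events.tsv"
    )
    events: list[tuple[float, float]] = []
    if events_path.exists():
        ev = pd.read_csv(events_path, sep="\t")
        ev = ev[ev["trial_type"] == "sz_onset"]
        events = [
            (float(o), float(o) + float(d))
            for o, d in zip(ev["onset"], ev["duration"])
        ]
    return Recording(
        signal=signal,
        fs=float(meta["fs"]),
        channel_labels=meta["channel_labels"],
        soz_label=np.asarray(meta["soz_label"], dtype=bool),
        events=events,
        patient_id=meta.get("patient_id", ""),
        seizure_id=meta.get("seizure_id", ""),
    )
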