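"""Synthetic iEEG cohorts with known seizure-onset-zone ground truth.

Background activity is 1/f^beta Gaussian noise (synthesized in the frequency
domain) plus an optional mains-line sinusoid. Onset morphologies follow the
eight-class taxonomy of intracranial seizure-onset patterns:

=====  ==================================================  ==================
class  morphology                                          carrier bands
=====  ==================================================  ==================
A      low-voltage fast activity (LVFA): 30–150 Hz chirp,  gamma, high_gamma
       low initial voltage, growing amplitude
B      preictal transient spikes, then LVFA                gamma, high_gamma
C      polyspike bursts, then LVFA                         gamma, high_gamma
D      high-amplitude slow wave, then LVFA                 delta, gamma,
                                                           high_gamma
E      rhythmic 1–2 Hz spike train                         delta, theta
F      rhythmic sharp 4–13 Hz activity                     theta, alpha
G      rhythmic sharp 13–30 Hz activity                    beta
H      1–4 Hz slow wave with superimposed 90–150 Hz brush  delta, high_gamma
=====  ==================================================  ==================

Templates are additive amplitude-modulated waveforms, not neural-mass
simulations: downstream analysis consumes band power only, so what matters is
where each class puts its spectral energy relative to the 1/f background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Recording, write_recording

__all__ = [
    "PatternSpec",
    "CohortConfig",
    "CohortLabels",
    "generate_background",
    "inject_onset_pattern",
    "generate_cohort",
    "write_cohort",
    "PATTERN_CLASSES",
    "CARRIER_BANDS",
]

PATTERN_CLASSES = ("A", "B", "C", "D", "E", "F", "G", "H")

#: bands each onset class energizes (names match the spectral module's bands)
CARRIER_BANDS: dict[str, frozenset[str]] = {
    "A": frozenset({"gamma", "high_gamma"}),
    "B": frozenset({"gamma", "high_gamma"}),
    "C": frozenset({"gamma", "high_gamma"}),
    "D": frozenset({"delta", "gamma", "high_gamma"}),
    "E": frozenset({"delta", "theta"}),
    "F": frozenset({"theta", "alpha"}),
    "G": frozenset({"beta"}),
    "H": frozenset({"delta", "high_gamma"}),
}


@dataclass(frozen=True)
class PatternSpec:
    """One seizure-onset morphology placed at a known time.

    amplitude_gain scales the template to ``gain × `` the per-channel
    background RMS; gain 0 is an exact no-op.
    """

    pattern_class: str = "A"
    onset_s: float = 60.0
    duration_s: float = 20.0
    amplitude_gain: float = 5.0
    carrier_bands: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.pattern_class not in PATTERN_CLASSES:
            raise ValueError(
                f"unknown pattern class {self.pattern_class!r}; "
                f"expected one of {PATTERN_CLASSES}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.amplitude_gain < 0:
            raise ValueError("amplitude_gain must be non-negative")
        if not self.carrier_bands:
            object.__setattr__(
                self, "carrier_bands", CARRIER_BANDS[self.pattern_class]
            )


@dataclass
class CohortConfig:
    """Stated world for a synthetic cohort.

    Defaults: 8 patients × 40 channels (4 true SOZ) × 2 seizures at 500 Hz,
    records 60 s pre-onset + 30 s post-onset, onset-class A (LVFA) at gain 5,
    no label noise. ``label_noise`` is the fraction of true-SOZ channels whose
    label is swapped onto a background channel; it may be a scalar or one
    value per patient. A patient is seizure-free iff the labelled SOZ covers
    the true SOZ (``outcome_rule``).
    """

    n_patients: int = 8
    channels_per_patient: int = 40
    soz_channels_per_patient: int = 4
    seizures_per_patient: int = 2
    fs: float = 500.0
    pattern_assignment: dict[int, PatternSpec] | None = None
    label_noise: float | Sequence[float] = 0.0
    outcome_rule: bool = True
    seed: int = 0
    pre_onset_s: float = 60.0
    post_onset_s: float = 30.0
    target_rms_uv: float = 50.0
    line_hz: float = 60.0
    line_amp_uv: float = 5.0
    background_beta: float = 1.0

    def __post_init__(self) -> None:
        if self.fs < 500:
            raise ValueError("fs must be >= 500 Hz")
        if self.soz_channels_per_patient >= self.channels_per_patient:
            raise ValueError("soz_channels_per_patient must be < channels_per_patient")
        noise = np.atleast_1d(np.asarray(self.label_noise, dtype=float))
        if noise.size == 1:
            noise = np.repeat(noise, self.n_patients)
        if noise.size != self.n_patients:
            raise ValueError("label_noise must be scalar or one value per patient")
        if np.any((noise < 0) | (noise > 1)):
            raise ValueError("label_noise must lie in [0, 1]")
        self._noise_per_patient = noise

    def pattern_for(self, patient_index: int) -> PatternSpec:
        if self.pattern_assignment and patient_index in self.pattern_assignment:
            return self.pattern_assignment[patient_index]
        cls = PATTERN_CLASSES[patient_index % len(PATTERN_CLASSES)]
        return PatternSpec(
            pattern_class=cls,
            onset_s=self.pre_onset_s,
            duration_s=20.0,
            amplitude_gain=5.0,
        )


@dataclass
class CohortLabels:
    """Ground-truth and labelled channel/outcome tables for one cohort."""

    channels: pd.DataFrame  # patient_id, name, soz (labelled), true_soz
    patients: pd.DataFrame  # patient_id, outcome (1 = seizure-free)


def generate_background(
    n_channels: int,
    duration_s: float,
    fs: float,
    seed: int,
    *,
    beta: float = 1.0,
    line_hz: float = 60.0,
    line_amp_uv: float = 5.0,
    target_rms_uv: float = 50.0,
) -> Recording:
    """Independent 1/f^beta Gaussian channels plus a mains-line sinusoid.

    Each channel is normalized to exactly ``target_rms_uv`` before the line
    component is added, so the realized RMS stays within the ±20% contract
    for any line amplitude below ~60% of the target.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 s")
    if fs < 500:
        raise ValueError("fs must be >= 500 Hz")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-beta / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    x = x * (target_rms_uv / rms)
    if line_amp_uv > 0:
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
        x = x + line_amp_uv * np.sin(2 * np.pi * line_hz * t + phases)
    labels = [f"ch{i:03d}" for i in range(n_channels)]
    return Recording(
        signal=x,
        fs=fs,
        channel_labels=labels,
        soz_label=np.zeros(n_channels, dtype=bool),
        events=[],
    )


def _ramp_envelope(n: int, frac: float = 0.05) -> np.ndarray:
    """Linear on/off ramps over a fraction of the window (avoids edge clicks)."""
    env = np.ones(n)
    k = max(1, int(n * frac))
    env[:k] = np.linspace(0, 1, k)
    env[-k:] = np.linspace(1, 0, k)
    return env


def _spike_waveform(fs: float, width_s: float = 0.06) -> np.ndarray:
    """Biphasic sharp transient (derivative-of-Gaussian shape)."""
    m = max(3, int(round(width_s * fs)))
    t = np.linspace(-3, 3, m)
    w = -t * np.exp(-(t**2) / 2.0)
    return w / np.max(np.abs(w))


def _spike_train(
    n: int,
    fs: float,
    rate_hz: float,
    rng: np.random.Generator,
    width_s: float = 0.06,
) -> np.ndarray:
    out = np.zeros(n)
    w = _spike_waveform(fs, width_s)
    period = int(round(fs / rate_hz))
    jitter = max(1, period // 10)
    pos = 0
    while pos + len(w) < n:
        out[pos : pos + len(w)] += w
        pos += period + int(rng.integers(-jitter, jitter + 1))
    return out


def _lvfa(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Low-voltage fast activity: 30–150 Hz chirp with growing amplitude."""
    dur = t[-1] if len(t) > 1 else 1.0
    f0, f1 = 110.0, 45.0  # downward chirp through the gamma range
    phase = rng.uniform(0, 2 * np.pi)
    carrier = sps.chirp(t, f0=f0, f1=f1, t1=dur, method="linear", phi=np.degrees(phase))
    env = 0.15 + 0.85 * (t / dur)  # low initial voltage, growing amplitude
    return env * carrier


def _pattern_template(
    cls: str, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS template of `n` samples for one onset class."""
    t = np.arange(n) / fs
    dur = n / fs
    if cls == "A":
        x = _lvfa(t, rng)
    elif cls == "B":
        # sparse preictal spikes over the first 15%, then LVFA
        n0 = int(0.15 * n)
        x = np.zeros(n)
        x[:n0] = 1.5 * _spike_train(n0, fs, rate_hz=1.0, rng=rng)
        x[n0:] = _lvfa(t[: n - n0], rng)
    elif cls == "C":
        # polyspike bursts (runs of fast spikes) over the first 25%, then LVFA
        n0 = int(0.25 * n)
        burst = np.zeros(n0)
        w = _spike_waveform(fs, width_s=0.02)
        burst_period = int(0.5 * fs)
        pos = 0
        while pos + 5 * len(w) < n0:
            for k in range(5):
                start = pos + k * int(0.02 * fs)
                burst[start : start + len(w)] += w[: max(0, min(len(w), n0 - start))]
            pos += burst_period
        x = np.zeros(n)
        x[:n0] = 1.5 * burst
        x[n0:] = _lvfa(t[: n - n0], rng)
    elif cls == "D":
        # single high-amplitude slow wave (~1 Hz half cycle), then LVFA
        n0 = min(n, int(1.0 * fs))
        x = np.zeros(n)
        x[:n0] = 3.0 * np.sin(np.pi * np.arange(n0) / n0)
        x[n0:] = _lvfa(t[: n - n0], rng)
    elif cls == "E":
        # broad (150 ms) sharp waves: harmonics stay below the gamma band
        x = _spike_train(n, fs, rate_hz=1.5, rng=rng, width_s=0.15)
        x += 0.8 * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi))
    elif cls == "F":
        # sharp (harmonic-rich) theta/alpha rhythm
        x = sps.sawtooth(2 * np.pi * 6.0 * t + rng.uniform(0, 2 * np.pi), width=0.2)
    elif cls == "G":
        x = sps.sawtooth(2 * np.pi * 18.0 * t + rng.uniform(0, 2 * np.pi), width=0.2)
    elif cls == "H":
        # delta-brush: slow wave with high-gamma "brush" riding its crests
        slow = np.sin(2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi))
        brush_env = np.clip(slow, 0, None)
        brush = brush_env * np.sin(2 * np.pi * 120.0 * t + rng.uniform(0, 2 * np.pi))
        x = slow + 0.9 * brush
    else:  # pragma: no cover - guarded by PatternSpec
        raise ValueError(f"unknown pattern class {cls!r}")
    x = x * _ramp_envelope(n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise RuntimeError(f"degenerate template for class {cls} (dur {dur:g} s)")
    return x / rms


def inject_onset_pattern(
    rec: Recording,
    channels: Sequence[int],
    spec: PatternSpec,
    seed: int = 0,
) -> Recording:
    """Additively place one onset morphology on the listed channels.

    All other channels are bit-identical to the input. The template is scaled
    to ``amplitude_gain ×`` each target channel's pre-injection RMS; gain 0
    returns an unmodified copy.
    """
    channels = np.asarray(channels, dtype=int)
    if channels.size and (channels.min() < 0 or channels.max() >= rec.n_channels):
        raise IndexError("channel index out of range")
    start = int(np.floor(spec.onset_s * rec.fs))
    n = int(round(spec.duration_s * rec.fs))
    if start < 0 or start + n > rec.n_samples:
        raise ValueError("pattern window extends outside the record")
    out = rec.copy()
    if spec.amplitude_gain == 0 or channels.size == 0:
        return out
    rng = np.random.default_rng(seed)
    for ch in channels:
        template = _pattern_template(spec.pattern_class, n, rec.fs, rng)
        ch_rms = np.sqrt(np.mean(rec.signal[ch] ** 2))
        out.signal[ch, start : start + n] += (
            spec.amplitude_gain * ch_rms * template
        )
    return out


def generate_cohort(cfg: CohortConfig) -> tuple[list[Recording], CohortLabels]:
    """Simulate a patient cohort with ground-truth SOZ channels.

    Per patient: a constant true-SOZ channel set carries that patient's onset
    pattern in every seizure; every other channel is background only.
    Labelled SOZ is the true set with ``label_noise`` of its channels swapped
    onto background channels. Outcome is seizure-free iff labelled ⊇ true.
    """
    root = np.random.SeedSequence(cfg.seed)
    patient_seeds = root.spawn(cfg.n_patients)
    recordings: list[Recording] = []
    chan_rows = []
    patient_rows = []
    duration_s = cfg.pre_onset_s + cfg.post_onset_s
    n_ch = cfg.channels_per_patient
    n_soz = cfg.soz_channels_per_patient
    for p in range(cfg.n_patients):
        pid = f"sub{p:02d}"
        pss = patient_seeds[p]
        p_rng = np.random.default_rng(pss)
        true_soz = np.sort(p_rng.choice(n_ch, size=n_soz, replace=False))
        # mislabelling = swap: move a true-SOZ label onto a background channel
        noise = cfg._noise_per_patient[p]
        n_swap = int(round(noise * n_soz))
        labelled = set(true_soz.tolist())
        background = [c for c in range(n_ch) if c not in labelled]
        swap_out = p_rng.choice(true_soz, size=n_swap, replace=False)
        swap_in = p_rng.choice(background, size=n_swap, replace=False)
        for o, i in zip(swap_out, swap_in):
            labelled.discard(int(o))
            labelled.add(int(i))
        labelled_arr = np.zeros(n_ch, dtype=bool)
        labelled_arr[sorted(labelled)] = True
        spec = cfg.pattern_for(p)
        outcome = int(labelled.issuperset(true_soz.tolist())) if cfg.outcome_rule else 1
        patient_rows.append({"patient_id": pid, "outcome": outcome,
                             "pattern_class": spec.pattern_class})
        for c in range(n_ch):
            chan_rows.append(
                {
                    "patient_id": pid,
                    "name": f"ch{c:03d}",
                    "soz": int(labelled_arr[c]),
                    "true_soz": int(c in true_soz),
                }
            )
        seizure_seeds = pss.spawn(cfg.seizures_per_patient)
        for s in range(cfg.seizures_per_patient):
            s_rng_seed = int(seizure_seeds[s].generate_state(1)[0] % (2**31))
            rec = generate_background(
                n_ch,
                duration_s,
                cfg.fs,
                seed=s_rng_seed,
                beta=cfg.background_beta,
                line_hz=cfg.line_hz,
                line_amp_uv=cfg.line_amp_uv,
                target_rms_uv=cfg.target_rms_uv,
            )
            rec.events = [(cfg.pre_onset_s, cfg.pre_onset_s + spec.duration_s)]
            rec.soz_label = labelled_arr.copy()
            rec.patient_id = pid
            rec.seizure_id = f"sz{s:02d}"
            rec = inject_onset_pattern(rec, true_soz, spec, seed=s_rng_seed + 1)
            rec.validate_event_margins()
            recordings.append(rec)
    labels = CohortLabels(
        channels=pd.DataFrame(chan_rows),
        patients=pd.DataFrame(patient_rows),
    )
    return recordings, labels


def write_cohort(
    recordings: list[Recording],
    labels: CohortLabels,
    outdir: str | Path,
    fmt: str = "binary",
) -> Path:
    """Write all recordings plus channels.tsv / patients.tsv label tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, outdir, fmt=fmt)
    labels.channels.to_csv(outdir / "channels.tsv", sep="\t", index=False)
    labels.patients.to_csv(outdir / "patients.tsv", sep="\t", index=False)
    return outdir
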