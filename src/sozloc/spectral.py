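"""Sliding-window multitaper power spectral density and band aggregation.

Power is estimated per 2.5 s window advanced in 0.5 s steps, as the
unweighted average of K discrete-prolate-spheroidal-sequence (DPSS) tapered
periodograms. The estimate is a one-sided density in μV²/Hz scaled so that
its integral over frequency approximates the windowed signal variance.
Window means are removed before tapering, so the estimate measures variance
about the local mean (the DC bin is near zero and no band starts below
0.5 Hz).

Band power is the simple mean of the PSD bins falling in each band. Bands
are half-open ``[lo, hi)`` intervals so the canonical six bands partition
0.5–150 Hz without double counting the shared edges:

    delta [0.5, 4), theta [4, 8), alpha [8, 13), beta [13, 30),
    gamma [30, 90), high_gamma [90, 150) Hz.

The first window starts at the epoch start and windows needing data past the
epoch end are not produced, giving W = floor((T − window)/step) + 1 windows:
36 for the 20 s ictal epoch and 16 for the 10 s baseline at the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows as spwin

__all__ = [
    "DEFAULT_BANDS",
    "BAND_NAMES",
    "SpectralConfig",
    "BandPowerTensor",
    "multitaper_psd",
    "band_power",
    "compute_band_power",
    "band_power_to_frame",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 90.0),
    "high_gamma": (90.0, 150.0),
}
BAND_NAMES = tuple(DEFAULT_BANDS)


@dataclass(frozen=True)
class SpectralConfig:
    """Multitaper parameters.

    window_s / step_s: sliding-window geometry (s). time_bandwidth: DPSS NW.
    n_tapers: K, must satisfy K <= 2·NW − 1. bands: ordered name → (lo, hi).
    """

    window_s: float = 2.5
    step_s: float = 0.5
    time_bandwidth: float = 3.0
    n_tapers: int = 5
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if not (self.window_s > self.step_s > 0):
            raise ValueError("require window_s > step_s > 0")
        if self.n_tapers < 1 or self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("require 1 <= n_tapers <= 2*NW - 1")
        prev_hi = 0.0
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {name}: require 0 < lo < hi")
            if lo < prev_hi:
                raise ValueError(f"band {name} overlaps the previous band")
            prev_hi = hi


@dataclass
class BandPowerTensor:
    """electrodes × bands × windows mean PSD (μV²/Hz)."""

    values: np.ndarray
    window_centers_s: np.ndarray
    band_names: tuple[str, ...]
    channel_labels: list[str] = field(default_factory=list)
    patient_id: str = ""
    seizure_id: str = ""
    epoch: str = ""

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]


def _window_starts(n_samples: int, n_win: int, n_step: int) -> np.ndarray:
    if n_samples < n_win:
        raise ValueError(
            f"segment ({n_samples} samples) shorter than one window ({n_win})"
        )
    n_windows = (n_samples - n_win) // n_step + 1
    return np.arange(n_windows) * n_step


def multitaper_psd(
    segment: np.ndarray, fs: float, cfg: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper PSD.

    Parameters
    ----------
    segment
        ``(channels, samples)`` array (a 1-D array is treated as one channel).
    fs
        Sampling rate, Hz.
    cfg
        Spectral parameters; defaults to :class:`SpectralConfig`.

    Returns
    -------
    psd : ``(channels, n_freq, n_windows)`` one-sided density, μV²/Hz
    freqs : frequency grid, Hz
    centers : window-center times relative to segment start, s
    """
    cfg = cfg or SpectralConfig()
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n_win = int(round(cfg.window_s * fs))
    n_step = int(round(cfg.step_s * fs))
    starts = _window_starts(segment.shape[1], n_win, n_step)
    tapers = spwin.dpss(n_win, cfg.time_bandwidth, Kmax=cfg.n_tapers)  # (K, n_win)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    # (channels, W, n_win) view of all windows
    wins = np.lib.stride_tricks.sliding_window_view(segment, n_win, axis=1)[
        :, starts, :
    ]
    wins = wins - wins.mean(axis=-1, keepdims=True)
    # taper → (channels, W, K, n_win), FFT over samples
    tapered = wins[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    pk = (spec.real**2 + spec.imag**2) / fs
    # one-sided density: double everything except DC and (for even n) Nyquist
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if n_win % 2 == 0:
        scale[-1] = 1.0
    psd = pk.mean(axis=2) * scale  # unweighted mean over tapers
    psd = np.moveaxis(psd, 1, 2)  # (channels, n_freq, W)
    centers = (starts + n_win / 2.0) / fs
    return psd, freqs, centers


def band_power(
    psd: np.ndarray,
    freqs: np.ndarray,
    cfg: SpectralConfig | None = None,
    *,
    window_centers_s: np.ndarray | None = None,
    channel_labels: list[str] | None = None,
    patient_id: str = "",
    seizure_id: str = "",
    epoch: str = "",
) -> BandPowerTensor:
    """Aggregate a PSD array into per-band mean power (half-open bins)."""
    cfg = cfg or SpectralConfig()
    nyq = freqs[-1]
    values = np.empty((psd.shape[0], len(cfg.bands), psd.shape[2]))
    for b, (name, (lo, hi)) in enumerate(cfg.bands.items()):
        if hi > nyq + 1e-9:
            raise ValueError(
                f"band {name} upper edge {hi:g} Hz exceeds the frequency grid "
                f"(max {nyq:g} Hz)"
            )
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(f"band {name} contains no frequency bins")
        values[:, b, :] = psd[:, mask, :].mean(axis=1)
    if window_centers_s is None:
        window_centers_s = np.arange(psd.shape[2], dtype=float)
    return BandPowerTensor(
        values=values,
        window_centers_s=np.asarray(window_centers_s, dtype=float),
        band_names=tuple(cfg.bands),
        channel_labels=list(channel_labels or []),
        patient_id=patient_id,
        seizure_id=seizure_id,
        epoch=epoch,
    )


def compute_band_power(
    segment: np.ndarray,
    fs: float,
    cfg: SpectralConfig | None = None,
    **meta,
) -> BandPowerTensor:
    """multitaper_psd followed by band aggregation in one call."""
    cfg = cfg or SpectralConfig()
    psd, freqs, centers = multitaper_psd(segment, fs, cfg)
    return band_power(psd, freqs, cfg, window_centers_s=centers, **meta)


def band_power_to_frame(bp: BandPowerTensor) -> pd.DataFrame:
    """Long-format export: one row per (electrode, band, window)."""
    labels = bp.channel_labels or [f"ch{i:03d}" for i in range(bp.n_electrodes)]
    rows = []
    for e, name in enumerate(labels):
        for b, band in enumerate(bp.band_names):
            for w, c in enumerate(bp.window_centers_s):
                rows.append(
                    (name, band, c, bp.values[e, b, w],
                     bp.patient_id, bp.seizure_id, bp.epoch)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "electrode", "band", "window_center_s", "power_uv2_per_hz",
            "patient_id", "seizure_id", "epoch",
        ],
    )
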