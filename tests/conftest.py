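import numpy as np
import pytest

from sozloc.spectral import BAND_NAMES, BandPowerTensor
from sozloc.synthetic import CohortConfig, PatternSpec, generate_background, generate_cohort


@pytest.fixture(scope="session")
def background_60s():
    """Shared 60 s, 4-channel 1/f background at 500 Hz."""
    return generate_background(4, 60, 500, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Small class-A cohort: 4 patients x 12 channels (2 SOZ) x 2 seizures."""
    spec = PatternSpec(pattern_class="A", onset_s=60, duration_s=20, amplitude_gain=5)
    cfg = CohortConfig(
        n_patients=4,
        channels_per_patient=12,
        soz_channels_per_patient=2,
        seizures_per_patient=2,
        fs=500,
        pattern_assignment={p: spec for p in range(4)},
        label_noise=0.0,
        seed=123,
    )
    return generate_cohort(cfg)


def make_band_power(values, centers=None, **meta) -> BandPowerTensor:
    """BandPowerTensor from a raw (electrodes, 6, W) array."""
    values = np.asarray(values, dtype=float)
    if centers is None:
        centers = 1.25 + 0.5 * np.arange(values.shape[2])
    return BandPowerTensor(
        values=values,
        window_centers_s=np.asarray(centers, dtype=float),
        band_names=BAND_NAMES,
        **meta,
    )
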