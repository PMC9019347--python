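import numpy as np
import pytest

from boomloc import BoomSpec, SceneConfig, make_circular_array


@pytest.fixture
def boom_spec():
    return BoomSpec()


@pytest.fixture
def scene():
    return SceneConfig()


@pytest.fixture
def array_10cm():
    return make_circular_array(0.1, 8)


@pytest.fixture
def das_oracle():
    """The independent delay-and-sum argmax oracle as a callable."""
    return das_argmax


def das_argmax(sig, geom, scene, band_hz, grid_step_deg=5.0):
    """Independent delay-and-sum beamformer oracle.

    Aligns channels in the frequency domain by advancing each by its
    hypothesized propagation delay (and undoing 1/d spreading), sums,
    and returns the azimuth of maximum band-limited output power.  Kept
    free of the package's STFT/covariance/MUSIC code path.
    """
    fs = sig.sample_rate
    c = scene.speed_of_sound
    x = sig.channels
    nfft = int(2 ** np.ceil(np.log2(x.shape[1])))
    X = np.fft.rfft(x, n=nfft)
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    mask = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    grid = np.arange(0.0, 360.0, grid_step_deg)
    powers = []
    for az_deg in grid:
        az = np.deg2rad(az_deg)
        src = scene.source_distance * np.array([np.cos(az), np.sin(az)])
        d = np.linalg.norm(geom.xy - src[None, :], axis=1)
        align = np.exp(2j * np.pi * freqs[mask][None, :] * (d / c)[:, None]) * d[:, None]
        powers.append(float(np.sum(np.abs((X[:, mask] * align).sum(axis=0)) ** 2)))
    return float(grid[int(np.argmax(powers))])
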