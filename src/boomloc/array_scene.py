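"""Microphone-array geometry and free-field scene simulation.

Planar (2-D) geometry throughout: the arrays estimate azimuthal direction
of arrival only.  Propagation is free field — spherical spreading (1/d
amplitude) and a pure delay d/c per microphone, with no reverberation,
ground reflection or atmospheric absorption.  Fractional delays are
applied in the frequency domain (exact phase shift on zero-padded blocks).

"Diffuse" ambient noise is realized as spatially independent white
Gaussian noise per channel, scaled to a target array-average SNR; the
independence is a neutral modeling choice in the absence of a stated
coherence model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArrayGeometry",
    "SceneConfig",
    "MultichannelSignal",
    "SteeringSet",
    "make_circular_array",
    "make_hybrid_array",
    "steering_set",
    "propagate",
    "add_diffuse_noise",
]

SPEED_OF_SOUND = 340.0  # m/s, default; configurable everywhere it is used


@dataclass(frozen=True)
class ArrayGeometry:
    """Ordered planar microphone coordinates, meters, array center at origin."""

    mic_positions: tuple[tuple[float, float], ...]
    label: str = ""

    @property
    def M(self) -> int:
        return len(self.mic_positions)

    @property
    def xy(self) -> np.ndarray:
        """(M, 2) coordinate array."""
        return np.asarray(self.mic_positions, dtype=np.float64)

    @property
    def max_radius(self) -> float:
        return float(np.max(np.linalg.norm(self.xy, axis=1)))

    @property
    def aperture(self) -> float:
        """Largest pairwise microphone distance, meters."""
        xy = self.xy
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        return float(d.max())


@dataclass(frozen=True)
class SceneConfig:
    """Source placement and rendering parameters for one simulated scene."""

    source_azimuth: float = 0.0  # degrees, array polar coordinates
    source_distance: float = 30.0  # meters from array center
    speed_of_sound: float = SPEED_OF_SOUND
    sample_rate: int = 16000
    snr_db: float | None = 20.0  # None = no noise added

    def __post_init__(self) -> None:
        if self.source_distance <= 0:
            raise ValueError("source_distance must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def source_xy(self, azimuth_deg: float | None = None) -> np.ndarray:
        az = np.deg2rad(self.source_azimuth if azimuth_deg is None else azimuth_deg)
        return self.source_distance * np.array([np.cos(az), np.sin(az)])


@dataclass
class MultichannelSignal:
    """M synchronized channels sharing one sample clock; shape (M, N)."""

    channels: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=np.float64))

    @property
    def M(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass
class SteeringSet:
    """Free-field transfer-function vectors H(theta, omega).

    ``H[a, b, :]`` is the complex M-vector for azimuth ``azimuth_grid[a]``
    and frequency ``freq_bins[b]``.
    """

    azimuth_grid: np.ndarray  # degrees
    freq_bins: np.ndarray  # Hz
    H: np.ndarray  # complex, (n_az, n_freq, M)

    def __post_init__(self) -> None:
        if np.any(np.all(self.H == 0, axis=-1)):
            raise ValueError("all-zero steering vector")


def make_circular_array(radius: float, M: int = 8, label: str | None = None) -> ArrayGeometry:
    """Uniform circular array: mic k at azimuth k*(360/M) degrees.

    The field arrays place 8 microphones on the periphery at 45-degree
    intervals; mic 0 sits at azimuth 0.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if M < 2:
        raise ValueError("need at least 2 microphones")
    angles = 2 * np.pi * np.arange(M) / M
    pos = tuple((radius * np.cos(a), radius * np.sin(a)) for a in angles)
    return ArrayGeometry(pos, label or f"circular_r{radius:g}m_M{M}")


def make_hybrid_array(
    r_small: float, r_large: float, M: int = 8, label: str | None = None
) -> ArrayGeometry:
    """Two interleaved radii, alternating around the circle.

    Even-indexed nodes sit at ``r_small``, odd-indexed at ``r_large``;
    azimuths stay uniform (45 degrees apart for M=8), so each small/large
    pair of neighbors covers a 90-degree sector.
    """
    if M % 2 != 0:
        raise ValueError("hybrid array needs an even microphone count")
    if r_small <= 0 or r_large <= 0:
        raise ValueError("radii must be positive")
    angles = 2 * np.pi * np.arange(M) / M
    radii = np.where(np.arange(M) % 2 == 0, r_small, r_large)
    pos = tuple((r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles))
    return ArrayGeometry(pos, label or f"hybrid_r{r_small:g}m_r{r_large:g}m_M{M}")


def _distances(geom: ArrayGeometry, source_xy: np.ndarray) -> np.ndarray:
    return np.linalg.norm(geom.xy - source_xy[None, :], axis=1)


def steering_set(
    geom: ArrayGeometry,
    scene: SceneConfig,
    azimuth_grid: np.ndarray,
    freq_bins: np.ndarray,
    wave_model: str = "spherical",
) -> SteeringSet:
    """Transfer functions H(theta, omega) over an azimuth grid.

    wave_model="spherical": h_i = (1/d_i) * exp(-j 2 pi f d_i / c) with
    d_i the exact distance from a source at ``scene.source_distance`` to
    mic i.  wave_model="planar": far-field, phase from the projection of
    the mic position onto the arrival direction, unit amplitude.
    """
    azimuth_grid = np.asarray(azimuth_grid, dtype=np.float64)
    freq_bins = np.asarray(freq_bins, dtype=np.float64)
    nyquist = scene.sample_rate / 2
    if np.any(freq_bins >= nyquist):
        raise ValueError(f"steering frequencies must lie below Nyquist ({nyquist} Hz)")
    c = scene.speed_of_sound
    az_rad = np.deg2rad(azimuth_grid)
    if wave_model == "spherical":
        src = scene.source_distance * np.stack([np.cos(az_rad), np.sin(az_rad)], axis=1)
        d = np.linalg.norm(src[:, None, :] - geom.xy[None, :, :], axis=-1)  # (n_az, M)
        phase = np.exp(-2j * np.pi * freq_bins[None, :, None] * d[:, None, :] / c)
        H = phase / d[:, None, :]
    elif wave_model == "planar":
        # delay relative to array center: -u . x_i / c for unit arrival dir u
        u = np.stack([np.cos(az_rad), np.sin(az_rad)], axis=1)
        tau = -(u @ geom.xy.T) / c  # (n_az, M)
        H = np.exp(-2j * np.pi * freq_bins[None, :, None] * tau[:, None, :])
    else:
        raise ValueError(f"unknown wave_model {wave_model!r}")
    return SteeringSet(azimuth_grid, freq_bins, H)


def propagate(w, geom: ArrayGeometry, scene: SceneConfig) -> MultichannelSignal:
    """Render a source waveform at each microphone of the array.

    Each channel is the source delayed by d_i/c (exact fractional delay
    via frequency-domain phase shift) and attenuated by 1/d_i; all
    channels share the clip's sample clock starting at the source's
    emission time.  Output length covers input length + max delay.
    """
    if w.sample_rate != scene.sample_rate:
        raise ValueError("waveform and scene sample rates differ")
    if scene.source_distance <= geom.max_radius:
        raise ValueError("source lies inside the array hull; free-field model invalid")
    c = scene.speed_of_sound
    fs = scene.sample_rate
    d = _distances(geom, scene.source_xy())
    max_delay = int(np.ceil(d.max() / c * fs))
    x = np.asarray(w.samples, dtype=np.float64)
    n_out = len(x) + max_delay + 1
    nfft = int(2 ** np.ceil(np.log2(n_out + 1)))
    X = np.fft.rfft(x, n=nfft)
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    shifts = np.exp(-2j * np.pi * freqs[None, :] * (d / c)[:, None])
    Y = X[None, :] * shifts / d[:, None]
    chans = np.fft.irfft(Y, n=nfft)[:, :n_out]
    return MultichannelSignal(chans, fs)


def add_diffuse_noise(
    sig: MultichannelSignal, snr_db: float, seed: int
) -> MultichannelSignal:
    """Add independent white Gaussian noise per channel at a target SNR.

    The noise variance is set so that the channel-mean signal power over
    the whole clip divided by the channel-mean noise power equals
    10^(snr_db/10).  ``snr_db=inf`` returns the input unchanged.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return MultichannelSignal(sig.channels.copy(), sig.sample_rate)
    p_sig = float(np.mean(sig.channels**2))
    if p_sig == 0:
        raise ValueError("silent input: SNR undefined")
    p_noise = p_sig / 10 ** (snr_db / 10)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(sig.channels.shape) * np.sqrt(p_noise)
    return MultichannelSignal(sig.channels + noise, sig.sample_rate)
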