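"""Band-limited MUSIC direction-of-arrival pipeline.

Stages: multichannel STFT -> per-bin time-averaged spatial covariance ->
eigendecomposition -> noise-subspace spatial spectrum over an azimuth
grid, restricted to a frequency band, -> per-frame peak extraction.

The spatial spectrum is computed, by default, as

    P(theta, omega, f) = ||H(theta, omega)||^2
                         / sum_{i=Ns+1..M} |H(theta, omega)* e_i(omega, f)|

with *magnitudes* (not squared magnitudes) in the denominator, matching
the formulation this pipeline reproduces; the textbook squared-magnitude
form is available via ``squared=True``.  At the true source direction the
steering vector is orthogonal to the noise-subspace eigenvectors
e_{Ns+1}..e_M, the denominator approaches zero and P peaks; a floor of
1e-12 on the denominator keeps P finite.

Covariance matrices are time-averaged over W consecutive STFT frames
(default W=50, i.e. 500 ms at a 10-ms hop) and the eigendecomposition is
evaluated only every PERIOD frames (default 16) for economy, mirroring
field practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .array_scene import MultichannelSignal, SteeringSet

__all__ = [
    "SpectralFrames",
    "BandSelection",
    "CorrSeq",
    "EigenSeq",
    "MusicSpectrum",
    "stft",
    "select_band",
    "correlation",
    "eigendecompose",
    "music_spectrum",
    "frame_peak_azimuths",
]

DENOM_FLOOR = 1e-12


@dataclass
class SpectralFrames:
    """Short-time spectra: X[ch, bin, frame], complex."""

    X: np.ndarray
    window_size: int
    shift: int
    sample_rate: int

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]

    @property
    def n_frames(self) -> int:
        return self.X.shape[2]

    @property
    def bin_hz(self) -> float:
        """Bandwidth of one frequency bin, Hz."""
        return self.sample_rate / self.window_size

    @property
    def hop_s(self) -> float:
        """Time between consecutive frames, seconds."""
        return self.shift / self.sample_rate

    def frame_times(self) -> np.ndarray:
        """Center time of each analysis window, seconds."""
        return (np.arange(self.n_frames) * self.shift + self.window_size / 2) / self.sample_rate

    def restrict(self, band: "BandSelection") -> "SpectralFrames":
        """Keep only the band's bins (bin axis reindexed to the band)."""
        out = SpectralFrames(
            self.X[:, band.bin_indices, :], self.window_size, self.shift, self.sample_rate
        )
        return out


@dataclass(frozen=True)
class BandSelection:
    """Contiguous set of STFT bins covering [low_hz, high_hz].

    ``bin_indices`` are 0-based array indices; the 1-based labeling used
    in field reports counts the 0 Hz bin as bin 1, so the "3rd bin" of a
    16 kHz / 512-sample analysis is index 2 at 62.5 Hz.
    """

    bin_indices: tuple[int, ...]
    low_hz: float
    high_hz: float
    bin_hz: float

    @property
    def center_freqs(self) -> np.ndarray:
        return np.asarray(self.bin_indices) * self.bin_hz

    @property
    def n_bins(self) -> int:
        return len(self.bin_indices)


@dataclass
class CorrSeq:
    """Per-bin spatial covariance at each evaluation frame.

    R[eval, bin] is an M x M Hermitian matrix averaging W consecutive
    STFT frames starting at ``frame_indices[eval]``; evaluation frames
    are spaced ``period`` STFT frames apart.
    """

    R: np.ndarray  # (n_eval, n_bins, M, M) complex
    frame_indices: np.ndarray  # start frame of each averaging window
    W: int
    period: int
    hop_s: float

    def eval_times(self, window_size: int, sample_rate: int) -> np.ndarray:
        """Center time of each averaging window, seconds."""
        start = self.frame_indices * self.hop_s + window_size / (2 * sample_rate)
        return start + (self.W - 1) * self.hop_s / 2


@dataclass
class EigenSeq:
    """Eigendecomposition of each covariance in a CorrSeq.

    Eigenvalues sorted descending; columns of E are the matching
    orthonormal eigenvectors, so E[..., :, Ns:] spans the noise subspace.
    """

    E: np.ndarray  # (n_eval, n_bins, M, M) complex, eigenvectors in columns
    eigenvalues: np.ndarray  # (n_eval, n_bins, M) real, descending
    frame_indices: np.ndarray
    hop_s: float
    Ns: int = 1


@dataclass
class MusicSpectrum:
    """MUSIC spatial spectrum per evaluation frame.

    ``P_bins[eval, az, bin]`` is the per-bin spectrum; ``P[eval, az]``
    the band aggregate (arithmetic mean over bins by default).
    """

    P: np.ndarray
    P_bins: np.ndarray
    azimuth_grid: np.ndarray
    frame_indices: np.ndarray
    hop_s: float

    def eval_times(self, window_size: int = 512, sample_rate: int = 16000) -> np.ndarray:
        start = self.frame_indices * self.hop_s + window_size / (2 * sample_rate)
        return start


def stft(sig: MultichannelSignal, window_size: int = 512, shift: int = 160) -> SpectralFrames:
    """Hann-windowed short-time Fourier transform per channel.

    Frames are taken from the signal without padding, so
    ``n_frames = floor((N - window_size) / shift) + 1``; each frame has
    ``window_size/2 + 1`` one-sided bins (257 for a 512-sample window).
    """
    if shift > window_size:
        raise ValueError("shift must not exceed window_size")
    N = sig.n_samples
    if N < window_size:
        raise ValueError(f"signal ({N} samples) shorter than one window ({window_size})")
    n_frames = (N - window_size) // shift + 1
    idx = np.arange(window_size)[None, :] + shift * np.arange(n_frames)[:, None]
    frames = sig.channels[:, idx]  # (M, n_frames, window)
    win = hann(window_size, sym=False)
    X = np.fft.rfft(frames * win[None, None, :], axis=-1)  # (M, n_frames, bins)
    return SpectralFrames(np.transpose(X, (0, 2, 1)), window_size, shift, sig.sample_rate)


def select_band(
    low_hz: float, high_hz: float, sample_rate: int = 16000, window_size: int = 512
) -> BandSelection:
    """Bins whose center frequency k * (fs/window) lies in [low, high]."""
    nyquist = sample_rate / 2
    if not (0 <= low_hz < high_hz <= nyquist):
        raise ValueError(f"need 0 <= low < high <= Nyquist ({nyquist} Hz)")
    bin_hz = sample_rate / window_size
    n_bins = window_size // 2 + 1
    centers = np.arange(n_bins) * bin_hz
    sel = np.flatnonzero((centers >= low_hz) & (centers <= high_hz))
    if sel.size == 0:
        raise ValueError(
            f"no bin centers in [{low_hz}, {high_hz}] Hz with {bin_hz} Hz spacing"
        )
    return BandSelection(tuple(int(k) for k in sel), low_hz, high_hz, bin_hz)


def correlation(Xb: SpectralFrames, W: int = 50, period: int = 16) -> CorrSeq:
    """Time-averaged spatial covariance per bin.

    For each evaluation frame f (every ``period`` STFT frames) and bin,
    R = (1/W) sum_{i=0}^{W-1} X(f+i) X(f+i)^H over the channel dimension;
    Hermitian PSD by construction.
    """
    n_frames = Xb.n_frames
    if W < 1 or period < 1:
        raise ValueError("W and period must be positive")
    if W > n_frames:
        raise ValueError(f"averaging window W={W} exceeds available frames ({n_frames})")
    starts = np.arange(0, n_frames - W + 1, period)
    X = Xb.X  # (M, bins, frames)
    Rs = np.empty((len(starts), Xb.n_bins, X.shape[0], X.shape[0]), dtype=complex)
    for e, s in enumerate(starts):
        seg = X[:, :, s : s + W]  # (M, bins, W)
        # (bins, M, M): average outer products over the W frames
        Rs[e] = np.einsum("ibf,jbf->bij", seg, seg.conj()) / W
    return CorrSeq(Rs, starts, W, period, Xb.hop_s)


def eigendecompose(Rseq: CorrSeq, Ns: int = 1, herm_tol: float = 1e-8) -> EigenSeq:
    """Eigendecomposition R = E diag(lambda) E^H, eigenvalues descending."""
    R = Rseq.R
    scale = np.maximum(np.abs(R).max(axis=(-2, -1), keepdims=True), 1e-300)
    if np.max(np.abs(R - R.conj().swapaxes(-2, -1)) / scale) > herm_tol:
        raise ValueError("covariance not Hermitian within tolerance")
    vals, vecs = np.linalg.eigh(R)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    return EigenSeq(vecs, vals, Rseq.frame_indices, Rseq.hop_s, Ns)


def music_spectrum(
    Eseq: EigenSeq,
    S: SteeringSet,
    band: BandSelection,
    Ns: int | None = None,
    squared: bool = False,
    aggregate: str = "mean",
) -> MusicSpectrum:
    """Noise-subspace spatial spectrum over the steering azimuth grid.

    ``S.freq_bins`` must match the band's bin center frequencies (that is,
    the covariance bins).  Per bin,
    ``P = ||H||^2 / sum_i |H^H e_i|`` over the M - Ns noise eigenvectors
    (magnitudes squared instead when ``squared=True``); the band
    aggregate is the arithmetic mean over bins by default (``sum`` and
    ``gmean`` are accepted).
    """
    M = Eseq.E.shape[-1]
    Ns = Eseq.Ns if Ns is None else Ns
    if not 0 < Ns < M:
        raise ValueError(f"need 0 < Ns < M={M}, got Ns={Ns}")
    if len(S.freq_bins) != band.n_bins or not np.allclose(S.freq_bins, band.center_freqs):
        raise ValueError("steering frequencies do not match the band's bin centers")
    H = S.H  # (n_az, n_bins, M)
    En = Eseq.E[..., Ns:]  # (n_eval, n_bins, M, M-Ns) noise subspace
    # inner products H^H e_i: (n_eval, n_az, n_bins, M-Ns)
    proj = np.einsum("abm,ebmk->eabk", H.conj(), En)
    mag = np.abs(proj) ** 2 if squared else np.abs(proj)
    denom = np.maximum(mag.sum(axis=-1), DENOM_FLOOR)
    num = np.sum(np.abs(H) ** 2, axis=-1)  # (n_az, n_bins)
    P_bins = num[None, :, :] / denom
    if aggregate == "mean":
        P = P_bins.mean(axis=-1)
    elif aggregate == "sum":
        P = P_bins.sum(axis=-1)
    elif aggregate == "gmean":
        P = np.exp(np.log(np.maximum(P_bins, 1e-300)).mean(axis=-1))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return MusicSpectrum(P, P_bins, S.azimuth_grid, Eseq.frame_indices, Eseq.hop_s)


def _circular_local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima on a circular grid."""
    left = np.roll(p, 1)
    right = np.roll(p, -1)
    return np.flatnonzero((p >= left) & (p > right) | (p > left) & (p >= right))


def frame_peak_azimuths(
    P: MusicSpectrum, thresh: float, num_source: int = 1
) -> list[list[tuple[float, float]]]:
    """Per-evaluation-frame peak list.

    Returns, for each evaluation frame, up to ``num_source``
    ``(azimuth_deg, power)`` pairs at circular local maxima of the
    band-aggregated spectrum with power >= thresh, strongest first; ties
    broken toward the lower azimuth.
    """
    peaks: list[list[tuple[float, float]]] = []
    az = P.azimuth_grid
    for p in P.P:
        cand = _circular_local_maxima(p)
        cand = cand[p[cand] >= thresh]
        # strongest first, lower azimuth wins ties
        order = sorted(cand, key=lambda i: (-p[i], az[i]))
        peaks.append([(float(az[i]), float(p[i])) for i in order[:num_source]])
    return peaks
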