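import numpy as np
import pytest

from boomloc import (
    BoomSpec,
    MultichannelSignal,
    SceneConfig,
    correlation,
    eigendecompose,
    frame_peak_azimuths,
    make_circular_array,
    music_spectrum,
    propagate,
    select_band,
    steering_set,
    stft,
    synthesize_boom,
)
from boomloc.experiments import BANDS, localize_scene
from boomloc.music_core import MusicSpectrum


class TestStft:
    def test_10s_clip_gives_997_frames_of_257_bins(self):
        sig = MultichannelSignal(np.random.default_rng(0).standard_normal((8, 160000)), 16000)
        frames = stft(sig, 512, 160)
        assert frames.n_frames == 997
        assert frames.n_bins == 257
        assert frames.bin_hz == pytest.approx(31.25)

    def test_pure_tone_dominant_bin(self):
        t = np.arange(16000) / 16000
        sig = MultichannelSignal(np.sin(2 * np.pi * 125.0 * t)[None, :], 16000)
        frames = stft(sig)
        mag = np.abs(frames.X[0]).mean(axis=1)
        assert np.argmax(mag) == 4  # 125 Hz at 31.25 Hz spacing

    def test_zero_input_zero_spectra(self):
        frames = stft(MultichannelSignal(np.zeros((2, 2000)), 16000))
        assert np.all(frames.X == 0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            stft(MultichannelSignal(np.zeros((2, 100)), 16000), 512, 160)


class TestSelectBand:
    def test_lf_band_is_seven_bins(self):
        band = select_band(50, 250, 16000, 512)
        assert band.n_bins == 7
        assert band.center_freqs[0] == pytest.approx(62.5)
        assert band.center_freqs[-1] == pytest.approx(250.0)

    def test_wideband_selection(self):
        band = select_band(50, 2800, 16000, 512)
        assert band.center_freqs[0] == pytest.approx(62.5)
        assert band.center_freqs[-1] == pytest.approx(2781.25)

    def test_full_band(self):
        assert select_band(0, 8000, 16000, 512).n_bins == 257

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            select_band(33.0, 60.0, 16000, 512)


class TestCorrelation:
    def _frames(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        sig = MultichannelSignal(rng.standard_normal((8, 512 + 160 * (n - 1))), 16000)
        return stft(sig).restrict(select_band(50, 250, 16000, 512))

    def test_window_covers_500ms(self):
        Rseq = correlation(self._frames(), W=50, period=16)
        assert Rseq.W * Rseq.hop_s == pytest.approx(0.5)

    def test_single_frame_window_is_rank_one(self):
        Rseq = correlation(self._frames(), W=1, period=16)
        vals = np.linalg.eigvalsh(Rseq.R[0, 0])
        assert vals[-2] / vals[-1] < 1e-10

    def test_hermitian_psd(self):
        Rseq = correlation(self._frames(), W=50, period=16)
        assert np.allclose(Rseq.R, Rseq.R.conj().swapaxes(-2, -1))
        assert np.linalg.eigvalsh(Rseq.R).min() > -1e-10

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            correlation(self._frames(n=20), W=50)

    def test_noiseless_single_source_near_rank_one(self):
        # stationary tone: steering identical in every frame, so R is rank 1
        from boomloc.call_synth import Waveform

        scene = SceneConfig(snr_db=None)
        t = np.arange(80000) / 16000
        tone = Waveform(0.2 * np.sin(2 * np.pi * 125.0 * t), 16000)
        sig = propagate(tone, make_circular_array(0.1, 8), scene)
        frames = stft(sig).restrict(select_band(100, 150, 16000, 512))
        Rseq = correlation(frames, W=50, period=16)
        tr = np.trace(Rseq.R, axis1=-2, axis2=-1).real.sum(axis=1)
        vals = np.linalg.eigvalsh(Rseq.R[np.argmax(tr), 0])
        assert vals[-2] / vals[-1] < 1e-6


class TestEigendecompose:
    def test_identity_input(self):
        from boomloc.music_core import CorrSeq

        R = np.eye(8, dtype=complex)[None, None]
        seq = CorrSeq(R, np.array([0]), 1, 1, 0.01)
        E = eigendecompose(seq)
        assert np.allclose(E.eigenvalues, 1.0)

    def test_rank_one_closed_form(self):
        from boomloc.music_core import CorrSeq

        rng = np.random.default_rng(1)
        h = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        R = np.outer(h, h.conj())[None, None]
        E = eigendecompose(CorrSeq(R, np.array([0]), 1, 1, 0.01))
        assert E.eigenvalues[0, 0, 0] == pytest.approx(np.linalg.norm(h) ** 2)
        assert np.allclose(E.eigenvalues[0, 0, 1:], 0.0, atol=1e-9)

    def test_matches_power_iteration_oracle(self):
        from boomloc.music_core import CorrSeq

        rng = np.random.default_rng(2)
        A = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        R = A @ A.conj().T  # Hermitian PSD
        E = eigendecompose(CorrSeq(R[None, None], np.array([0]), 1, 1, 0.01))
        # deflated power iteration, independent of numpy.linalg.eigh
        M = R.copy()
        oracle = []
        for _ in range(8):
            v = rng.standard_normal(8) + 1j * rng.standard_normal(8)
            for _ in range(2000):
                v = M @ v
                v /= np.linalg.norm(v)
            lam = float((v.conj() @ M @ v).real)
            oracle.append(lam)
            M = M - lam * np.outer(v, v.conj())
        assert np.allclose(E.eigenvalues[0, 0], sorted(oracle, reverse=True), atol=1e-6)

    def test_descending_and_orthonormal(self):
        from boomloc.music_core import CorrSeq

        rng = np.random.default_rng(3)
        A = rng.standard_normal((5, 3, 8, 8)) + 1j * rng.standard_normal((5, 3, 8, 8))
        R = A @ A.conj().swapaxes(-2, -1)
        E = eigendecompose(CorrSeq(R, np.arange(5), 1, 1, 0.01))
        assert np.all(np.diff(E.eigenvalues, axis=-1) <= 1e-9)
        gram = E.E.conj().swapaxes(-2, -1) @ E.E
        assert np.allclose(gram, np.eye(8), atol=1e-10)

    def test_non_hermitian_rejected(self):
        from boomloc.music_core import CorrSeq

        R = np.random.default_rng(4).standard_normal((8, 8)) + 0j
        with pytest.raises(ValueError):
            eigendecompose(CorrSeq(R[None, None], np.array([0]), 1, 1, 0.01))


class TestMusicSpectrum:
    def test_noiseless_source_at_grid_azimuth(self):
        scene = SceneConfig(source_azimuth=45.0, source_distance=30.0, snr_db=None)
        geom = make_circular_array(1.0, 8)
        sig = propagate(synthesize_boom(BoomSpec(), 1), geom, scene)
        spec = localize_scene(sig, geom, scene, BANDS["LF"])
        best = np.unravel_index(np.argmax(spec.P), spec.P.shape)
        assert spec.azimuth_grid[best[1]] == pytest.approx(45.0)

    def test_ns_not_less_than_m_rejected(self, scene):
        geom = make_circular_array(0.1, 8)
        sig = MultichannelSignal(
            np.random.default_rng(0).standard_normal((8, 40000)), 16000
        )
        band = select_band(50, 250)
        frames = stft(sig).restrict(band)
        Eseq = eigendecompose(correlation(frames))
        S = steering_set(geom, scene, np.arange(0, 360, 5.0), band.center_freqs)
        with pytest.raises(ValueError):
            music_spectrum(Eseq, S, band, Ns=8)

    def test_noise_only_spectrum_flat(self, scene):
        geom = make_circular_array(1.0, 8)
        rng = np.random.default_rng(7)
        acc = []
        for _ in range(20):
            sig = MultichannelSignal(rng.standard_normal((8, 40000)), 16000)
            spec = localize_scene(sig, geom, scene, BANDS["LF"])
            acc.append(spec.P.mean(axis=0))
        mean_p = np.mean(acc, axis=0)
        assert mean_p.max() / mean_p.min() < 1.5

    def test_noise_subspace_orthogonality_improves_with_snr(self, boom_spec):
        geom = make_circular_array(1.0, 8)
        from boomloc import add_diffuse_noise

        resid = []
        for snr in [10.0, 40.0]:
            scene = SceneConfig(snr_db=snr)
            sig = add_diffuse_noise(
                propagate(synthesize_boom(boom_spec, 1), geom, scene), snr, seed=5
            )
            spec = localize_scene(sig, geom, scene, BANDS["LF"])
            # P at truth ~ 1/residual: higher SNR, deeper null
            resid.append(1.0 / spec.P[:, 0].max())
        assert resid[1] < resid[0]


class TestFramePeaks:
    def _spec(self, P):
        n = P.shape[1]
        return MusicSpectrum(P, P[:, :, None], np.arange(0, 360, 360 / n), np.arange(len(P)), 0.16)

    def test_flat_below_threshold_no_peaks(self):
        peaks = frame_peak_azimuths(self._spec(np.full((3, 72), 0.5)), thresh=1.0)
        assert all(p == [] for p in peaks)

    def test_single_injected_maximum(self):
        P = np.full((1, 72), 0.1)
        P[0, 9] = 5.0  # 45 degrees
        peaks = frame_peak_azimuths(self._spec(P), thresh=1.0)
        assert peaks[0] == [(45.0, 5.0)]

    def test_num_source_one_keeps_larger(self):
        P = np.full((1, 72), 0.1)
        P[0, 9] = 5.0
        P[0, 40] = 7.0
        peaks = frame_peak_azimuths(self._spec(P), thresh=1.0, num_source=1)
        assert peaks[0] == [(200.0, 7.0)]
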