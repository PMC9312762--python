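"""Signal conditioning and feature extraction."""

import numpy as np
import pytest
import scipy.signal

from ssrnet.containers import AudioRecording, EmgRecording
from ssrnet.sigproc import (
    bandpass_filter,
    extract_emg_features,
    extract_mel,
    extract_stft_features,
    extract_td_features,
    frame_count,
    mel_band_centers,
    notch_filter,
)


def emg_from(x: np.ndarray, rate: int = 2000) -> EmgRecording:
    return EmgRecording(np.tile(x, (5, 1)), rate=rate)


def sine(freq: float, rate: int = 2000, seconds: float = 2.0) -> np.ndarray:
    t = np.arange(int(rate * seconds)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_dc_removed(self):
        rec = emg_from(np.full(4000, 3.7))
        out = bandpass_filter(rec)
        assert np.max(np.abs(out.samples)) < 1e-6 * 3.7

    @pytest.mark.parametrize(
        "freq,passes",
        [(200.0, True), (900.0, False)],
    )
    def test_band_edges(self, freq, passes):
        # oracle: the designed filter's squared frequency response
        sos = scipy.signal.butter(4, [4, 400], btype="bandpass", fs=2000, output="sos")
        w, h = scipy.signal.sosfreqz(sos, worN=[2 * np.pi * freq / 2000])
        expected = np.abs(h[0]) ** 2  # zero-phase: forward-backward squares it
        out = bandpass_filter(emg_from(sine(freq))).samples[0]
        steady = out[1500:-1500]
        amp = np.max(np.abs(steady))
        if passes:
            assert abs(amp - 1.0) < 0.05
            assert abs(expected - 1.0) < 0.05
        else:
            assert amp < 0.05
            assert expected < 0.05

    def test_bad_edges_rejected(self):
        rec = emg_from(sine(50))
        with pytest.raises(ValueError):
            bandpass_filter(rec, low_hz=0.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, low_hz=4, high_hz=1200)


class TestNotch:
    def test_zero_signal(self):
        out = notch_filter(emg_from(np.zeros(2000)))
        assert np.allclose(out.samples, 0.0)

    def test_mains_attenuated_sideband_kept(self):
        # oracle: cascade frequency response at 50 Hz and 75 Hz
        resp = np.ones(2, dtype=complex)
        for f0 in np.arange(50, 401, 50):
            b, a = scipy.signal.iirnotch(f0, 30, fs=2000)
            w, h = scipy.signal.freqz(b, a, worN=2 * np.pi * np.array([50.0, 75.0]) / 2000)
            resp *= h
        assert np.abs(resp[0]) ** 2 < 10 ** (-20 / 10)  # >= 20 dB down, zero-phase
        assert abs(np.abs(resp[1]) ** 2 - 1.0) < 0.1

        out50 = notch_filter(emg_from(sine(50)))
        amp50 = np.max(np.abs(out50.samples[0][2000:-1000]))
        assert amp50 < 0.1  # >= 20 dB attenuation
        out75 = notch_filter(emg_from(sine(75)))
        amp75 = np.max(np.abs(out75.samples[0][2000:-1000]))
        assert abs(amp75 - 1.0) < 0.1

    def test_bad_q(self):
        with pytest.raises(ValueError):
            notch_filter(emg_from(sine(50)), q=0.0)


class TestTdFeatures:
    def test_zero_frame(self):
        assert np.allclose(extract_td_features(np.zeros(128)), 0.0)

    def test_constant_frame_zero_crossings(self):
        f = extract_td_features(np.full(128, 2.5))
        assert f[4] == 0

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        frame = rng.standard_normal(128)
        # independent loop-based recomputation of each definition
        k = 9
        pad = np.concatenate([np.repeat(frame[0], k // 2), frame, np.repeat(frame[-1], k // 2)])
        w1 = np.array([np.mean(pad[i : i + k]) for i in range(len(frame))])
        pad2 = np.concatenate([np.repeat(w1[0], k // 2), w1, np.repeat(w1[-1], k // 2)])
        w = np.array([np.mean(pad2[i : i + k]) for i in range(len(frame))])
        hf = frame - w
        r = np.abs(hf)
        zc = sum(
            1
            for i in range(1, len(hf))
            if (hf[i - 1] > 0 and hf[i] < 0) or (hf[i - 1] < 0 and hf[i] > 0)
        )
        expected = [
            np.mean(w),
            np.mean(w**2),
            np.mean(r),
            np.mean(r**2),
            zc,
            np.mean(np.abs(frame)),
        ]
        assert np.allclose(extract_td_features(frame), expected, atol=1e-12)

    def test_short_frame_rejected(self):
        with pytest.raises(ValueError):
            extract_td_features(np.ones(4))


class TestStft:
    def test_window_bin_arithmetic(self):
        out = extract_stft_features(np.random.default_rng(0).standard_normal(2000), 2000)
        assert out.shape[1] == 65  # 128-sample window -> 65 one-sided bins

    def test_zero_signal(self):
        out = extract_stft_features(np.zeros(2000), 2000)
        assert np.allclose(out, 0.0)

    def test_250hz_peak_bin(self):
        # 250 Hz at a 2000/128 = 15.625 Hz bin spacing -> bin 16
        out = extract_stft_features(sine(250), 2000)
        interior = out[5:-5]
        assert np.all(np.argmax(interior, axis=1) == 16)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_stft_features(np.array([]), 2000)


class TestEmgFeatures:
    def test_dimension_355(self):
        rng = np.random.default_rng(0)
        rec = EmgRecording(rng.standard_normal((5, 2000)))
        feats = extract_emg_features(rec)
        assert feats.dim == 355

    def test_zero_recording(self):
        feats = extract_emg_features(EmgRecording(np.zeros((5, 2000))))
        assert np.allclose(feats.frames, 0.0)

    def test_frame_count_matches_stft(self):
        x = np.random.default_rng(1).standard_normal(2048)  # 1.024 s
        rec = EmgRecording(np.tile(x, (5, 1)))
        feats = extract_emg_features(rec)
        stft = extract_stft_features(x, 2000)
        assert len(feats) == stft.shape[0] == frame_count(2048, 32)

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            extract_emg_features(EmgRecording(np.zeros((4, 2000))))

    def test_linearity_of_filters(self):
        rng = np.random.default_rng(3)
        s1 = EmgRecording(rng.standard_normal((5, 3000)))
        s2 = EmgRecording(rng.standard_normal((5, 3000)))
        a, b = 2.0, -0.7
        mix = EmgRecording(a * s1.samples + b * s2.samples)
        lhs = bandpass_filter(mix).samples
        rhs = a * bandpass_filter(s1).samples + b * bandpass_filter(s2).samples
        assert np.allclose(lhs, rhs, rtol=1e-8, atol=1e-10)

    def test_determinism(self):
        rec = EmgRecording(np.random.default_rng(9).standard_normal((5, 2000)))
        f1 = extract_emg_features(rec).frames
        f2 = extract_emg_features(rec).frames
        assert np.array_equal(f1, f2)


class TestMel:
    def test_80_bands(self):
        audio = AudioRecording(np.random.default_rng(0).standard_normal(16000) * 0.1)
        assert extract_mel(audio).dim == 80

    def test_silence_hits_floor(self):
        mel = extract_mel(AudioRecording(np.zeros(16000)))
        assert np.allclose(mel.frames, -10.0)  # log10 of the 1e-10 floor

    def test_1khz_band(self):
        t = np.arange(16000) / 16000
        mel = extract_mel(AudioRecording(0.5 * np.sin(2 * np.pi * 1000 * t)))
        band = int(np.argmax(mel.frames.mean(axis=0)))
        centers = mel_band_centers()
        # band whose center is nearest 1 kHz
        assert band == int(np.argmin(np.abs(centers - 1000.0)))

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValueError):
            extract_mel(AudioRecording(np.zeros(8000), rate=8000))

    def test_frame_rate_equality_with_emg(self):
        # equal-duration co-recorded signals -> frame counts within 2
        seconds = 1.3
        n_emg = int(2000 * seconds)
        n_audio = int(16000 * seconds)
        emg_frames = frame_count(n_emg, 32)
        mel_frames = frame_count(n_audio, 256)
        assert abs(emg_frames - mel_frames) <= 2
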