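"""Signal conditioning and feature extraction.

Conditioning: a zero-phase Butterworth bandpass (4-400 Hz by default)
removes offset and high-frequency content from the EMG, and a cascade of
IIR notches suppresses 50 Hz mains interference and its harmonics.

Features: per 64 ms frame (16 ms hop) each EMG channel yields six
time-domain descriptors plus 65 one-sided STFT magnitudes, giving
5 x (6 + 65) = 355 dimensions per frame.  Audio is reduced to an
80-band log-mel spectrogram over 80-7600 Hz with a 1024-point window and
256-point hop at 16 kHz, so EMG and mel frames share the 16 ms grid.

Framing convention (both streams): frame i is centered at i * hop via
reflect padding, and the frame count is ceil(T / hop); co-recorded EMG and
audio of equal duration therefore produce equal frame counts.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .containers import (
    AUDIO_RATE,
    EMG_CHANNELS,
    EMG_FEATURE_DIM,
    MEL_DIM,
    MEL_FMAX,
    MEL_FMIN,
    AudioRecording,
    EmgFeatureSequence,
    EmgRecording,
    MelSequence,
)

EMG_WINDOW_S = 0.064
EMG_HOP_S = 0.016
MEL_WINDOW = 1024
MEL_HOP = 256
LOG_FLOOR = 1e-10

__all__ = [
    "bandpass_filter",
    "notch_filter",
    "extract_td_features",
    "extract_stft_features",
    "extract_emg_features",
    "extract_mel",
    "mel_filterbank",
    "frame_count",
]


def frame_count(n_samples: int, hop: int) -> int:
    """Number of centered frames for a signal of ``n_samples`` samples."""
    if n_samples <= 0:
        raise ValueError("empty signal")
    return int(np.ceil(n_samples / hop))


def _frame_centered(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Frame a 1-D signal into [n_frames x win] with reflect center padding."""
    n = frame_count(x.size, hop)
    half = win // 2
    pad_right = max(0, (n - 1) * hop + win - half - x.size)
    mode = "reflect" if x.size > max(half, pad_right) else "edge"
    xp = np.pad(x, (half, pad_right), mode=mode)
    idx = np.arange(n)[:, None] * hop + np.arange(win)[None, :]
    return xp[idx]


def bandpass_filter(
    rec: EmgRecording, low_hz: float = 4.0, high_hz: float = 400.0, order: int = 4
) -> EmgRecording:
    """Zero-phase Butterworth bandpass, applied channel-wise."""
    nyq = rec.rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}"
        )
    sos = scipy.signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rec.rate, output="sos"
    )
    filtered = scipy.signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EmgRecording(filtered, rate=rec.rate, mode=rec.mode)


def notch_filter(
    rec: EmgRecording, base_hz: float = 50.0, max_hz: float = 400.0, q: float = 30.0
) -> EmgRecording:
    """Cascaded zero-phase notches at base_hz and its harmonics up to max_hz."""
    if q <= 0:
        raise ValueError("notch quality factor q must be positive")
    nyq = rec.rate / 2.0
    if not (0 < base_hz < nyq):
        raise ValueError("base frequency must lie in (0, Nyquist)")
    out = rec.samples
    f = base_hz
    while f <= min(max_hz, nyq * 0.999):
        b, a = scipy.signal.iirnotch(f, q, fs=rec.rate)
        out = scipy.signal.filtfilt(b, a, out, axis=1)
        f += base_hz
    return EmgRecording(out, rate=rec.rate, mode=rec.mode)


def _double_running_mean(x: np.ndarray, k: int = 9) -> np.ndarray:
    """Two passes of a centered k-point running mean (edge-padded)."""
    kernel = np.ones(k) / k
    half = k // 2
    y = x
    for _ in range(2):
        yp = np.pad(y, half, mode="edge")
        y = np.convolve(yp, kernel, mode="valid")
    return y


def _zero_crossings(x: np.ndarray) -> int:
    """Sign-change count: positions where consecutive samples change sign."""
    s = np.sign(x)
    # treat exact zeros as carrying the previous sign so a touch does not count twice
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return int(np.sum(s[1:] * s[:-1] < 0))


def extract_td_features(frame: np.ndarray, smooth_k: int = 9) -> np.ndarray:
    """Six time-domain features of one channel's frame.

    The frame is split into a low-frequency part ``w`` (double ``smooth_k``
    point running mean) and the high-frequency residual ``frame - w`` whose
    rectification is ``r``.  Features, in order: mean(w), power(w), mean(r),
    power(r), zero-crossing count of the signed residual, mean(|frame|).
    Power is the mean of squares.
    """
    frame = np.asarray(frame, dtype=np.float64).reshape(-1)
    if frame.size < smooth_k:
        raise ValueError(
            f"frame of {frame.size} samples is shorter than the {smooth_k}-point smoother"
        )
    w = _double_running_mean(frame, smooth_k)
    hf = frame - w
    r = np.abs(hf)
    return np.array(
        [
            np.mean(w),
            np.mean(w**2),
            np.mean(r),
            np.mean(r**2),
            _zero_crossings(hf),
            np.mean(np.abs(frame)),
        ]
    )


def extract_stft_features(channel: np.ndarray, rate: int) -> np.ndarray:
    """One-sided STFT magnitudes per frame: 64 ms Hann window, 16 ms hop.

    At 2000 Hz this is a 128-sample window and 32-sample hop, yielding 65
    frequency bins per frame.
    """
    channel = np.asarray(channel, dtype=np.float64).reshape(-1)
    if channel.size == 0:
        raise ValueError("empty signal")
    win = int(round(EMG_WINDOW_S * rate))
    hop = int(round(EMG_HOP_S * rate))
    if channel.size < 1:
        raise ValueError("signal shorter than one window")
    frames = _frame_centered(channel, win, hop)
    window = scipy.signal.get_window("hann", win, fftbins=True)
    return np.abs(np.fft.rfft(frames * window, axis=1))


def extract_emg_features(rec: EmgRecording) -> EmgFeatureSequence:
    """Concatenate per-channel TD and STFT features into [N x 355] frames.

    Block order: channel-major TD features (5 x 6) first, then channel-major
    STFT magnitudes (5 x 65).
    """
    if rec.channel_count != EMG_CHANNELS:
        raise ValueError(
            f"expected {EMG_CHANNELS} EMG channels, got {rec.channel_count}"
        )
    win = int(round(EMG_WINDOW_S * rec.rate))
    hop = int(round(EMG_HOP_S * rec.rate))
    td_blocks = []
    stft_blocks = []
    for ch in rec.samples:
        frames = _frame_centered(ch, win, hop)
        td_blocks.append(np.apply_along_axis(extract_td_features, 1, frames))
        window = scipy.signal.get_window("hann", win, fftbins=True)
        stft_blocks.append(np.abs(np.fft.rfft(frames * window, axis=1)))
    feats = np.concatenate(td_blocks + stft_blocks, axis=1)
    assert feats.shape[1] == EMG_FEATURE_DIM
    return EmgFeatureSequence(feats, hop_s=EMG_HOP_S)


def mel_filterbank(
    n_mels: int = MEL_DIM,
    n_fft: int = MEL_WINDOW,
    rate: int = AUDIO_RATE,
    fmin: float = MEL_FMIN,
    fmax: float = MEL_FMAX,
) -> np.ndarray:
    """Triangular mel filterbank [n_mels x (n_fft//2 + 1)].

    Centers are equally spaced on the HTK mel scale between fmin and fmax;
    each triangle is area-normalized (Slaney convention) so band energy is
    comparable across the spectrum.
    """

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # area normalization
    return fb


def mel_band_centers(
    n_mels: int = MEL_DIM, fmin: float = MEL_FMIN, fmax: float = MEL_FMAX
) -> np.ndarray:
    """Center frequencies (Hz) of the mel bands."""
    mel = 2595.0 * np.log10(1.0 + np.array([fmin, fmax]) / 700.0)
    pts = np.linspace(mel[0], mel[1], n_mels + 2)
    return 700.0 * (10.0 ** (pts[1:-1] / 2595.0) - 1.0)


def extract_mel(audio: AudioRecording, allow_resample: bool = False) -> MelSequence:
    """80-band log-mel spectrogram of 16 kHz audio (1024 window / 256 hop)."""
    if audio.rate != AUDIO_RATE:
        if not allow_resample:
            raise ValueError(
                f"audio rate {audio.rate} != {AUDIO_RATE}; pass allow_resample=True"
            )
        samples = scipy.signal.resample_poly(audio.samples, AUDIO_RATE, audio.rate)
        audio = AudioRecording(samples, AUDIO_RATE)
    frames = _frame_centered(audio.samples, MEL_WINDOW, MEL_HOP)
    window = scipy.signal.get_window("hann", MEL_WINDOW, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * window, axis=1))
    fb = mel_filterbank()
    mel = mag @ fb.T
    logmel = np.log10(np.maximum(mel, LOG_FLOOR))
    return MelSequence(logmel, hop_s=MEL_HOP / AUDIO_RATE)
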