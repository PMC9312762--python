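"""Mel-spectrogram to waveform synthesis.

The production-quality path is an externally trained neural vocoder
(Parallel WaveGAN style) consumed through ``vocoder_adapter``; training
such a vocoder is out of scope here.  The self-contained path is
Griffin-Lim phase recovery: the 80-band log-mel is mapped back to a
linear magnitude spectrogram through a non-negative clamped pseudo-inverse
of the mel filterbank, and phases are estimated by iterating
STFT-consistency projections with the same 1024/256 analysis parameters
used by the front end.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.signal

from .containers import AUDIO_RATE, MEL_FMAX, MEL_FMIN, AudioRecording, MelSequence
from .sigproc import LOG_FLOOR, MEL_HOP, MEL_WINDOW, mel_filterbank

__all__ = ["griffin_lim_synthesize", "vocoder_adapter", "synthesize"]


def _check_mel_config(mel: MelSequence) -> None:
    if mel.dim != 80:
        raise ValueError(f"expected 80 mel bands, got {mel.dim}")
    if abs(mel.hop_s - MEL_HOP / AUDIO_RATE) > 1e-9:
        raise ValueError(f"mel hop {mel.hop_s}s does not match {MEL_HOP / AUDIO_RATE}s")
    if abs(mel.fmin - MEL_FMIN) > 1e-6 or abs(mel.fmax - MEL_FMAX) > 1e-6:
        raise ValueError("mel band edges do not match the analysis configuration")


def _mel_to_linear(logmel: np.ndarray) -> np.ndarray:
    """Invert log compression and the mel filterbank (clamped pseudo-inverse)."""
    fb = mel_filterbank()
    mel_mag = np.power(10.0, logmel)
    mel_mag[mel_mag <= LOG_FLOOR * 1.0000001] = 0.0
    inv = np.linalg.pinv(fb)
    return np.maximum(mel_mag @ inv.T, 0.0)


def _stft(x: np.ndarray) -> np.ndarray:
    window = scipy.signal.get_window("hann", MEL_WINDOW, fftbins=True)
    n = int(np.ceil(x.size / MEL_HOP))
    half = MEL_WINDOW // 2
    pad_right = max(0, (n - 1) * MEL_HOP + MEL_WINDOW - half - x.size)
    xp = np.pad(x, (half, pad_right), mode="reflect" if x.size > max(half, pad_right) else "edge")
    idx = np.arange(n)[:, None] * MEL_HOP + np.arange(MEL_WINDOW)[None, :]
    return np.fft.rfft(xp[idx] * window, axis=1)


def _istft(spec: np.ndarray, n_samples: int) -> np.ndarray:
    """Overlap-add inverse of ``_stft`` (centered frames, Hann window)."""
    window = scipy.signal.get_window("hann", MEL_WINDOW, fftbins=True)
    frames = np.fft.irfft(spec, n=MEL_WINDOW, axis=1) * window
    half = MEL_WINDOW // 2
    total = (spec.shape[0] - 1) * MEL_HOP + MEL_WINDOW
    y = np.zeros(total)
    wsum = np.zeros(total)
    for i in range(spec.shape[0]):
        s = i * MEL_HOP
        y[s : s + MEL_WINDOW] += frames[i]
        wsum[s : s + MEL_WINDOW] += window**2
    y = y / np.maximum(wsum, 1e-8)
    y = y[half : half + n_samples]
    if y.size < n_samples:
        y = np.pad(y, (0, n_samples - y.size))
    return y


def griffin_lim_synthesize(
    mel: MelSequence, iterations: int = 60, seed: int = 0
) -> AudioRecording:
    """Phase-recovery synthesis; output length is ``M * 256`` samples."""
    _check_mel_config(mel)
    mag = _mel_to_linear(mel.frames)
    M = mel.frames.shape[0]
    n_samples = M * MEL_HOP
    rng = np.random.default_rng(seed)
    phase = np.exp(2j * np.pi * rng.random(mag.shape))
    spec = mag * phase
    for _ in range(iterations):
        x = _istft(spec, n_samples)
        rebuilt = _stft(x)[:M]
        phase = rebuilt / np.maximum(np.abs(rebuilt), 1e-12)
        spec = mag * phase
    y = _istft(spec, n_samples)
    peak = np.max(np.abs(y))
    if peak > 1.0:
        y = y / peak
    return AudioRecording(y, rate=AUDIO_RATE)


def vocoder_adapter(mel: MelSequence, model_path: str | Path) -> AudioRecording:
    """Invoke an externally trained neural vocoder checkpoint.

    The checkpoint directory must provide a ``synthesize(mel, rate)``
    entry point (see docs).  When no checkpoint is available, raise with a
    pointer at the Griffin-Lim fallback so pipelines can degrade cleanly.
    """
    _check_mel_config(mel)
    path = Path(model_path) if model_path is not None else None
    if path is None or not path.exists():
        raise FileNotFoundError(
            f"vocoder checkpoint {model_path!r} not found; use "
            "griffin_lim_synthesize (or synthesize(..., vocoder_path=None)) "
            "as the self-contained fallback"
        )
    raise NotImplementedError(
        "no neural vocoder runtime is bundled; point model_path at an external "
        "vocoder installation or use the Griffin-Lim fallback"
    )


def synthesize(
    mel: MelSequence,
    vocoder_path: str | Path | None = None,
    iterations: int = 60,
    seed: int = 0,
) -> AudioRecording:
    """Synthesize audio, preferring the vocoder and falling back to Griffin-Lim."""
    if vocoder_path is not None:
        try:
            return vocoder_adapter(mel, vocoder_path)
        except FileNotFoundError:
            pass
    return griffin_lim_synthesize(mel, iterations=iterations, seed=seed)
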