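"""Core in-memory containers shared across the pipeline.

The pipeline works on four sequence types: raw multichannel surface-EMG
recordings, mono audio recordings, per-frame EMG feature matrices and
per-frame log-mel spectrogram matrices.  EMG is framed with a 64 ms window
and 16 ms hop at 2000 Hz; audio with a 1024-sample window and 256-sample
hop at 16 kHz, so both feature streams tick at the same 16 ms frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EMG_RATE = 2000
AUDIO_RATE = 16000
HOP_S = 0.016

EMG_CHANNELS = 5
TD_FEATURES_PER_CHANNEL = 6
STFT_BINS_PER_CHANNEL = 65
EMG_FEATURE_DIM = EMG_CHANNELS * (TD_FEATURES_PER_CHANNEL + STFT_BINS_PER_CHANNEL)

MEL_DIM = 80
MEL_FMIN = 80.0
MEL_FMAX = 7600.0


@dataclass
class EmgRecording:
    """Raw multichannel sEMG samples.

    ``samples`` is [channels x time] in arbitrary amplitude units;
    ``mode`` distinguishes silent articulation (no phonation) from vocal
    speech recorded together with audio.
    """

    samples: np.ndarray
    rate: int = EMG_RATE
    mode: str = "vocal"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("EMG samples must be a [channels x time] matrix")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.mode not in ("silent", "vocal"):
            raise ValueError(f"mode must be 'silent' or 'vocal', got {self.mode!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")

    @property
    def channel_count(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.rate


@dataclass
class AudioRecording:
    """Mono audio with amplitude in [-1, 1]."""

    samples: np.ndarray
    rate: int = AUDIO_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class EmgFeatureSequence:
    """Per-frame EMG feature matrix [N x 355].

    Layout: 5 channels x 6 time-domain features first, then 5 channels x 65
    one-sided STFT magnitudes, concatenated channel-major within each block.
    """

    frames: np.ndarray
    hop_s: float = HOP_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2:
            raise ValueError("feature frames must be 2-D [N x D]")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("feature frames must be finite")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def dim(self) -> int:
        return self.frames.shape[1]


@dataclass
class MelSequence:
    """Per-frame 80-band log-mel spectrogram [M x 80] at the 16 ms hop."""

    frames: np.ndarray
    hop_s: float = HOP_S
    fmin: float = MEL_FMIN
    fmax: float = MEL_FMAX

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2:
            raise ValueError("mel frames must be 2-D [M x n_mels]")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("mel frames must be finite")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def dim(self) -> int:
        return self.frames.shape[1]


@dataclass
class TonemeSequence:
    """Frame-level toneme labels (onset/nucleus/coda symbols or ``sil``)."""

    labels: list[str] = field(default_factory=list)
    hop_s: float = HOP_S

    def __len__(self) -> int:
        return len(self.labels)
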