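"""Synthetic paired silent/vocal EMG + audio corpora with known ground truth.

Real silent-speech corpora pair (a) vocal-mode recordings, where 5-channel
facial sEMG and audio are captured simultaneously, with (b) silent-mode
repetitions of the same sentence, related to the vocal take by an unknown
monotone time warp.  This module emulates exactly that structure so every
pipeline stage can be exercised end to end:

* per toneme, the vocal-mode EMG is an amplitude-modulated burst of
  band-limited (4-400 Hz) noise whose per-channel gains form a stable
  toneme-specific template (mimicking articulator-specific electrodes);
* the audio is a harmonic complex whose f0 contour encodes the Mandarin
  tone class (level / rising / dipping / falling / short level) for vowel
  nuclei, a high-band noise burst for onsets and a low nasal hum for codas;
* the silent-mode EMG is the vocal-mode EMG resampled through a random
  piecewise-linear monotone warp (slopes 0.7-1.4), scaled to 60% amplitude
  (silent articulation is weaker) with optional additive noise.

All segment durations are multiples of the 16 ms hop, so EMG feature and
mel frame counts agree exactly and the generating warp converts into an
exact ground-truth duration sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .alignment import DurationSequence
from .containers import (
    AUDIO_RATE,
    EMG_RATE,
    HOP_S,
    AudioRecording,
    EmgRecording,
    TonemeSequence,
)
from .toneme import SIL, is_vowel_toneme, split_syllable, tone_of

__all__ = [
    "SynthSpec",
    "UtteranceSample",
    "generate_utterance",
    "generate_corpus",
    "recover_tone",
]

#: a small phonetically balanced pilot inventory: all five tones, varied
#: onsets (labial/nasal/lateral/velar/alveolar), nuclei and a nasal coda
DEFAULT_SYLLABLES = (
    "ba1", "ba2", "ba3", "ba4", "ba5",
    "ma1", "mi2", "lu3", "gao4",
    "teng2", "ting1", "me5",
)

# f0 contours per tone: (start, mid, end) in Hz
_TONE_F0 = {
    1: (230.0, 230.0, 230.0),
    2: (170.0, 215.0, 270.0),
    3: (220.0, 150.0, 240.0),
    4: (290.0, 225.0, 160.0),
    5: (200.0, 200.0, 200.0),
}

_FRAME = HOP_S  # 16 ms


def _round_frames(seconds: float) -> int:
    """Round a duration to a whole number of 16 ms frames (at least 1)."""
    return max(1, int(round(seconds / _FRAME)))


@dataclass
class SynthSpec:
    n_utterances: int = 20
    syllables_min: int = 2
    syllables_max: int = 5
    syllable_inventory: tuple[str, ...] = DEFAULT_SYLLABLES
    emg_rate: int = EMG_RATE
    audio_rate: int = AUDIO_RATE
    warp_slope_min: float = 0.7
    warp_slope_max: float = 1.4
    warp_segments: int = 3
    noise_snr_db: float | None = 30.0
    baseline_level: float = 0.05
    silent_scale: float = 0.6
    onset_s: float = 0.080
    vowel_s: float = 0.160
    neutral_vowel_s: float = 0.096
    coda_s: float = 0.080
    pad_s: float = 0.064
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warp_slope_min <= 0 or self.warp_slope_max < self.warp_slope_min:
            raise ValueError("warp slope range must be positive and ordered")
        if self.noise_snr_db is not None and not np.isfinite(self.noise_snr_db):
            raise ValueError("noise SNR must be finite or None")
        if not self.syllable_inventory:
            raise ValueError("syllable inventory must be non-empty")


@dataclass
class UtteranceSample:
    silent_emg: EmgRecording
    vocal_emg: EmgRecording
    audio: AudioRecording
    toneme_labels: TonemeSequence
    true_durations: DurationSequence
    true_warp: np.ndarray  # [2 x K] breakpoints: silent seconds -> vocal seconds
    transcript: list[str] = field(default_factory=list)
    uid: str = ""


def _template(symbol: str) -> tuple[np.ndarray, np.ndarray]:
    """Stable per-toneme activation template: channel gains and passbands.

    Each toneme excites the five electrodes with a fixed gain pattern and a
    toneme-specific frequency band per channel inside the 4-400 Hz EMG
    range, emulating articulator-specific muscle recruitment with distinct
    firing statistics per articulator.
    """
    rng = np.random.default_rng(zlib.crc32(symbol.encode()) & 0x7FFFFFFF)
    gains = rng.uniform(0.25, 1.0, size=5)
    # bias articulator groups: onsets load lip channels, nuclei the jaw/chin,
    # codas the submental channel
    if is_vowel_toneme(symbol):
        gains[2:4] += 0.5
        gains[4] += 0.15 * (tone_of(symbol) or 0)
    else:
        gains[0:2] += 0.5
    f_lo = rng.uniform(20.0, 260.0, size=5)
    f_hi = np.minimum(f_lo + rng.uniform(40.0, 120.0, size=5), 380.0)
    return gains, np.stack([f_lo, f_hi], axis=1)


def _emg_burst(
    rng: np.random.Generator,
    n: int,
    rate: int,
    template: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Per-channel narrowband noise bursts under a Hann envelope, [5 x n].

    The 5-channel passband pattern identifies the toneme per frame; a slow
    common amplitude modulation (recruitment fluctuation) and a
    deterministic per-channel gain ramp across the gesture give each burst
    temporal texture, so alignments stay identifiable inside long steady
    gestures.  Broadband-in-time noise carriers keep per-frame spectra
    approximately invariant under mild time warps.
    """
    gains, bands = template
    pad = rate // 10
    out = np.empty((5, n))
    for ch in range(5):
        sos = scipy.signal.butter(
            2, bands[ch], btype="bandpass", fs=rate, output="sos"
        )
        noise = rng.standard_normal(n + 2 * pad)
        band = scipy.signal.sosfiltfilt(sos, noise)[pad : pad + n]
        band /= np.sqrt(np.mean(band**2)) + 1e-12
        out[ch] = band
    # double-peaked contraction envelope: the mid-gesture dip is a sharp,
    # warp-covariant amplitude landmark that keeps within-gesture alignment
    # identifiable
    u_rel = np.arange(n) / max(n - 1, 1)
    env = 0.25 + 0.75 * np.sin(np.pi * u_rel) ** 2 * (
        0.5 + 0.5 * np.cos(4.0 * np.pi * u_rel)
    )
    sos_env = scipy.signal.butter(2, 12.0, btype="lowpass", fs=rate, output="sos")
    mod = scipy.signal.sosfiltfilt(sos_env, rng.standard_normal(n + 2 * pad))[pad : pad + n]
    mod = 1.0 + 0.25 * mod / (np.std(mod) + 1e-12)
    env = env * np.clip(mod, 0.2, 2.0)
    # deterministic onset->offset gain drift per channel (stable per template)
    ratio = np.array(
        [
            0.6 + 0.8 * ((zlib.crc32(bytes(int(b[0]) + i)) % 97) / 96.0)
            for i, b in enumerate(bands)
        ]
    )
    g = gains[:, None] * (
        1.0 + (ratio[:, None] - 1.0) * np.arange(n)[None, :] / max(n - 1, 1)
    )
    return out * env[None, :] * g


def _f0_contour(tone: int, n: int, rate: int) -> np.ndarray:
    s, m, e = _TONE_F0[tone]
    half = n // 2
    f0 = np.concatenate(
        [np.linspace(s, m, half, endpoint=False), np.linspace(m, e, n - half)]
    )
    return f0


def _vowel_audio(rng: np.random.Generator, tone: int, n: int, rate: int) -> np.ndarray:
    f0 = _f0_contour(tone, n, rate)
    phase = 2.0 * np.pi * np.cumsum(f0) / rate
    y = np.zeros(n)
    for h in range(1, 9):
        y += np.sin(h * phase) / h
    env = np.hanning(n) * 0.8 + 0.2
    return 0.35 * y / np.max(np.abs(y) + 1e-12) * env


def _consonant_audio(rng: np.random.Generator, n: int, rate: int) -> np.ndarray:
    sos = scipy.signal.butter(4, [2000.0, 6000.0], btype="bandpass", fs=rate, output="sos")
    noise = rng.standard_normal(n + 512)
    band = scipy.signal.sosfiltfilt(sos, noise)[256 : 256 + n]
    return 0.12 * band / (np.max(np.abs(band)) + 1e-12) * np.hanning(n)


def _coda_audio(rng: np.random.Generator, n: int, rate: int) -> np.ndarray:
    t = np.arange(n) / rate
    y = np.sin(2 * np.pi * 140.0 * t) + 0.5 * np.sin(2 * np.pi * 280.0 * t)
    return 0.18 * y / (np.max(np.abs(y)) + 1e-12) * np.hanning(n)


def _segment_plan(spec: SynthSpec, syllables: list[str]) -> list[tuple[str, int]]:
    """(toneme label, duration in frames) per segment, vocal timeline."""
    pad_f = _round_frames(spec.pad_s)
    plan: list[tuple[str, int]] = [(SIL, pad_f)]
    for syl in syllables:
        parts = split_syllable(syl)
        for k, part in enumerate(parts):
            if is_vowel_toneme(part):
                dur = (
                    spec.neutral_vowel_s
                    if tone_of(part) == 5
                    else spec.vowel_s
                )
            elif k == 0:
                dur = spec.onset_s
            else:
                dur = spec.coda_s
            plan.append((part, _round_frames(dur)))
    plan.append((SIL, pad_f))
    return plan


def generate_utterance(spec: SynthSpec, seed: int) -> UtteranceSample:
    """One paired silent/vocal utterance with exact alignment ground truth."""
    rng = np.random.default_rng(seed)
    n_syl = int(rng.integers(spec.syllables_min, spec.syllables_max + 1))
    # no immediate repeats (phonetically balanced prompts avoid them; adjacent
    # identical gestures would also make the alignment inherently ambiguous)
    syllables: list[str] = []
    while len(syllables) < n_syl:
        cand = spec.syllable_inventory[int(rng.integers(0, len(spec.syllable_inventory)))]
        if len(spec.syllable_inventory) > 1 and syllables and cand == syllables[-1]:
            continue
        syllables.append(cand)
    plan = _segment_plan(spec, syllables)
    M = sum(f for _, f in plan)

    emg_hop = int(round(_FRAME * spec.emg_rate))
    audio_hop = int(round(_FRAME * spec.audio_rate))
    emg = np.zeros((5, M * emg_hop))
    audio = np.zeros(M * audio_hop)
    labels: list[str] = []
    pos = 0
    for sym, frames in plan:
        ne = frames * emg_hop
        na = frames * audio_hop
        s_e, s_a = pos * emg_hop, pos * audio_hop
        if sym != SIL:
            emg[:, s_e : s_e + ne] = _emg_burst(rng, ne, spec.emg_rate, _template(sym))
            if is_vowel_toneme(sym):
                audio[s_a : s_a + na] = _vowel_audio(rng, tone_of(sym), na, spec.audio_rate)
            elif sym in ("n", "ng", "r", "m"):
                audio[s_a : s_a + na] = _coda_audio(rng, na, spec.audio_rate)
            else:
                audio[s_a : s_a + na] = _consonant_audio(rng, na, spec.audio_rate)
        labels.extend([sym] * frames)
        pos += frames

    # resting muscle tone: a low-level broadband baseline over the whole
    # vocal recording; it rides along through the warp, so the alignment
    # stays identifiable even across silent stretches
    if spec.baseline_level > 0:
        emg = emg + spec.baseline_level * rng.standard_normal(emg.shape)

    # ---- monotone piecewise-linear warp: silent time -> vocal time -------
    K = spec.warp_segments
    bounds_v = np.linspace(0, M, K + 1)  # vocal frames
    slopes = rng.uniform(spec.warp_slope_min, spec.warp_slope_max, size=K)
    seg_v = np.diff(bounds_v)
    seg_s = seg_v / slopes  # silent-frame extent of each vocal chunk
    # round silent breakpoints to whole frames, keeping monotonicity
    bounds_s = np.concatenate([[0.0], np.cumsum(seg_s)])
    bounds_s = np.round(bounds_s)
    for k in range(1, K + 1):
        bounds_s[k] = max(bounds_s[k], bounds_s[k - 1] + 1)
    N = int(bounds_s[-1])

    def warp_silent_to_vocal(ts: np.ndarray) -> np.ndarray:
        return np.interp(ts, bounds_s * _FRAME, bounds_v * _FRAME)

    # silent EMG: sample vocal EMG at warped times
    t_sil = np.arange(N * emg_hop) / spec.emg_rate
    t_voc = warp_silent_to_vocal(t_sil)
    t_voc = np.clip(t_voc, 0.0, (emg.shape[1] - 1) / spec.emg_rate)
    idx = t_voc * spec.emg_rate
    silent = np.stack(
        [np.interp(idx, np.arange(emg.shape[1]), ch) for ch in emg]
    ) * spec.silent_scale
    if spec.noise_snr_db is not None:
        sig_pow = np.mean(silent**2) + 1e-20
        noise_pow = sig_pow / (10.0 ** (spec.noise_snr_db / 10.0))
        silent = silent + rng.standard_normal(silent.shape) * np.sqrt(noise_pow)
        vocal_noise = np.sqrt(noise_pow) / spec.silent_scale
        emg = emg + rng.standard_normal(emg.shape) * vocal_noise

    # ---- exact ground-truth durations from the warp ----------------------
    inv_s = bounds_v * _FRAME  # vocal breakpoints (s)
    inv_t = bounds_s * _FRAME  # silent breakpoints (s)
    # frames are center-aligned, so vocal frame j (center j*hop) maps to the
    # silent frame whose center is nearest the inverse-warped time
    centers_v = np.arange(M) * _FRAME
    silent_times = np.interp(centers_v, inv_s, inv_t)
    A = np.clip(np.round(silent_times / _FRAME).astype(np.int64), 0, N - 1) + 1
    A = np.maximum.accumulate(A)
    d = np.bincount(A - 1, minlength=N)
    durations = DurationSequence(d, source_length=N, target_length=M)

    return UtteranceSample(
        silent_emg=EmgRecording(silent, rate=spec.emg_rate, mode="silent"),
        vocal_emg=EmgRecording(emg, rate=spec.emg_rate, mode="vocal"),
        audio=AudioRecording(audio, rate=spec.audio_rate),
        toneme_labels=TonemeSequence(labels=labels, hop_s=_FRAME),
        true_durations=durations,
        true_warp=np.stack([bounds_s * _FRAME, bounds_v * _FRAME]),
        transcript=syllables,
        uid=f"utt{seed:06d}",
    )


def generate_corpus(
    spec: SynthSpec, n: int | None = None, split: tuple[int, int, int] = (8, 1, 1)
) -> dict:
    """Deterministic train/val/test corpus with an 8:1:1 default split."""
    n = spec.n_utterances if n is None else n
    total = sum(split)
    if n < total:
        raise ValueError(f"need at least {total} utterances for a {split} split")
    samples = [generate_utterance(spec, spec.seed * 100003 + i) for i in range(n)]
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * split[1] / total)))
    n_test = max(1, int(round(n * split[2] / total)))
    n_train = n - n_val - n_test
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train : n_train + n_val]]
    test = [samples[i] for i in order[n_train + n_val :]]
    manifest = {
        "seed": spec.seed,
        "n": n,
        "splits": {
            "train": [s.uid for s in train],
            "val": [s.uid for s in val],
            "test": [s.uid for s in test],
        },
        "transcripts": {s.uid: s.transcript for s in samples},
    }
    return {"train": train, "val": val, "test": test, "manifest": manifest}


# ---------------------------------------------------------------------------
# tone recoverability heuristic (sanity signal for the generated audio)


def _f0_autocorr(x: np.ndarray, rate: int) -> float:
    """Fundamental frequency of a voiced slice by autocorrelation peak."""
    x = x - x.mean()
    if np.max(np.abs(x)) < 1e-9:
        return 0.0
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    lo = int(rate / 320.0)
    hi = int(rate / 130.0)
    lag = lo + int(np.argmax(ac[lo:hi]))
    return rate / lag


def recover_tone(audio: AudioRecording, start_s: float, end_s: float) -> int:
    """Classify the tone of a vowel segment from its f0 contour shape.

    Samples short analysis windows near the start, middle and end of the
    segment (edges avoided because of the amplitude envelope) and compares
    the three pitch estimates: a dip marks tone 3, a rise tone 2, a fall
    tone 4; level contours split into tone 1 vs the short neutral tone 5
    by duration.
    """
    rate = audio.rate
    seg = audio.samples[int(start_s * rate) : int(end_s * rate)]
    win = max(min(int(0.040 * rate), seg.size // 3), 32)

    def f0_at(frac: float) -> float:
        c = int(frac * seg.size)
        lo = max(0, c - win // 2)
        return _f0_autocorr(seg[lo : lo + win], rate)

    f_start, f_mid, f_end = f0_at(0.12), f0_at(0.5), f0_at(0.88)
    dur = end_s - start_s
    if f_mid < min(f_start, f_end) * 0.85:
        return 3
    if f_end > f_start * 1.15:
        return 2
    if f_end < f_start * 0.85:
        return 4
    return 5 if dur <= 0.12 else 1
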