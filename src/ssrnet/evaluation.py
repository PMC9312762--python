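"""Objective evaluation of reconstructed speech.

Metrics:

* ``cer`` — character error rate: Levenshtein edit distance divided by the
  reference length.  Unbounded above (a hypothesis may insert arbitrarily
  many characters).
* ``mcd`` — mel-cepstral distortion in dB: DTW-aligned frame-wise
  (10 / ln 10) * sqrt(2) * ||c_ref - c_hyp|| over 13 mel-cepstral
  coefficients with c0 excluded.
* ``stoi_score`` — short-time objective intelligibility (Taal et al. 2011):
  one-third-octave band envelope correlations over 384 ms segments after
  silent-frame removal; higher is more intelligible.
* ``toneme_confusion`` — frame-level consonant / vowel / tone confusion
  matrices, silence-true frames excluded, each column normalized to
  percentages of its true-label count.
"""

from __future__ import annotations

import numpy as np
import scipy.fft
import scipy.signal

import edlib

from .alignment import dtw
from .containers import AudioRecording, TonemeSequence
from .sigproc import extract_mel
from .toneme import SIL, is_vowel_toneme, tone_of

__all__ = ["cer", "mcd", "stoi_score", "toneme_confusion", "levenshtein"]


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two unicode strings (delegated to edlib)."""
    if not a and not b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b)["editDistance"])


def cer(reference: str, hypothesis: str) -> float:
    """Character error rate = Levenshtein(ref, hyp) / len(ref); may exceed 1."""
    if len(reference) == 0:
        raise ValueError("reference must be non-empty")
    return levenshtein(reference, hypothesis) / len(reference)


def _mel_cepstra(audio: AudioRecording, n_coeffs: int = 13) -> np.ndarray:
    """Mel-cepstral coefficients c1..c13 per frame (c0 excluded)."""
    logmel = extract_mel(audio, allow_resample=True).frames
    cep = scipy.fft.dct(logmel, type=2, norm="ortho", axis=1)
    return cep[:, 1 : n_coeffs + 1]


_MCD_CONST = 10.0 / np.log(10.0) * np.sqrt(2.0)


def mcd(ref_audio: AudioRecording, hyp_audio: AudioRecording) -> float:
    """Mel-cepstral distortion (dB), DTW-aligned mean over frame pairs."""
    if ref_audio.rate != hyp_audio.rate:
        raise ValueError("sample rates must match")
    c_ref = _mel_cepstra(ref_audio)
    c_hyp = _mel_cepstra(hyp_audio)
    if c_ref.shape[0] < 1 or c_hyp.shape[0] < 1:
        raise ValueError("signal too short for one analysis frame")
    align = dtw(c_ref, c_hyp)
    dists = [
        np.linalg.norm(c_ref[i - 1] - c_hyp[j - 1]) for i, j in align.path
    ]
    return float(_MCD_CONST * np.mean(dists))


# ---------------------------------------------------------------------------
# short-time objective intelligibility


_STOI_RATE = 10000
_STOI_FRAME = 256
_STOI_HOP = 128
_STOI_NFFT = 512
_STOI_NBANDS = 15
_STOI_SEG = 30  # frames per segment (384 ms)
_STOI_BETA = -15.0  # lower signal-to-distortion bound, dB
_STOI_DYN_RANGE = 40.0  # silent-frame removal threshold, dB


def _third_octave_bands(rate: int, nfft: int, n_bands: int, fmin: float = 150.0):
    f = np.linspace(0, rate / 2, nfft // 2 + 1)
    cf = fmin * 2.0 ** (np.arange(n_bands) / 3.0)
    lo = cf * 2.0 ** (-1.0 / 6.0)
    hi = cf * 2.0 ** (1.0 / 6.0)
    H = np.zeros((n_bands, f.size))
    for i in range(n_bands):
        H[i, (f >= lo[i]) & (f < hi[i])] = 1.0
    return H


def _stoi_frames(x: np.ndarray) -> np.ndarray:
    n = 1 + (x.size - _STOI_FRAME) // _STOI_HOP
    if n < 1:
        raise ValueError("signal too short for STOI analysis")
    idx = np.arange(n)[:, None] * _STOI_HOP + np.arange(_STOI_FRAME)[None, :]
    return x[idx] * np.hanning(_STOI_FRAME)


def stoi_score(ref_audio: AudioRecording, hyp_audio: AudioRecording) -> float:
    """Short-time objective intelligibility of hyp against clean ref."""
    if ref_audio.rate != hyp_audio.rate:
        raise ValueError("sample rates must match")
    if min(ref_audio.duration_s, hyp_audio.duration_s) < 0.5:
        raise ValueError("STOI needs at least 0.5 s of audio")
    n = min(ref_audio.samples.size, hyp_audio.samples.size)
    x = scipy.signal.resample_poly(ref_audio.samples[:n], _STOI_RATE, ref_audio.rate)
    y = scipy.signal.resample_poly(hyp_audio.samples[:n], _STOI_RATE, hyp_audio.rate)

    xf = _stoi_frames(x)
    yf = _stoi_frames(y)
    energy = 20.0 * np.log10(np.linalg.norm(xf, axis=1) + 1e-12)
    keep = energy > energy.max() - _STOI_DYN_RANGE
    xf, yf = xf[keep], yf[keep]
    if xf.shape[0] < _STOI_SEG:
        raise ValueError("too few active frames for STOI")

    X = np.abs(np.fft.rfft(xf, n=_STOI_NFFT, axis=1))
    Y = np.abs(np.fft.rfft(yf, n=_STOI_NFFT, axis=1))
    H = _third_octave_bands(_STOI_RATE, _STOI_NFFT, _STOI_NBANDS)
    Xb = np.sqrt((X**2) @ H.T)  # [frames x bands]
    Yb = np.sqrt((Y**2) @ H.T)

    scores = []
    clip = 10.0 ** (-_STOI_BETA / 20.0)
    for m in range(_STOI_SEG, Xb.shape[0] + 1):
        xs = Xb[m - _STOI_SEG : m]  # [seg x bands]
        ys = Yb[m - _STOI_SEG : m]
        alpha = np.linalg.norm(xs, axis=0) / (np.linalg.norm(ys, axis=0) + 1e-12)
        ysn = np.minimum(ys * alpha, xs * (1.0 + clip) + 1e-12)
        xc = xs - xs.mean(axis=0)
        yc = ysn - ysn.mean(axis=0)
        num = (xc * yc).sum(axis=0)
        den = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc, axis=0) + 1e-12
        scores.append(num / den)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# frame-level toneme confusion


def _confusion(
    true_labels: list[str], pred_labels: list[str], classes: list[str]
) -> np.ndarray:
    """Column-normalized percentage matrix [pred (+other) x true]."""
    counts = np.zeros((len(classes) + 1, len(classes)))
    cindex = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true_labels, pred_labels):
        j = cindex[t]
        i = cindex.get(p, len(classes))  # off-set predictions -> "other" row
        counts[i, j] += 1.0
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / col
    pct[:, col == 0] = 0.0
    return pct


def toneme_confusion(
    true_tm: TonemeSequence,
    pred_tm: TonemeSequence,
    display_threshold_pct: float = 0.5,
) -> dict:
    """Consonant, vowel and tone confusion matrices plus tone accuracy.

    Frames whose true label is silence are dropped.  Each matrix column is
    normalized to percentages of the true-label frame count; a ``display``
    copy masks entries below ``display_threshold_pct``.  The tone matrix is
    restricted to frames whose true label is a vowel; tone accuracy is both
    the macro average (mean of the tone-matrix diagonal) and the micro
    average (fraction of vowel frames with the tone predicted correctly).
    """
    if len(true_tm) != len(pred_tm):
        raise ValueError("label sequences must have equal length")
    pairs = [
        (t, p) for t, p in zip(true_tm.labels, pred_tm.labels) if t != SIL
    ]
    result: dict = {"warnings": []}
    if not pairs:
        result["warnings"].append("all true frames are silence; matrices empty")
        for key in ("consonant", "vowel", "tone"):
            result[key] = {"classes": [], "matrix": np.zeros((0, 0)), "display": np.zeros((0, 0))}
        result["tone_accuracy_macro"] = float("nan")
        result["tone_accuracy_micro"] = float("nan")
        return result

    def build(subset_pairs, classes):
        mat = _confusion([t for t, _ in subset_pairs], [p for _, p in subset_pairs], classes)
        display = mat.copy()
        display[display < display_threshold_pct] = 0.0
        return {"classes": classes, "matrix": mat, "display": display}

    cons_pairs = [(t, p) for t, p in pairs if not is_vowel_toneme(t)]
    cons_classes = sorted({t for t, _ in cons_pairs})
    result["consonant"] = build(cons_pairs, cons_classes)

    vowel_pairs = [(t, p) for t, p in pairs if is_vowel_toneme(t)]
    vowel_classes = sorted({t for t, _ in vowel_pairs})
    result["vowel"] = build(vowel_pairs, vowel_classes)

    tone_pairs = [
        (str(tone_of(t)), str(tone_of(p)) if (p != SIL and is_vowel_toneme(p)) else "none")
        for t, p in vowel_pairs
    ]
    tone_classes = sorted({t for t, _ in tone_pairs})
    result["tone"] = build(tone_pairs, tone_classes)

    tm = result["tone"]["matrix"]
    if tm.size:
        diag = [tm[i, i] for i in range(len(tone_classes))]
        result["tone_accuracy_macro"] = float(np.mean(diag))
        correct = sum(1 for t, p in tone_pairs if t == p)
        result["tone_accuracy_micro"] = float(100.0 * correct / len(tone_pairs))
    else:
        result["tone_accuracy_macro"] = float("nan")
        result["tone_accuracy_micro"] = float("nan")
        result["warnings"].append("no vowel frames; tone accuracy undefined")
    return result
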