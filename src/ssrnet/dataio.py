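"""On-disk formats: WAV audio, EMG arrays with JSON sidecars, feature
archives, Praat TextGrids and corpus manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .containers import (
    AudioRecording,
    EmgFeatureSequence,
    EmgRecording,
    MelSequence,
    TonemeSequence,
)

__all__ = [
    "write_wav",
    "read_wav",
    "write_emg",
    "read_emg",
    "write_features",
    "read_features",
    "write_mel",
    "read_mel",
    "write_textgrid",
    "write_manifest",
    "read_manifest",
]


def write_wav(path: str | Path, audio: AudioRecording) -> None:
    """16-bit PCM mono WAV."""
    x = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(str(path), audio.rate, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> AudioRecording:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AudioRecording(np.asarray(data, dtype=np.float64), rate=rate)


def write_emg(path: str | Path, rec: EmgRecording) -> None:
    """NPY array [channels x time] plus a JSON sidecar {rate, mode, channels}."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), rec.samples.astype(np.float32))
    sidecar = {"rate": rec.rate, "mode": rec.mode, "channels": rec.channel_count}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_emg(path: str | Path) -> EmgRecording:
    path = Path(path)
    samples = np.load(path.with_suffix(".npy")).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EmgRecording(samples, rate=int(meta["rate"]), mode=meta["mode"])


def write_features(path: str | Path, feats: EmgFeatureSequence) -> None:
    np.savez(Path(path), frames=feats.frames, hop_s=feats.hop_s)


def read_features(path: str | Path) -> EmgFeatureSequence:
    with np.load(Path(path)) as z:
        return EmgFeatureSequence(z["frames"], hop_s=float(z["hop_s"]))


def write_mel(path: str | Path, mel: MelSequence) -> None:
    np.savez(
        Path(path), frames=mel.frames, hop_s=mel.hop_s, fmin=mel.fmin, fmax=mel.fmax
    )


def read_mel(path: str | Path) -> MelSequence:
    with np.load(Path(path)) as z:
        return MelSequence(
            z["frames"], hop_s=float(z["hop_s"]), fmin=float(z["fmin"]), fmax=float(z["fmax"])
        )


def write_textgrid(path: str | Path, seq: TonemeSequence, tier_name: str = "tonemes") -> None:
    """Long-form Praat TextGrid with one interval tier of frame labels."""
    intervals: list[tuple[float, float, str]] = []
    for j, lab in enumerate(seq.labels):
        start = j * seq.hop_s
        end = (j + 1) * seq.hop_s
        if intervals and intervals[-1][2] == lab:
            intervals[-1] = (intervals[-1][0], end, lab)
        else:
            intervals.append((start, end, lab))
    xmax = len(seq.labels) * seq.hop_s
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (s, e, lab) in enumerate(intervals, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {s:.6f}",
            f"            xmax = {e:.6f}",
            f'            text = "{lab}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
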