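"""Mandarin toneme inventory, syllable splitting and label ingestion.

A toneme is a tone-bearing phonological unit: each tone-numbered Pinyin
syllable is split into an optional onset (initial consonant cluster), a
vowel nucleus that carries the syllable's tone digit, and an optional
coda, e.g. ``teng2 -> t, e2, ng``.  Mandarin has five tones (high level,
rising, dipping, high-falling, neutral); the neutral tone is encoded as
tone 5.  Frame-level label sequences come from forced-alignment interval
annotations (Praat TextGrid, long or short form) or plain two-column
label files; frames are labeled by the interval covering their center
time, half-open on the right, with uncovered frames labeled ``sil``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .containers import HOP_S, TonemeSequence

__all__ = [
    "Toneme",
    "split_syllable",
    "build_inventory",
    "inventory_ids",
    "read_textgrid_labels",
    "read_label_file",
    "tone_of",
    "is_vowel_toneme",
    "SIL",
]

SIL = "sil"
_VOWELS = set("aeiouüv")
_SYLLABLE_RE = re.compile(r"^([^aeiouüv\d]*)([aeiouüv]+)([^aeiouüv\d]*)([1-5])$")


@dataclass(frozen=True)
class Toneme:
    symbol: str
    category: str  # "consonant" or "vowel"
    tone: int | None = None

    def __post_init__(self):
        if self.category == "vowel" and self.tone not in (1, 2, 3, 4, 5):
            raise ValueError("vowel tonemes must carry a tone in 1..5")
        if self.category == "consonant" and self.tone is not None:
            raise ValueError("consonant tonemes carry no tone")


def split_syllable(pinyin_with_tone: str) -> list[str]:
    """Split a tone-numbered Pinyin syllable into onset / toned nucleus / coda.

    The nucleus is the maximal run of vowel letters (glides included) and
    receives the tone digit; onset and coda are the flanking consonant
    letters.  ``teng2 -> ['t', 'e2', 'ng']``, ``a1 -> ['a1']``.
    """
    s = pinyin_with_tone.strip().lower()
    m = _SYLLABLE_RE.match(s)
    if not m:
        raise ValueError(
            f"malformed syllable {pinyin_with_tone!r}: expected onset? + vowels + coda? + tone 1-5"
        )
    onset, nucleus, coda, tone = m.groups()
    parts = []
    if onset:
        parts.append(onset)
    parts.append(nucleus + tone)
    if coda:
        parts.append(coda)
    return parts


def tone_of(label: str) -> int | None:
    """Tone digit of a vowel toneme; None for consonants and sil."""
    if not label:
        raise ValueError("empty toneme label")
    if label == SIL:
        return None
    if label[-1].isdigit():
        if label[-1] not in "12345" or not all(c in _VOWELS for c in label[:-1]):
            raise ValueError(f"malformed toneme label {label!r}")
        return int(label[-1])
    return None


def is_vowel_toneme(label: str) -> bool:
    return label != SIL and label[-1].isdigit()


def build_inventory(corpus_syllables) -> dict[str, int]:
    """De-duplicated sorted toneme set plus ``sil``, with stable ids.

    ``sil`` always takes id 0; remaining tonemes are sorted alphabetically
    so ids form a bijection onto 0..K.
    """
    tonemes = set()
    for syl in corpus_syllables:
        tonemes.update(split_syllable(syl))
    inv = {SIL: 0}
    for i, t in enumerate(sorted(tonemes), start=1):
        inv[t] = i
    return inv


def inventory_ids(seq: TonemeSequence, inventory: dict[str, int]):
    unknown = sorted({l for l in seq.labels if l not in inventory})
    if unknown:
        raise ValueError(f"labels outside inventory: {unknown}")
    return [inventory[l] for l in seq.labels]


# ---------------------------------------------------------------------------
# interval annotations -> frame labels


def _frames_from_intervals(
    intervals: list[tuple[float, float, str]],
    hop_s: float,
    total_frames: int,
    inventory: dict[str, int] | None,
) -> TonemeSequence:
    intervals = sorted(intervals, key=lambda iv: iv[0])
    for (s1, e1, _), (s2, _, _) in zip(intervals, intervals[1:]):
        if s2 < e1 - 1e-9:
            raise ValueError(f"overlapping intervals at {s2:.3f}s")
    if inventory is not None:
        unknown = sorted(
            {lab for _, _, lab in intervals if lab and lab not in inventory}
        )
        if unknown:
            raise ValueError(f"labels outside inventory: {unknown}")
    labels = []
    for j in range(total_frames):
        center = j * hop_s
        lab = SIL
        for start, end, name in intervals:
            # half-open [start, end): a boundary exactly at the center
            # belongs to the later interval
            if start <= center < end and name:
                lab = name
                break
        labels.append(lab)
    return TonemeSequence(labels=labels, hop_s=hop_s)


_NUM = r"[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?"


def _parse_textgrid(text: str) -> list[tuple[float, float, str]]:
    """Intervals of the first interval tier of a TextGrid (long/short form)."""
    if "ooTextFile" not in text or "TextGrid" not in text:
        raise ValueError("not a Praat TextGrid file")
    intervals: list[tuple[float, float, str]] = []
    if re.search(r"intervals\s*\[\d+\]", text):
        # Long form: keyed interval blocks.  Restrict to the first tier.
        tier_starts = [m.start() for m in re.finditer(r"item\s*\[\d+\]", text)]
        if len(tier_starts) > 1:
            text = text[: tier_starts[1]]
        pat = re.compile(
            r"xmin\s*=\s*(" + _NUM + r")\s*\n\s*xmax\s*=\s*(" + _NUM + r")"
            r'\s*\n\s*text\s*=\s*"((?:[^"]|"")*)"'
        )
        for m in pat.finditer(text):
            xmin, xmax, lab = float(m.group(1)), float(m.group(2)), m.group(3)
            if xmax > xmin:
                intervals.append((xmin, xmax, lab.replace('""', '"').strip()))
    else:
        # Short form: a flat stream of quoted strings and numbers.
        toks = re.findall(r'"(?:[^"]|"")*"|' + _NUM, text)
        seq: list[tuple[str, object]] = []
        for t in toks:
            if t.startswith('"'):
                seq.append(("str", t[1:-1].replace('""', '"')))
            else:
                seq.append(("num", float(t)))
        try:
            idx = next(
                i for i, (k, v) in enumerate(seq) if k == "str" and v == "IntervalTier"
            )
        except StopIteration:
            raise ValueError("no interval tier found in TextGrid") from None
        i = idx + 1
        if i < len(seq) and seq[i][0] == "str":
            i += 1  # tier name
        skipped = 0
        while i < len(seq) and skipped < 3 and seq[i][0] == "num":
            i += 1  # tier xmin, xmax, interval count
            skipped += 1
        while (
            i + 2 < len(seq)
            and seq[i][0] == "num"
            and seq[i + 1][0] == "num"
            and seq[i + 2][0] == "str"
        ):
            xmin, xmax, lab = seq[i][1], seq[i + 1][1], seq[i + 2][1]
            if xmax > xmin:
                intervals.append((float(xmin), float(xmax), lab.strip()))
            i += 3
    if not intervals:
        raise ValueError("no interval tier found in TextGrid")
    return intervals


def read_textgrid_labels(
    path: str | Path,
    hop_s: float = HOP_S,
    total_frames: int | None = None,
    inventory: dict[str, int] | None = None,
) -> TonemeSequence:
    """Frame labels from a Praat TextGrid's first interval tier."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        intervals = _parse_textgrid(text)
    except ValueError:
        raise
    except Exception as exc:  # malformed numeric layout etc.
        raise ValueError(f"unparseable TextGrid {path}: {exc}") from exc
    if total_frames is None:
        total_frames = int(round(max(e for _, e, _ in intervals) / hop_s))
    return _frames_from_intervals(intervals, hop_s, total_frames, inventory)


def read_label_file(
    path: str | Path,
    hop_s: float = HOP_S,
    total_frames: int | None = None,
    inventory: dict[str, int] | None = None,
) -> TonemeSequence:
    """Frame labels from a plain ``start_s end_s label`` text file."""
    intervals = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"bad label line {line!r}; expected 'start end label'")
        intervals.append((float(parts[0]), float(parts[1]), parts[2]))
    if not intervals:
        raise ValueError(f"no intervals in {path}")
    if total_frames is None:
        total_frames = int(round(max(e for _, e, _ in intervals) / hop_s))
    return _frames_from_intervals(intervals, hop_s, total_frames, inventory)
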