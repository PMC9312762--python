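"""Duration extraction by dynamic time warping, and length regulation.

Silent-mode EMG has no time-aligned audio.  The silent feature sequence
X[1..N] is aligned to the vocal-mode feature sequence x[1..M] by DTW with
cost(i, j) = ||X[i] - x[j]||; the monotone path is collapsed to a frame
assignment A[1..M] (one source frame per vocal frame), and per-source-frame
durations d[i] = #{j : A[j] = i}, so sum(d) = M.  A refined cost adds a
weighted distance between the model's unregulated mel prediction and the
true mel, pulling the alignment toward acoustically plausible warps.

The length regulator repeats hidden frame i exactly d[i] times, expanding
an N-length sequence to an M = sum(d) length one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.spatial.distance

from .containers import EmgFeatureSequence, MelSequence

__all__ = [
    "AlignmentResult",
    "DurationSequence",
    "dtw",
    "refined_cost",
    "assignment_from_path",
    "durations_from_assignment",
    "length_regulate",
]


@dataclass
class AlignmentResult:
    """A DTW path with its collapsed frame assignment.

    ``path`` is a list of 1-based (i, j) pairs from (1, 1) to (N, M), each
    step incrementing i, j or both; ``assignment`` gives, for every target
    frame j, the single source frame assigned to it (first visit along the
    path); ``cost`` is the accumulated path cost.
    """

    path: list[tuple[int, int]]
    assignment: np.ndarray
    cost: float

    def to_json(self) -> str:
        d = durations_from_assignment(self.assignment, self.path[-1][0])
        return json.dumps(
            {
                "path": [list(p) for p in self.path],
                "assignment": [int(a) for a in self.assignment],
                "durations": [int(v) for v in d.d],
                "cost": float(self.cost),
            }
        )


@dataclass
class DurationSequence:
    """Non-negative integer frame durations d[1..N] with sum(d) = M."""

    d: np.ndarray
    source_length: int = 0
    target_length: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.int64)
        if np.any(self.d < 0):
            raise ValueError("durations must be non-negative")
        if self.source_length == 0:
            self.source_length = int(self.d.size)
        if self.target_length == 0:
            self.target_length = int(self.d.sum())
        if self.d.size != self.source_length:
            raise ValueError("duration length must equal source length")
        if int(self.d.sum()) != self.target_length:
            raise ValueError("sum of durations must equal target length")

    def __len__(self) -> int:
        return int(self.d.size)


def _as_matrix(seq) -> np.ndarray:
    if isinstance(seq, (EmgFeatureSequence, MelSequence)):
        return seq.frames
    return np.asarray(seq, dtype=np.float64)


def pairwise_distance(X, x) -> np.ndarray:
    """Euclidean distance matrix [N x M] between two feature sequences."""
    A, B = _as_matrix(X), _as_matrix(x)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions must match")
    return scipy.spatial.distance.cdist(A, B, metric="euclidean")


def dtw(X, x, extra: np.ndarray | None = None) -> AlignmentResult:
    """Align X[1..N] to x[1..M] with steps {(1,0),(0,1),(1,1)}.

    The accumulated cost D[i,j] = cost(i,j) + min of the three predecessors;
    ties prefer the diagonal step, then horizontal (advance i), then
    vertical.  ``extra`` is an optional additive [N x M] cost term.
    """
    cost = pairwise_distance(X, x)
    N, M = cost.shape
    if N < 1 or M < 1:
        raise ValueError("sequences must be non-empty")
    if extra is not None:
        extra = np.asarray(extra, dtype=np.float64)
        if extra.shape != (N, M):
            raise ValueError(f"extra cost must be shape {(N, M)}")
        cost = cost + extra

    D = np.full((N, M), np.inf)
    # step code: 0 diagonal (i-1,j-1), 1 horizontal (i-1,j), 2 vertical (i,j-1)
    step = np.zeros((N, M), dtype=np.int8)
    D[0, 0] = cost[0, 0]
    for i in range(1, N):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        step[i, 0] = 1
    for j in range(1, M):
        D[0, j] = D[0, j - 1] + cost[0, j]
        step[0, j] = 2
    for i in range(1, N):
        ci = cost[i]
        for j in range(1, M):
            best = D[i - 1, j - 1]
            s = 0
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                s = 1
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                s = 2
            D[i, j] = ci[j] + best
            step[i, j] = s

    path = []
    i, j = N - 1, M - 1
    while True:
        path.append((i + 1, j + 1))
        if i == 0 and j == 0:
            break
        s = step[i, j]
        if s == 0:
            i, j = i - 1, j - 1
        elif s == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    assignment = assignment_from_path(path)
    return AlignmentResult(path=path, assignment=assignment, cost=float(D[N - 1, M - 1]))


def refined_cost(X, x, y_pred: MelSequence, y_true: MelSequence, lambda_align: float = 10.0) -> np.ndarray:
    """EMG distance plus weighted predicted-vs-true mel distance, [N x M].

    ``y_pred`` is the unregulated N-length mel prediction; ``y_true`` the
    M-length mel of the vocal recording.  With lambda_align = 0 this reduces
    to the plain EMG feature distance.
    """
    base = pairwise_distance(X, x)
    N, M = base.shape
    yp, yt = _as_matrix(y_pred), _as_matrix(y_true)
    if yp.shape[0] != N:
        raise ValueError(f"y_pred has {yp.shape[0]} frames, expected N={N}")
    if yt.shape[0] != M:
        raise ValueError(f"y_true has {yt.shape[0]} frames, expected M={M}")
    return base + lambda_align * pairwise_distance(yp, yt)


def assignment_from_path(path) -> np.ndarray:
    """Collapse a DTW path to A[1..M]: first source index visiting column j.

    Source frames traversed only by (1,0) steps are skipped by every column
    and therefore receive duration zero.
    """
    M = path[-1][1]
    A = np.zeros(M, dtype=np.int64)
    for i, j in path:
        if A[j - 1] == 0:
            A[j - 1] = i
    return A


def durations_from_assignment(assignment, N: int) -> DurationSequence:
    """Invert an assignment into per-source durations d[i] = #{j: A[j] = i}."""
    A = np.asarray(assignment, dtype=np.int64)
    if A.size == 0:
        raise ValueError("assignment must be non-empty")
    if np.any(A < 1) or np.any(A > N):
        raise ValueError("assignment values must lie in [1, N]")
    if np.any(np.diff(A) < 0):
        raise ValueError("assignment must be non-decreasing")
    d = np.bincount(A - 1, minlength=N)
    return DurationSequence(d, source_length=N, target_length=int(A.size))


def length_regulate(h: np.ndarray, d) -> np.ndarray:
    """Repeat hidden frame i d[i] times: [N x H] -> [sum(d) x H]."""
    if isinstance(d, DurationSequence):
        d = d.d
    d = np.asarray(d, dtype=np.int64)
    h = np.asarray(h)
    if h.shape[0] != d.size:
        raise ValueError("duration length must match number of hidden frames")
    if np.any(d < 0):
        raise ValueError("durations must be non-negative")
    if int(d.sum()) == 0:
        raise ValueError("total duration is zero; nothing to emit")
    return np.repeat(h, d, axis=0)
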