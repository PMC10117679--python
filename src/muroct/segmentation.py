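"""Per-sample classification of B-scans and monotone boundary extraction.

A segmented volume assigns every axial sample one of 10 classes: vitreous
(0), the eight retinal layers inner-to-outer (1..8), and sub-RPE tissue (9).
Class maps come either from the trained encoder-decoder network
(:mod:`muroct.unet`) or from ground truth (:func:`oracle_classmap`), which
lets downstream stages be validated independently of network quality.

Raw per-sample classifications need not respect the anatomical ordering of
the layers. :func:`monotone_cuts` projects them onto the nearest valid
layering: per A-scan it finds cut positions 0 <= c0 <= ... <= c8 <= n that
maximise the total score of the induced monotone labeling, by dynamic
programming in O(n_samples x classes). Among ties it returns the
lexicographically smallest cut vector (layers pushed upward), so the result
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phantom import GroundTruth

__all__ = [
    "ClassMap",
    "BoundarySet",
    "N_CLASSES",
    "oracle_classmap",
    "monotone_cuts",
    "boundaries_from_classmap",
]

#: vitreous + 8 layers + sub-RPE
N_CLASSES = 10


@dataclass
class ClassMap:
    """Per-sample class labels for a volume, plus optional per-class scores.

    ``labels``: (n_bscans, n_ascans, n_samples) integers in 0..9.
    ``scores``: optional (n_bscans, n_ascans, n_samples, 10) array (e.g.
    softmax probabilities) retained for the boundary-projection step.
    """

    labels: np.ndarray
    scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError(f"labels must be 3-D, got {lab.shape}")
        if lab.min() < 0 or lab.max() >= N_CLASSES:
            raise ValueError("labels must lie in 0..9")
        self.labels = lab
        if self.scores is not None and self.scores.shape != lab.shape + (N_CLASSES,):
            raise ValueError("scores must be labels.shape + (10,)")


@dataclass
class BoundarySet:
    """Nine boundary surfaces over the en-face grid, in axial sample units.

    Where ``valid``, b0 <= b1 <= ... <= b8 (equality means a locally absent
    layer) and all values lie in [0, n_samples].
    """

    boundaries: np.ndarray  # (9, n_bscans, n_ascans)
    valid: np.ndarray  # (n_bscans, n_ascans) bool

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if b.ndim != 3 or b.shape[0] != 9:
            raise ValueError(f"boundaries must be (9, H, W), got {b.shape}")
        v = np.asarray(self.valid, bool)
        if v.shape != b.shape[1:]:
            raise ValueError("valid mask shape mismatch")
        if v.any() and np.any(np.diff(b[:, v], axis=0) < 0):
            raise ValueError("valid boundaries must be non-decreasing")
        self.boundaries = b
        self.valid = v


def oracle_classmap(truth: GroundTruth, n_samples: int) -> ClassMap:
    """Exact class map implied by ground-truth boundaries.

    Sample s of an A-scan gets class k iff b_k <= s < b_{k+1}; class 0 above
    b_0 and class 9 at/below b_8.
    """
    b = truth.boundaries  # (9, H, W)
    _, h, w = b.shape
    s = np.arange(n_samples)
    labels = np.empty((h, w, n_samples), np.uint8)
    for i in range(h):
        labels[i] = (s[None, :] >= np.ceil(b[:, i, :, None])).sum(axis=0)
    return ClassMap(labels)


def _cuts_for_chunk(scores: np.ndarray) -> np.ndarray:
    """DP over one chunk of A-scans: scores (m, n, K) -> cuts (m, K-1)."""
    m, n, K = scores.shape
    s32 = np.ascontiguousarray(scores, dtype=np.float32)
    # suffix values: T[s, :, c] = best score of samples s..n-1 with all
    # classes >= c; recurrence T[s][c] = max(S[s][c] + T[s+1][c], T[s][c+1])
    T = np.empty((n + 1, m, K), np.float32)
    T[n] = 0.0
    for s in range(n - 1, -1, -1):
        Ss = s32[:, s, :]
        T[s, :, K - 1] = Ss[:, K - 1] + T[s + 1, :, K - 1]
        for c in range(K - 2, -1, -1):
            np.maximum(Ss[:, c] + T[s + 1, :, c], T[s, :, c + 1], out=T[s, :, c])
    # greedy forward walk: advance class as early as equality of suffix
    # values permits -> lexicographically smallest cut vector among optima
    cur = np.zeros(m, np.int64)
    cuts = np.full((m, K - 1), n, np.int64)
    cls_idx = np.arange(K)
    rows = np.arange(m)
    for s in range(n):
        Ts = T[s]
        curval = Ts[rows, cur]
        # T[s, a, :] is non-increasing in class, so equality with the current
        # value is contiguous from cur; count gives the furthest class
        eq = (Ts == curval[:, None]) & (cls_idx[None, :] >= cur[:, None])
        new = cur + eq.sum(axis=1) - 1
        for k in range(K - 1):
            crossed = (cur <= k) & (new > k)
            if crossed.any():
                cuts[crossed, k] = s
        cur = new
    return cuts


def monotone_cuts(scores: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Optimal monotone cut positions for a batch of A-scans.

    ``scores``: (n_ascans, n_samples, K) finite per-class scores (hard labels
    score 1/0). Returns (n_ascans, K-1) integer cuts with
    0 <= c0 <= ... <= c_{K-2} <= n_samples; sample s receives class k iff
    c_{k-1} <= s < c_k. Always feasible — empty layers are allowed.
    """
    scores = np.asarray(scores)
    if scores.ndim != 3:
        raise ValueError(f"scores must be (n_ascans, n_samples, K), got {scores.shape}")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    out = np.empty((scores.shape[0], scores.shape[2] - 1), np.int64)
    for start in range(0, scores.shape[0], chunk):
        sl = slice(start, min(start + chunk, scores.shape[0]))
        out[sl] = _cuts_for_chunk(scores[sl])
    return out


def _one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    return (labels[..., None] == np.arange(K)).astype(np.float32)


def boundaries_from_classmap(classmap: ClassMap) -> BoundarySet:
    """Project a class map onto valid (monotone) boundary surfaces.

    Uses the per-class scores when available, else the hard labels with 1/0
    scores. The output always satisfies the monotone-boundary invariant.
    """
    h, w, n = classmap.labels.shape
    cuts = np.empty((h * w, N_CLASSES - 1), np.int64)
    for i in range(h):
        if classmap.scores is not None:
            sc = classmap.scores[i]
        else:
            sc = _one_hot(classmap.labels[i], N_CLASSES)
        cuts[i * w : (i + 1) * w] = monotone_cuts(sc)
    boundaries = cuts.reshape(h, w, N_CLASSES - 1).transpose(2, 0, 1).astype(float)
    return BoundarySet(boundaries, np.ones((h, w), bool))
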