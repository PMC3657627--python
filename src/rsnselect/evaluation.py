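"""Assessment of automatic selection against a reference labelling.

The reference is the set of component indices an expert (or the synthetic
ground truth) calls resting-state networks.  Components both selected and in
the reference are true positives; selected-only are false positives;
reference-only are false negatives; the rest are true negatives.  Accuracy
is (TP + TN) / (TP + TN + FP + FN) and precision TP / (TP + FP).

Cross-session reproducibility is supported by greedy spatial-correlation
matching of two sessions' selected maps — an objective surrogate for the
per-network expert judgement such comparisons are usually based on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MatchedPair",
    "confusion",
    "accuracy",
    "precision",
    "rounded_percent",
    "match_sessions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts over the components of one decomposition."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class MatchedPair(NamedTuple):
    index_a: int
    index_b: int
    correlation: float


def confusion(
    selected: Iterable[int], reference: Iterable[int], total: int
) -> ConfusionCounts:
    """Confusion counts of a selected set against a reference set.

    Both sets must be subsets of ``range(total)``; true negatives are the
    components in neither set, so the four counts always sum to ``total``.
    """
    selected = set(int(i) for i in selected)
    reference = set(int(i) for i in reference)
    for name, idx_set in (("selected", selected), ("reference", reference)):
        bad = [i for i in idx_set if not (0 <= i < total)]
        if bad:
            raise ValueError(f"{name} indices {sorted(bad)} outside [0, {total})")
    tp = len(selected & reference)
    fp = len(selected - reference)
    fn = len(reference - selected)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("accuracy undefined for all-zero confusion counts")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); undefined when nothing was selected."""
    if c.tp + c.fp == 0:
        raise ValueError("precision undefined: no components were selected (TP + FP == 0)")
    return c.tp / (c.tp + c.fp)


def rounded_percent(value: float) -> int:
    """A proportion as the nearest integer percent (the usual reported form)."""
    return int(round(100.0 * value))


def _correlation_matrix(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    a = maps_a - maps_a.mean(axis=1, keepdims=True)
    b = maps_b - maps_b.mean(axis=1, keepdims=True)
    a_norm = np.linalg.norm(a, axis=1)
    b_norm = np.linalg.norm(b, axis=1)
    denom = np.outer(a_norm, b_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (a @ b.T) / denom
    corr[~np.isfinite(corr)] = 0.0  # constant maps correlate with nothing
    return corr


def match_sessions(
    maps_a: np.ndarray | Sequence[np.ndarray],
    maps_b: np.ndarray | Sequence[np.ndarray],
    r_threshold: float = 0.4,
) -> list[MatchedPair]:
    """Greedy one-to-one matching of two sessions' component maps.

    ``maps_a`` and ``maps_b`` are (n_components x n_voxels) arrays on the
    same voxel grid (e.g. retained-voxel-filtered source rows).  Pairs are
    taken in order of descending Pearson spatial correlation; each map is
    matched at most once and pairs below ``r_threshold`` are dropped.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if maps_a.size == 0 or maps_b.size == 0:
        return []
    if maps_a.shape[1] != maps_b.shape[1]:
        raise ValueError(
            f"voxel grid mismatch: maps_a has {maps_a.shape[1]} voxels, "
            f"maps_b has {maps_b.shape[1]}"
        )
    corr = _correlation_matrix(maps_a, maps_b)
    pairs: list[MatchedPair] = []
    free_a = np.ones(corr.shape[0], dtype=bool)
    free_b = np.ones(corr.shape[1], dtype=bool)
    # stable order: descending correlation, then (i, j) to break exact ties
    order = sorted(
        ((i, j) for i in range(corr.shape[0]) for j in range(corr.shape[1])),
        key=lambda ij: (-corr[ij], ij),
    )
    for i, j in order:
        if corr[i, j] < r_threshold:
            break
        if free_a[i] and free_b[j]:
            pairs.append(MatchedPair(i, j, float(corr[i, j])))
            free_a[i] = False
            free_b[j] = False
    return pairs
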