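"""Steps 1-3 of the selection algorithm.

Step 1 rejects whole components whose spatial-map value distribution is
symmetric (noise-like), using Pearson's median skewness coefficient
``3 * (mean - median) / sigma`` compared against a per-run threshold (the
median of the per-component coefficients).

Step 2 filters voxels within each surviving component: the map values are
clustered by 1-D k-means (Euclidean distance on activation values), the
number of clusters is chosen by maximising the mean silhouette index, and
the cluster whose centroid lies nearest zero — the low-activation voxels —
is removed.

Step 3 cancels voxels that sit with high probability in white matter or
cerebrospinal fluid, restricting each map to gray matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .model import (
    STATUS_REJECTED_EMPTY,
    STATUS_REJECTED_SKEWNESS,
    ComponentState,
    ICADecomposition,
    SelectionConfig,
    TissueMaps,
    grid_to_vector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSolution",
    "ClusteringError",
    "pearson_coefficient",
    "skewness_threshold",
    "skewness_filter",
    "silhouette_value",
    "mean_silhouette",
    "choose_k",
    "cluster_filter",
    "tissue_filter",
]


class ClusteringError(ValueError):
    """Raised when no candidate k admits a valid partition of the values."""


@dataclass
class ClusterSolution:
    """A 1-D k-means partition together with its mean silhouette score."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    mean_silhouette: float


def pearson_coefficient(values: np.ndarray) -> float:
    """Pearson's median skewness coefficient, ``3 * (mean - median) / sigma``.

    ``sigma`` is the sample (n-1) standard deviation.  A zero-variance input
    returns 0: a constant map carries no network structure and is treated as
    maximally noise-like.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError(f"need at least 2 values, got {values.size}")
    sigma = values.std(ddof=1)
    if sigma == 0.0:
        return 0.0
    return float(3.0 * (values.mean() - np.median(values)) / sigma)


def _comparison_value(coefficient: float, mode: str) -> float:
    return abs(coefficient) if mode == "absolute" else coefficient


def skewness_threshold(coefficients: np.ndarray, cfg: SelectionConfig) -> float:
    """Per-run threshold TH: the median of the per-component coefficients."""
    if cfg.skewness_threshold_override is not None:
        return float(cfg.skewness_threshold_override)
    comp = [_comparison_value(c, cfg.skewness_mode) for c in coefficients]
    return float(np.median(comp))


def skewness_filter(dec: ICADecomposition, cfg: SelectionConfig) -> list[ComponentState]:
    """Step 1: reject components whose skewness falls strictly below TH.

    Every component receives its (signed) Pearson coefficient; the threshold
    is the median over the K per-component comparison values (absolute by
    default) unless overridden.  Components strictly below TH are rejected;
    ties survive, so K = 1 and all-identical-row inputs lose nothing.
    """
    if dec.n_components == 0:
        raise ValueError("decomposition has no components")
    coefficients = np.array([pearson_coefficient(row) for row in dec.sources])
    th = skewness_threshold(coefficients, cfg)
    logger.info("skewness threshold TH = %.6g (%s mode)", th, cfg.skewness_mode)

    states: list[ComponentState] = []
    m = dec.n_voxels
    for i, coeff in enumerate(coefficients):
        state = ComponentState(
            index=i,
            pearson_coefficient=float(coeff),
            retained_voxels=np.ones(m, dtype=bool),
        )
        state.voxel_counts["initial"] = m
        if _comparison_value(float(coeff), cfg.skewness_mode) < th:
            state.reject(
                STATUS_REJECTED_SKEWNESS,
                stage="skewness",
                reason=f"coefficient {coeff:.6g} below threshold {th:.6g}",
            )
        states.append(state)
    survivors = sum(s.is_candidate for s in states)
    logger.info("step 1: %d of %d components survive", survivors, len(states))
    return states


def silhouette_value(point_index: int, values: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette index ``(b - a) / max(a, b)`` of one point.

    ``a`` is the mean distance to the other points of the point's own
    cluster, ``b`` the smallest mean distance to any other cluster.  A point
    alone in its cluster scores 0 by convention; coincident clusters
    (a = b = 0) also score 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    own = labels[point_index]
    v = values[point_index]
    same = values[labels == own]
    if same.size <= 1:
        return 0.0
    a = (np.abs(same - v).sum()) / (same.size - 1)
    b = min(np.abs(values[labels == other] - v).mean() for other in unique if other != own)
    denom = max(a, b)
    if denom == 0.0:
        return 0.0
    return float((b - a) / denom)


def _cluster_prefix_tables(values: np.ndarray, labels: np.ndarray, unique: np.ndarray):
    """Sorted values + prefix sums per cluster, for O(log n) mean distances."""
    tables = {}
    for lab in unique:
        member = np.sort(values[labels == lab])
        prefix = np.concatenate(([0.0], np.cumsum(member)))
        tables[lab] = (member, prefix)
    return tables


def _sum_abs_dist(v: float, member: np.ndarray, prefix: np.ndarray) -> float:
    """Sum of |v - y| over the sorted array ``member`` via prefix sums."""
    idx = int(np.searchsorted(member, v))
    left = v * idx - prefix[idx]
    right = (prefix[-1] - prefix[idx]) - v * (member.size - idx)
    return left + right


def mean_silhouette(
    values: np.ndarray,
    labels: np.ndarray,
    subsample: int | None = None,
    seed: int = 0,
) -> float:
    """Mean silhouette over (a deterministic subsample of) the points.

    Exact when the point count is at or below ``subsample``; above it, the
    scored points are a fixed-seed draw but distances are still taken to all
    points.  Agrees with averaging :func:`silhouette_value` over the scored
    points (same formula, faster evaluation via sorted prefix sums).
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = values.size
    if subsample is not None and n > subsample:
        rng = np.random.default_rng(seed)
        scored = np.sort(rng.choice(n, size=subsample, replace=False))
    else:
        scored = np.arange(n)

    tables = _cluster_prefix_tables(values, labels, unique)
    sizes = {lab: int((labels == lab).sum()) for lab in unique}
    total = 0.0
    for j in scored:
        v = values[j]
        own = labels[j]
        if sizes[own] <= 1:
            continue  # singleton convention: contributes 0
        a = _sum_abs_dist(v, *tables[own]) / (sizes[own] - 1)
        b = min(
            _sum_abs_dist(v, *tables[lab]) / sizes[lab]
            for lab in unique
            if lab != own
        )
        denom = max(a, b)
        if denom > 0.0:
            total += (b - a) / denom
    return float(total / scored.size)


def choose_k(values: np.ndarray, cfg: SelectionConfig) -> ClusterSolution:
    """Cluster 1-D activation values, choosing k by maximal mean silhouette.

    Runs k-means (k-means++ seeding, 10 restarts, fixed seed) for every
    candidate k not exceeding the number of distinct values, scores each
    partition by mean silhouette, and returns the best; ties break toward
    smaller k.  Raises :class:`ClusteringError` when no candidate k is
    feasible (fewer distinct values than every candidate).
    """
    values = np.asarray(values, dtype=float).ravel()
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    n_distinct = np.unique(values).size
    feasible = sorted(int(k) for k in cfg.k_candidates if int(k) <= n_distinct)
    if not feasible:
        raise ClusteringError(
            f"only {n_distinct} distinct values; no candidate k in "
            f"{sorted(cfg.k_candidates)} admits a partition"
        )

    x = values.reshape(-1, 1)
    best: ClusterSolution | None = None
    for k in feasible:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=10,
            max_iter=300,
            tol=1e-6,
            random_state=cfg.kmeans_seed,
        ).fit(x)
        labels = km.labels_.astype(int)
        # recompute centroids as exact member means (Lloyd guarantees this
        # at convergence; enforce it so the invariant holds bit-for-bit)
        centroids = np.array([values[labels == c].mean() for c in range(k)])
        sil = mean_silhouette(
            values, labels, subsample=cfg.silhouette_subsample, seed=cfg.kmeans_seed
        )
        if best is None or sil > best.mean_silhouette:
            best = ClusterSolution(k=k, labels=labels, centroids=centroids, mean_silhouette=sil)
    assert best is not None
    return best


def cluster_filter(
    state: ComponentState, dec: ICADecomposition, cfg: SelectionConfig
) -> ComponentState:
    """Step 2: drop the voxels of the cluster whose centroid is nearest 0.

    Clustering runs on the component's currently retained voxel values.  If
    the values are too degenerate to cluster (fewer distinct values than any
    candidate k) the component is demoted to ``rejected_empty``.
    """
    if not state.is_candidate:
        raise ValueError(f"component {state.index} is not a candidate (status {state.status})")
    retained = np.asarray(state.retained_voxels, dtype=bool)
    values = dec.sources[state.index, retained]
    try:
        solution = choose_k(values, cfg)
    except ClusteringError as exc:
        logger.info("component %d: clustering impossible (%s)", state.index, exc)
        state.reject(STATUS_REJECTED_EMPTY, stage="clustering", reason=str(exc))
        state.voxel_counts["after_cluster"] = 0
        state.voxel_counts["after_tissue"] = 0
        return state

    eliminated_cluster = int(np.argmin(np.abs(solution.centroids)))
    keep_local = solution.labels != eliminated_cluster
    new_retained = retained.copy()
    new_retained[np.flatnonzero(retained)] = keep_local
    state.retained_voxels = new_retained
    state.chosen_k = solution.k
    state.voxel_counts["after_cluster"] = int(new_retained.sum())
    logger.info(
        "component %d: k=%d (silhouette %.4f), removed cluster centroid %.4g, %d voxels kept",
        state.index,
        solution.k,
        solution.mean_silhouette,
        solution.centroids[eliminated_cluster],
        state.voxel_counts["after_cluster"],
    )
    if state.voxel_counts["after_cluster"] == 0:
        state.reject(STATUS_REJECTED_EMPTY, stage="clustering", reason="no voxels retained")
    return state


def tissue_filter(
    state: ComponentState, tissue: TissueMaps, cfg: SelectionConfig, mask: np.ndarray
) -> ComponentState:
    """Step 3: cancel voxels that are confidently white matter or CSF.

    Under the default ``either_map`` rule a retained voxel is removed iff
    its WM probability or its CSF probability reaches the threshold
    (default 0.9); ``summed`` removes it when wm + csf reaches it.  A
    component left with no voxels is demoted to ``rejected_empty``.
    """
    if not state.is_candidate:
        raise ValueError(f"component {state.index} is not a candidate (status {state.status})")
    if tuple(tissue.grid_shape) != tuple(np.asarray(mask).shape):
        raise ValueError(
            f"tissue grid {tuple(tissue.grid_shape)} does not match "
            f"decomposition grid {tuple(np.asarray(mask).shape)}"
        )
    wm = grid_to_vector(tissue.wm, mask)
    csf = grid_to_vector(tissue.csf, mask)
    t = cfg.tissue_prob_threshold
    if cfg.tissue_rule == "either_map":
        cancelled = (wm >= t) | (csf >= t)
    elif cfg.tissue_rule == "summed":
        cancelled = (wm + csf) >= t
    else:  # pragma: no cover - config validation catches this upstream
        raise ValueError(f"unknown tissue_rule {cfg.tissue_rule!r}")

    retained = np.asarray(state.retained_voxels, dtype=bool) & ~cancelled
    state.retained_voxels = retained
    state.voxel_counts["after_tissue"] = int(retained.sum())
    logger.info(
        "component %d: %d voxels after tissue masking", state.index,
        state.voxel_counts["after_tissue"],
    )
    if state.voxel_counts["after_tissue"] == 0:
        state.reject(
            STATUS_REJECTED_EMPTY,
            stage="segmentation",
            reason="all retained voxels were high-probability WM/CSF",
        )
    return state
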