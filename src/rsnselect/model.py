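"""Core domain model for spatial-ICA component selection.

A probabilistic spatial-ICA decomposition of a resting-state fMRI run is
modelled as ``X = A S + E``: ``A`` is the N x K mixing matrix whose columns
are component time courses, ``S`` is the K x M source matrix whose rows are
spatial maps over the M in-brain voxels, and ``E`` is Gaussian noise.  The
selection pipeline never touches the raw 4-D data; every stage transforms an
:class:`ICADecomposition` plus per-component :class:`ComponentState` records.

Voxel ordering convention: in-mask voxels are linearised in Fortran order
(first axis fastest), matching the in-file layout of NIfTI volumes.  Column
``m`` of ``S`` therefore always refers to the same grid position across I/O
round trips; :func:`flat_mask_indices`, :func:`grid_to_vector` and
:func:`vector_to_grid` are the only places this convention is encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ICADecomposition",
    "TissueMaps",
    "ComponentState",
    "SelectionConfig",
    "STATUS_CANDIDATE",
    "STATUS_REJECTED_SKEWNESS",
    "STATUS_REJECTED_EMPTY",
    "STATUS_REJECTED_SPECTRAL",
    "STATUS_SELECTED",
    "REJECTED_STATUSES",
    "flat_mask_indices",
    "grid_to_vector",
    "vector_to_grid",
    "validate_decomposition",
    "validate_tissue_maps",
]

STATUS_CANDIDATE = "candidate"
STATUS_REJECTED_SKEWNESS = "rejected_skewness"
STATUS_REJECTED_EMPTY = "rejected_empty"
STATUS_REJECTED_SPECTRAL = "rejected_spectral"
STATUS_SELECTED = "selected"

REJECTED_STATUSES = frozenset(
    {STATUS_REJECTED_SKEWNESS, STATUS_REJECTED_EMPTY, STATUS_REJECTED_SPECTRAL}
)
_TERMINAL_STATUSES = REJECTED_STATUSES | {STATUS_SELECTED}


def flat_mask_indices(mask: np.ndarray) -> np.ndarray:
    """Flat (Fortran-order) grid indices of the true voxels of ``mask``."""
    return np.flatnonzero(np.asarray(mask, dtype=bool).ravel(order="F"))


def grid_to_vector(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract the in-mask values of a 3-D volume as a length-M vector."""
    volume = np.asarray(volume)
    if volume.shape != np.asarray(mask).shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask shape {np.asarray(mask).shape}"
        )
    return volume.ravel(order="F")[flat_mask_indices(mask)]


def vector_to_grid(vector: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Scatter a length-M voxel vector back onto the 3-D grid."""
    mask = np.asarray(mask, dtype=bool)
    idx = flat_mask_indices(mask)
    vector = np.asarray(vector)
    if vector.shape != (idx.size,):
        raise ValueError(
            f"vector length {vector.shape} does not match mask voxel count {idx.size}"
        )
    flat = np.full(mask.size, fill, dtype=np.result_type(vector.dtype, type(fill)))
    flat[idx] = vector
    return flat.reshape(mask.shape, order="F")


@dataclass
class ICADecomposition:
    """A spatial-ICA decomposition: mixing matrix, source maps, brain mask, TR.

    Parameters
    ----------
    mixing:
        N x K matrix; column ``k`` is the time course of component ``k``.
    sources:
        K x M matrix; row ``k`` holds the spatial map of component ``k``
        over the M in-mask voxels, in Fortran-order voxel linearisation.
    mask:
        Boolean 3-D brain mask with exactly M true voxels.
    tr_seconds:
        Repetition time (sampling interval) in seconds; must be positive.
    """

    mixing: np.ndarray
    sources: np.ndarray
    mask: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.sources = np.asarray(self.sources, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_timepoints(self) -> int:
        return int(self.mixing.shape[0])

    @property
    def n_components(self) -> int:
        return int(self.mixing.shape[1]) if self.mixing.ndim == 2 else 0

    @property
    def n_voxels(self) -> int:
        return int(self.sources.shape[1]) if self.sources.ndim == 2 else 0

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def component_map(self, index: int, fill: float = 0.0) -> np.ndarray:
        """Spatial map of one component as a 3-D volume."""
        return vector_to_grid(self.sources[index], self.mask, fill=fill)


@dataclass
class TissueMaps:
    """Per-voxel gray-matter / white-matter / CSF probabilities.

    All three grids share the decomposition's shape; values lie in [0, 1]
    and sum to at most 1 (plus numerical tolerance) at each voxel.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.gm.shape)


@dataclass
class ComponentState:
    """Running record of one component's fate through the four filter steps.

    ``status`` progresses one way only: a component starts as ``candidate``
    and ends in exactly one of ``rejected_skewness`` (step 1),
    ``rejected_empty`` (steps 2-3 removed every voxel), ``rejected_spectral``
    (step 4) or ``selected``.  Once terminal, the status never changes.
    """

    index: int
    pearson_coefficient: float = 0.0
    retained_voxels: Optional[np.ndarray] = None
    band_powers: Optional["object"] = None  # spectral.BandPowers once computed
    status: str = STATUS_CANDIDATE
    rejection_stage: Optional[str] = None
    chosen_k: Optional[int] = None
    voxel_counts: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def is_candidate(self) -> bool:
        return self.status == STATUS_CANDIDATE

    @property
    def is_selected(self) -> bool:
        return self.status == STATUS_SELECTED

    def reject(self, status: str, stage: str, reason: str = "") -> None:
        if status not in REJECTED_STATUSES:
            raise ValueError(f"{status!r} is not a rejection status")
        self._transition(status, stage, reason)

    def select(self) -> None:
        self._transition(STATUS_SELECTED, None, "")

    def _transition(self, status: str, stage: Optional[str], reason: str) -> None:
        if self.status in _TERMINAL_STATUSES:
            raise ValueError(
                f"component {self.index} already terminal ({self.status}); "
                f"cannot move to {status}"
            )
        self.status = status
        self.rejection_stage = stage
        if reason:
            self.notes.append(reason)

    def retained_count(self) -> int:
        if self.retained_voxels is None:
            return 0
        return int(np.count_nonzero(self.retained_voxels))


@dataclass(frozen=True)
class SelectionConfig:
    """All tunable thresholds of the selection pipeline, with defaults.

    Attributes
    ----------
    skewness_mode:
        ``"absolute"`` compares |coefficient| to the threshold (a symmetric
        noise distribution is near zero in magnitude, so strongly left-skewed
        maps are kept too); ``"signed"`` compares the raw coefficient.
    skewness_threshold_override:
        If set, used instead of the per-run median threshold.
    k_candidates:
        Candidate numbers of clusters scanned when choosing k by mean
        silhouette.
    kmeans_seed:
        Seed for k-means initialisation and silhouette subsampling; fixes
        the whole voxel-filter stage bit-for-bit.
    silhouette_subsample:
        Cap on the number of points the mean silhouette is evaluated at
        (exact below the cap; deterministic subsample above it).
    tissue_prob_threshold:
        Probability above which a voxel counts as white matter / CSF
        (default 0.9, i.e. "at least 90% probability").
    tissue_rule:
        ``"either_map"`` removes a voxel when wm >= t OR csf >= t;
        ``"summed"`` removes it when wm + csf >= t.
    f1_hz, f2_hz:
        Band edges of the low-frequency BOLD band (defaults 0.01 and 0.1 Hz).
    p2_min, p12_min:
        Spectral acceptance thresholds: a component needs P2 >= p2_min and
        P1 + P2 >= p12_min (under the default OR rejection logic).
    reject_logic:
        ``"or"`` rejects when either spectral criterion fails; ``"and"``
        only when both fail.
    detrend_degree:
        Degree of the polynomial trend removed from each voxel time course
        before averaging (1 = linear detrend).
    """

    skewness_mode: str = "absolute"
    skewness_threshold_override: Optional[float] = None
    k_candidates: tuple = tuple(range(2, 10))
    kmeans_seed: int = 0
    silhouette_subsample: int = 5000
    tissue_prob_threshold: float = 0.9
    tissue_rule: str = "either_map"
    f1_hz: float = 0.01
    f2_hz: float = 0.1
    p2_min: float = 0.5
    p12_min: float = 0.9
    reject_logic: str = "or"
    detrend_degree: int = 1

    def validate(self, tr_seconds: Optional[float] = None) -> list[str]:
        """Return a list of violated constraints (empty if valid)."""
        problems: list[str] = []
        if self.skewness_mode not in ("absolute", "signed"):
            problems.append(f"skewness_mode must be absolute|signed, got {self.skewness_mode!r}")
        if self.tissue_rule not in ("either_map", "summed"):
            problems.append(f"tissue_rule must be either_map|summed, got {self.tissue_rule!r}")
        if self.reject_logic not in ("or", "and"):
            problems.append(f"reject_logic must be or|and, got {self.reject_logic!r}")
        if not self.k_candidates:
            problems.append("k_candidates must be non-empty")
        elif any(int(k) < 2 for k in self.k_candidates):
            problems.append("k_candidates must all be >= 2")
        if not (0.0 < self.f1_hz < self.f2_hz):
            problems.append(f"need 0 < f1_hz < f2_hz, got f1={self.f1_hz}, f2={self.f2_hz}")
        if tr_seconds is not None:
            nyq = 1.0 / (2.0 * tr_seconds)
            if not self.f2_hz < nyq:
                problems.append(
                    f"f2_hz={self.f2_hz} must be below the Nyquist frequency "
                    f"{nyq:.6g} Hz implied by tr_seconds={tr_seconds}"
                )
        for name in ("tissue_prob_threshold", "p2_min", "p12_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                problems.append(f"{name} must be in (0, 1], got {v}")
        if self.silhouette_subsample < 2:
            problems.append("silhouette_subsample must be >= 2")
        if self.detrend_degree < 0:
            problems.append("detrend_degree must be >= 0")
        return problems

    def with_overrides(self, **kwargs) -> "SelectionConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def _finite(arr: np.ndarray) -> bool:
    return bool(np.isfinite(arr).all()) if arr.size else True


def validate_decomposition(dec: ICADecomposition) -> list[str]:
    """Check every structural invariant of a decomposition.

    Validation is total: it returns a (possibly empty) list of violation
    descriptions and never raises on finite-valued input.  Each entry names
    the offending field and the broken constraint.
    """
    problems: list[str] = []
    mixing = np.asarray(dec.mixing)
    sources = np.asarray(dec.sources)
    mask = np.asarray(dec.mask)

    if mixing.ndim != 2:
        problems.append(f"mixing must be 2-D (time x components), got ndim={mixing.ndim}")
    if sources.ndim != 2:
        problems.append(f"sources must be 2-D (components x voxels), got ndim={sources.ndim}")
    if mask.ndim != 3:
        problems.append(f"mask must be a 3-D grid, got ndim={mask.ndim}")

    if mixing.ndim == 2 and sources.ndim == 2 and mixing.shape[1] != sources.shape[0]:
        problems.append(
            "component count mismatch: mixing has "
            f"{mixing.shape[1]} columns but sources has {sources.shape[0]} rows"
        )
    if sources.ndim == 2 and mask.ndim == 3:
        m_mask = int(np.count_nonzero(mask))
        if sources.shape[1] != m_mask:
            problems.append(
                f"voxel count mismatch: sources has {sources.shape[1]} columns "
                f"but mask has {m_mask} true voxels"
            )
    try:
        tr = float(dec.tr_seconds)
        if not tr > 0:
            problems.append(f"tr_seconds must be > 0, got {tr}")
    except (TypeError, ValueError):
        problems.append(f"tr_seconds must be a positive number, got {dec.tr_seconds!r}")

    if not _finite(mixing):
        problems.append("mixing contains non-finite values")
    if not _finite(sources):
        problems.append("sources contains non-finite values")
    return problems


def validate_tissue_maps(
    tissue: TissueMaps,
    grid_shape: Optional[Sequence[int]] = None,
    tolerance: float = 1e-6,
) -> list[str]:
    """Check tissue-probability invariants; empty list means valid."""
    problems: list[str] = []
    shapes = {"gm": tissue.gm.shape, "wm": tissue.wm.shape, "csf": tissue.csf.shape}
    if len(set(shapes.values())) != 1:
        problems.append(f"tissue maps have mismatched shapes: {shapes}")
        return problems
    if grid_shape is not None and tuple(tissue.gm.shape) != tuple(grid_shape):
        problems.append(
            f"tissue grid {tissue.gm.shape} does not match decomposition grid {tuple(grid_shape)}"
        )
    for name in ("gm", "wm", "csf"):
        arr = getattr(tissue, name)
        if arr.size and (arr.min() < -tolerance or arr.max() > 1 + tolerance):
            problems.append(f"{name} has values outside [0, 1]")
    total = tissue.gm + tissue.wm + tissue.csf
    if total.size and total.max() > 1 + 1e-3:
        problems.append("gm + wm + csf exceeds 1 at some voxel")
    return problems
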