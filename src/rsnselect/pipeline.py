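"""Orchestration of the four selection steps in order.

Step 1 (skewness) and step 4 (spectral) act on whole components; steps 2
(clustering) and 3 (tissue masking) act on voxels within the survivors.
Per-component failures demote that component with a logged reason instead
of aborting the run — one degenerate component must not destroy a
whole-subject analysis — while structural problems (inconsistent shapes,
invalid configuration) abort immediately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .filters import skewness_filter, skewness_threshold, cluster_filter, tissue_filter
from .io import SelectionReport
from .model import (
    ComponentState,
    ICADecomposition,
    SelectionConfig,
    TissueMaps,
    validate_decomposition,
    validate_tissue_maps,
)
from .spectral import spectral_filter

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, for all K input components."""

    states: list[ComponentState]
    report: SelectionReport
    selected_indices: list[int]
    n_components: int          # K: components in
    n_after_skewness: int      # I: survivors of step 1
    n_selected: int            # J: finally selected


def run_pipeline(
    dec: ICADecomposition, tissue: TissueMaps, cfg: SelectionConfig | None = None
) -> PipelineResult:
    """Run skewness -> clustering -> tissue masking -> spectral selection.

    Deterministic given the configuration (all randomness is seeded from
    ``cfg.kmeans_seed``).  Returns the per-component states, an audit
    report covering all K components, and the K/I/J counts.
    """
    if cfg is None:
        cfg = SelectionConfig()
    problems = validate_decomposition(dec)
    problems += validate_tissue_maps(tissue, grid_shape=dec.grid_shape)
    problems += cfg.validate(tr_seconds=dec.tr_seconds)
    if problems:
        raise ValueError("invalid pipeline input:\n  " + "\n  ".join(problems))

    states = skewness_filter(dec, cfg)
    coefficients = np.array([s.pearson_coefficient for s in states])
    threshold = skewness_threshold(coefficients, cfg)

    for state in states:
        if state.is_candidate:
            cluster_filter(state, dec, cfg)
        if state.is_candidate:
            tissue_filter(state, tissue, cfg, dec.mask)

    spectral_filter(states, dec, cfg)

    selected = [s.index for s in states if s.is_selected]
    n_after_skewness = sum(s.status != "rejected_skewness" for s in states)
    logger.info(
        "pipeline: K=%d -> I=%d -> J=%d selected %s",
        len(states), n_after_skewness, len(selected), selected,
    )
    report = SelectionReport.from_states(states, cfg, threshold)
    return PipelineResult(
        states=states,
        report=report,
        selected_indices=selected,
        n_components=len(states),
        n_after_skewness=n_after_skewness,
        n_selected=len(selected),
    )
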