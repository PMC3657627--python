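"""On-disk formats: NIfTI volumes, mixing-matrix text, and selection reports.

Component spatial maps travel as a 4-D NIfTI volume with component as the
fourth dimension, and the mixing matrix as whitespace-delimited text with
one time point per row and one component per column — the layout MELODIC
writes (``melodic_IC.nii.gz`` / ``melodic_mix``), so decompositions produced
by that toolchain can be consumed directly.  Reports are JSON (lossless
round trip) or TSV (one row per component).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .model import (
    ComponentState,
    ICADecomposition,
    SelectionConfig,
    TissueMaps,
    flat_mask_indices,
    vector_to_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SelectionReport",
    "read_decomposition",
    "write_decomposition",
    "read_tissue_maps",
    "write_tissue_maps",
    "read_report",
    "write_report",
    "write_selected_maps",
]

_REPORT_FIELDS = [
    "index",
    "pearson_coefficient",
    "status",
    "rejection_stage",
    "chosen_k",
    "initial_voxels",
    "retained_after_cluster",
    "retained_after_tissue",
    "p1",
    "p2",
    "p3",
]


class FormatError(ValueError):
    """A file's structure does not match the expected on-disk format."""


@dataclass
class SelectionReport:
    """Per-component audit record of a pipeline run.

    ``records`` holds one dict per component (all K of them, rejected ones
    included) with the fields in ``_REPORT_FIELDS``; ``summary`` carries the
    component counts K (input), I (after the skewness step) and J (finally
    selected) plus the skewness threshold actually used; ``config`` echoes
    the configuration so a run is auditable from its report alone.
    """

    records: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    @classmethod
    def from_states(
        cls,
        states: list[ComponentState],
        cfg: SelectionConfig,
        threshold: float,
    ) -> "SelectionReport":
        records = []
        for s in states:
            bp = s.band_powers
            records.append(
                {
                    "index": s.index,
                    "pearson_coefficient": s.pearson_coefficient,
                    "status": s.status,
                    "rejection_stage": s.rejection_stage,
                    "chosen_k": s.chosen_k,
                    "initial_voxels": s.voxel_counts.get("initial"),
                    "retained_after_cluster": s.voxel_counts.get("after_cluster"),
                    "retained_after_tissue": s.voxel_counts.get("after_tissue"),
                    "p1": None if bp is None else bp.p1,
                    "p2": None if bp is None else bp.p2,
                    "p3": None if bp is None else bp.p3,
                }
            )
        cfg_dict = dataclasses.asdict(cfg)
        cfg_dict["k_candidates"] = list(cfg_dict["k_candidates"])
        summary = {
            "K": len(states),
            "I": sum(s.status != "rejected_skewness" for s in states),
            "J": sum(s.is_selected for s in states),
            "skewness_threshold": threshold,
        }
        return cls(records=records, config=cfg_dict, summary=summary)

    @property
    def selected_indices(self) -> list[int]:
        return [r["index"] for r in self.records if r["status"] == "selected"]


def _load_volume(path, expected_ndim: int) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != expected_ndim:
        raise FormatError(f"{path}: expected a {expected_ndim}-D volume, got shape {data.shape}")
    return data


def _parse_mix(path) -> np.ndarray:
    """Parse a melodic_mix-style text matrix, reporting bad lines by number."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric token on line {lineno}: {exc}") from None
            if len(rows[-1]) != len(rows[0]):
                raise FormatError(
                    f"{path}: line {lineno} has {len(rows[-1])} columns, "
                    f"expected {len(rows[0])}"
                )
    if not rows:
        raise FormatError(f"{path}: empty mixing matrix")
    return np.array(rows, dtype=float)


def read_decomposition(maps_path, mix_path, mask_path, tr_seconds: float) -> ICADecomposition:
    """Assemble a decomposition from MELODIC-layout files.

    ``maps_path`` is a 4-D NIfTI (x, y, z, component); ``mix_path`` a
    whitespace-delimited text matrix (time x component); ``mask_path`` a 3-D
    NIfTI whose nonzero voxels define the brain.  Source rows are the
    in-mask values of each component map.
    """
    maps = _load_volume(maps_path, 4)
    mask = _load_volume(mask_path, 3) > 0.5
    mixing = _parse_mix(mix_path)

    if maps.shape[:3] != mask.shape:
        raise FormatError(
            f"grid mismatch: component maps have grid {maps.shape[:3]} "
            f"but mask has grid {mask.shape}"
        )
    if maps.shape[3] != mixing.shape[1]:
        raise FormatError(
            f"component count mismatch: maps have {maps.shape[3]} volumes "
            f"but mixing matrix has {mixing.shape[1]} columns"
        )
    if not mask.any():
        raise FormatError(f"{mask_path}: mask contains no true voxels")

    idx = flat_mask_indices(mask)
    k = maps.shape[3]
    flat = maps.reshape(-1, k, order="F")  # spatial F-order rows, component columns
    sources = np.ascontiguousarray(flat[idx].T, dtype=float)
    return ICADecomposition(
        mixing=mixing, sources=sources, mask=mask, tr_seconds=float(tr_seconds)
    )


def write_decomposition(dec: ICADecomposition, maps_path, mix_path, mask_path) -> None:
    """Write a decomposition in the same layout :func:`read_decomposition` expects."""
    grid = dec.grid_shape
    k = dec.n_components
    maps = np.zeros(grid + (k,), dtype=np.float64)
    for i in range(k):
        maps[..., i] = vector_to_grid(dec.sources[i], dec.mask)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(maps, affine), str(maps_path))
    nib.save(nib.Nifti1Image(dec.mask.astype(np.uint8), affine), str(mask_path))
    np.savetxt(mix_path, dec.mixing, fmt="%.17g")


def read_tissue_maps(gm_path, wm_path, csf_path, dec: ICADecomposition) -> TissueMaps:
    """Read GM/WM/CSF probability volumes, checking the grid and clipping to [0, 1]."""
    arrays = {}
    for name, path in (("gm", gm_path), ("wm", wm_path), ("csf", csf_path)):
        data = _load_volume(path, 3).astype(float)
        if data.shape != dec.grid_shape:
            raise FormatError(
                f"{path}: {name} grid {data.shape} does not match "
                f"decomposition grid {dec.grid_shape}"
            )
        out_of_range = max(float(-data.min(initial=0.0)), float(data.max(initial=0.0) - 1.0))
        if out_of_range > 1e-6:
            logger.warning(
                "%s: %s probabilities outside [0, 1] by up to %.3g; clipping",
                path, name, out_of_range,
            )
        arrays[name] = np.clip(data, 0.0, 1.0)
    return TissueMaps(**arrays)


def write_tissue_maps(tissue: TissueMaps, gm_path, wm_path, csf_path) -> None:
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(tissue.gm.astype(np.float64), affine), str(gm_path))
    nib.save(nib.Nifti1Image(tissue.wm.astype(np.float64), affine), str(wm_path))
    nib.save(nib.Nifti1Image(tissue.csf.astype(np.float64), affine), str(csf_path))


def write_report(report: SelectionReport, path, format: str = "json") -> None:
    """Serialise a report as JSON (lossless) or TSV (one row per component)."""
    path = Path(path)
    if format == "json":
        payload = {
            "records": report.records,
            "config": report.config,
            "summary": report.summary,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        frame = pd.DataFrame(report.records, columns=_REPORT_FIELDS)
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r} (expected json or tsv)")


def read_report(path) -> SelectionReport:
    """Read back a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    return SelectionReport(
        records=payload["records"],
        config=payload["config"],
        summary=payload["summary"],
    )


def write_selected_maps(
    dec: ICADecomposition,
    states: list[ComponentState],
    path,
    only_selected: bool = True,
) -> list[int]:
    """Write a filtered 4-D NIfTI of the (selected) components.

    Non-retained voxels are set to 0, mirroring the pipeline's voxel-level
    filtering; returns the component indices written, in volume order.
    """
    chosen = [s for s in states if (s.is_selected if only_selected else True)]
    grid = dec.grid_shape
    out = np.zeros(grid + (len(chosen),), dtype=np.float64)
    for j, s in enumerate(chosen):
        retained = np.asarray(s.retained_voxels, dtype=bool)
        values = np.where(retained, dec.sources[s.index], 0.0)
        out[..., j] = vector_to_grid(values, dec.mask)
    nib.save(nib.Nifti1Image(out, np.eye(4)), str(path))
    return [s.index for s in chosen]
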