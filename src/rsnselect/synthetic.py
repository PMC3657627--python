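"""Ground-truth decomposition generator for testing the selection pipeline.

Generates mixing/source matrices with the statistical structure the
selection method assumes, directly in decomposed form (no ICA is run, so
the pipeline is tested independently of any ICA implementation's run-to-run
variability):

* **network** components: positively skewed spatial maps — folded-Gaussian
  activation amplitudes inside one to three ellipsoidal gray-matter blobs
  over a near-zero symmetric background — paired with band-limited time
  courses carrying >= 90% of their power in the 0.01-0.1 Hz range;
* **gaussian noise** components: zero-mean symmetric maps (skewness ~ 0)
  with broadband white time courses;
* **csf** components: maps confined to high-CSF-probability voxels
  (ventricle core) with time courses dominated by frequencies above 0.1 Hz,
  mimicking pulsation artifacts.

Tissue probability maps are smooth concentric fields (CSF ventricle core,
WM shell, GM cortex) on the same grid, summing to at most 1 per voxel.
Defaults match a typical resting-state acquisition: 197 time points at
TR = 2 s on a 20x20x20 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .model import ICADecomposition, TissueMaps, flat_mask_indices, grid_to_vector

__all__ = ["FixtureParams", "GroundTruth", "make_decomposition", "mix_to_4d"]


@dataclass(frozen=True)
class FixtureParams:
    """Generator parameters with realistic resting-state defaults.

    ``activation_scale`` is the folded-Gaussian sigma of blob amplitudes
    (arbitrary map units) and ``background_sigma`` the symmetric background
    noise on every map; their ratio sets how separable active voxels are
    from background in the clustering step.
    """

    grid_shape: tuple = (20, 20, 20)
    n_timepoints: int = 197
    tr_seconds: float = 2.0
    n_network: int = 3
    n_noise: int = 7
    n_csf: int = 2
    blobs_per_network: tuple = (2, 3)
    blob_radius_range: tuple = (3.2, 4.2)
    activation_scale: float = 4.0
    background_sigma: float = 0.2
    seed: int = 0

    @property
    def n_components(self) -> int:
        return self.n_network + self.n_noise + self.n_csf


@dataclass(frozen=True)
class GroundTruth:
    """Which generated component indices belong to which class."""

    network_indices: frozenset
    gaussian_noise_indices: frozenset
    csf_indices: frozenset
    params: FixtureParams

    def reference_set(self) -> set[int]:
        """The indices a perfect selector should return."""
        return set(self.network_indices)


def _radial_field(grid_shape) -> np.ndarray:
    """Normalised ellipsoidal radius (0 at center, 1 at the brain edge)."""
    axes = [np.arange(n) - (n - 1) / 2.0 for n in grid_shape]
    semi = [max(0.45 * n, 1.0) for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(
        (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_tissue_maps(grid_shape) -> tuple[TissueMaps, np.ndarray]:
    """Concentric smooth tissue fields and the brain mask they live on.

    CSF fills a central "ventricle" core (probability > 0.9 at the center),
    WM a mid-radius shell, GM an outer cortical shell; outside the brain
    all three fall to ~0.  The fields are renormalised where they would sum
    above 1.
    """
    r = _radial_field(grid_shape)
    csf = _sigmoid((0.18 - r) / 0.03)
    wm = _sigmoid((r - 0.17) / 0.03) * _sigmoid((0.55 - r) / 0.04)
    gm = _sigmoid((r - 0.53) / 0.04) * _sigmoid((0.97 - r) / 0.03)
    total = gm + wm + csf
    over = total > 1.0
    for arr in (gm, wm, csf):
        arr[over] /= total[over]
    mask = r <= 1.0
    return TissueMaps(gm=gm, wm=wm, csf=csf), mask


def _bandlimited_timecourse(
    rng: np.random.Generator,
    n: int,
    tr: float,
    band: tuple[float, float],
    out_of_band_amp: float = 0.05,
) -> np.ndarray:
    """Random-phase series with nearly all power inside ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n, d=tr)
    amp = np.where((freqs >= band[0]) & (freqs <= band[1]), 1.0, out_of_band_amp)
    amp[0] = 0.0  # no DC
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    tc = np.fft.irfft(spectrum, n=n)
    sd = tc.std()
    return tc / sd if sd > 0 else tc


def _ellipsoid_members(
    positions: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    d2 = ((positions - center) ** 2).sum(axis=1)
    return d2 <= radius**2


def _voxel_positions(mask: np.ndarray) -> np.ndarray:
    """(M x 3) grid coordinates of in-mask voxels, in source-column order."""
    idx = flat_mask_indices(mask)
    coords = np.unravel_index(idx, mask.shape, order="F")
    return np.stack(coords, axis=1).astype(float)


def make_decomposition(
    params: Optional[FixtureParams] = None, **overrides
) -> tuple[ICADecomposition, TissueMaps, GroundTruth]:
    """Generate a ground-truth decomposition, tissue maps and class labels.

    The seed fully determines every output.  Component order is a seeded
    permutation of the three classes, so class membership is only knowable
    through the returned :class:`GroundTruth`.
    """
    if params is None:
        params = FixtureParams()
    if overrides:
        params = replace(params, **overrides)
    if min(params.n_network, params.n_noise, params.n_csf) < 0:
        raise ValueError("component counts must be non-negative")
    if params.blob_radius_range[1] * 2 > min(params.grid_shape):
        raise ValueError(
            f"blob radius up to {params.blob_radius_range[1]} does not fit "
            f"grid {params.grid_shape}"
        )

    rng = np.random.default_rng(params.seed)
    tissue, mask = make_tissue_maps(params.grid_shape)
    m = int(mask.sum())
    n, k = params.n_timepoints, params.n_components
    positions = _voxel_positions(mask)
    gm_vec = grid_to_vector(tissue.gm, mask)
    csf_vec = grid_to_vector(tissue.csf, mask)

    gm_candidates = np.flatnonzero(gm_vec >= 0.5)
    csf_candidates = np.flatnonzero(csf_vec >= 0.92)
    if params.n_network and gm_candidates.size == 0:
        raise ValueError("grid has no gray-matter voxels to place network blobs in")
    if params.n_csf and csf_candidates.size == 0:
        raise ValueError("grid has no high-probability CSF voxels for csf components")

    sources = np.empty((k, m))
    mixing = np.empty((n, k))
    classes: list[str] = (
        ["network"] * params.n_network
        + ["noise"] * params.n_noise
        + ["csf"] * params.n_csf
    )
    order = rng.permutation(k)

    by_class: dict[str, set[int]] = {"network": set(), "noise": set(), "csf": set()}
    for slot, comp in enumerate(order):
        cls = classes[slot]
        by_class[cls].add(int(comp))
        values = rng.normal(0.0, params.background_sigma, size=m)
        if cls == "network":
            n_blobs = rng.integers(params.blobs_per_network[0], params.blobs_per_network[1] + 1)
            for _ in range(n_blobs):
                center = positions[rng.choice(gm_candidates)]
                radius = rng.uniform(*params.blob_radius_range)
                members = _ellipsoid_members(positions, center, radius)
                values[members] += np.abs(
                    rng.normal(0.0, params.activation_scale, size=int(members.sum()))
                )
            mixing[:, comp] = _bandlimited_timecourse(
                rng, n, params.tr_seconds, (0.01, 0.1)
            )
        elif cls == "csf":
            center = positions[rng.choice(csf_candidates)]
            members = _ellipsoid_members(positions, center, 2.5) & (csf_vec >= 0.9)
            values[members] += np.abs(
                rng.normal(0.0, params.activation_scale, size=int(members.sum()))
            )
            nyquist = 1.0 / (2.0 * params.tr_seconds)
            mixing[:, comp] = _bandlimited_timecourse(
                rng, n, params.tr_seconds, (0.12, nyquist)
            )
        else:  # gaussian noise
            values = rng.normal(0.0, 1.0, size=m)
            mixing[:, comp] = rng.normal(0.0, 1.0, size=n)
        sources[comp] = values

    dec = ICADecomposition(
        mixing=mixing, sources=sources, mask=mask, tr_seconds=params.tr_seconds
    )
    truth = GroundTruth(
        network_indices=frozenset(by_class["network"]),
        gaussian_noise_indices=frozenset(by_class["noise"]),
        csf_indices=frozenset(by_class["csf"]),
        params=params,
    )
    return dec, tissue, truth


def mix_to_4d(dec: ICADecomposition, noise_sigma: float, seed: int = 0) -> np.ndarray:
    """Mix a decomposition back to a 4-D volume: ``X = A S + E``.

    Returns a (x, y, z, time) array; in-mask voxels carry the exact mixture
    plus i.i.d. zero-mean Gaussian noise of the given sigma (added over the
    whole grid), out-of-mask voxels noise only.  With ``noise_sigma == 0``
    every in-mask voxel time series equals the exact mixture.
    """
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be non-negative, got {noise_sigma}")
    x = dec.mixing @ dec.sources  # (N, M)
    grid = dec.grid_shape
    n = dec.n_timepoints
    out = np.zeros(grid + (n,), dtype=float)
    idx = flat_mask_indices(dec.mask)
    flat = out.reshape(-1, n, order="F")
    flat[idx] = x.T
    out = flat.reshape(grid + (n,), order="F")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return out
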