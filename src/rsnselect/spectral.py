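"""Step 4: spectral rejection of surviving components.

Each component that kept at least one voxel through the spatial filters is
rebuilt in the time domain: every retained voxel's time course is the
mixing-matrix column scaled by the voxel's map value, baseline-corrected and
detrended, and the voxel time courses are averaged.  The plain (boxcar,
unwindowed) periodogram of the mean time course is split into three bands —
P1 below ``f1`` (default 0.01 Hz), P2 between ``f1`` and ``f2`` (default
0.1 Hz), and P3 above ``f2`` up to Nyquist — and expressed as fractions of
the total power excluding DC.  Resting-state networks concentrate power in
P2, so components with P2 < 50% or P1 + P2 < 90% are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .model import (
    STATUS_REJECTED_SPECTRAL,
    ComponentState,
    ICADecomposition,
    SelectionConfig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BandPowers",
    "ZeroPowerError",
    "reconstruct_mean_timecourse",
    "band_powers",
    "spectral_filter",
]


class ZeroPowerError(ValueError):
    """The time course has no power off DC; its spectrum is undefined."""


@dataclass(frozen=True)
class BandPowers:
    """Fractions of spectral power in the three bands of interest.

    ``p1 + p2 + p3 == 1`` (within 1e-9) whenever the series has nonzero
    power.  ``n_frequencies`` counts the positive-frequency periodogram bins
    and ``total_power`` their summed spectral density (excluding DC), so the
    absolute energy accounting remains auditable after normalisation.
    """

    p1: float
    p2: float
    p3: float
    nyquist_hz: float
    n_frequencies: int
    total_power: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


def _detrend_columns(x: np.ndarray, degree: int) -> np.ndarray:
    """Remove a degree-``degree`` polynomial trend from each column."""
    if degree < 0:
        return x
    n = x.shape[0]
    t = np.arange(n, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, x, deg=degree)
    trend = np.polynomial.polynomial.polyval(t, coeffs)
    return x - trend.T if trend.ndim == 2 else x - trend


def reconstruct_mean_timecourse(
    state: ComponentState, dec: ICADecomposition, cfg: SelectionConfig
) -> np.ndarray:
    """Mean fMRI time course of a component over its retained voxels.

    For each retained voxel ``m`` the voxel time course is
    ``x[:, m] = mixing[:, i] * sources[i, m]``; each is baseline-corrected
    (mean-subtracted) and polynomial-detrended before averaging.  The voxel
    time courses are scalar multiples of one mixing column, so voxels whose
    map values carry mixed signs can cancel in the average; this is logged
    when the retained map values are nearly sign-balanced.
    """
    retained = np.asarray(state.retained_voxels, dtype=bool)
    if not retained.any():
        raise ValueError(f"component {state.index} has no retained voxels")
    s = dec.sources[state.index, retained]
    a = dec.mixing[:, state.index]

    abs_mean = np.abs(s).mean()
    if abs_mean > 0 and abs(s.mean()) < 1e-3 * abs_mean:
        logger.warning(
            "component %d: retained map values are nearly sign-balanced "
            "(mean %.3g vs mean magnitude %.3g); averaging may cancel the signal",
            state.index, s.mean(), abs_mean,
        )

    x = np.outer(a, s)
    x = x - x.mean(axis=0, keepdims=True)
    x = _detrend_columns(x, cfg.detrend_degree)
    return x.mean(axis=1)


def band_powers(
    timecourse: np.ndarray, tr_seconds: float, cfg: SelectionConfig
) -> BandPowers:
    """Periodogram power fractions in [0, f1), [f1, f2), [f2, Nyquist].

    The series is demeaned and transformed with the plain unwindowed
    periodogram; the DC bin is excluded from every band and from the total,
    and each positive-frequency bin is assigned to exactly one band by its
    center frequency (half-open intervals, the last closed at Nyquist).
    """
    timecourse = np.asarray(timecourse, dtype=float).ravel()
    n = timecourse.size
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not cfg.f2_hz < nyquist:
        raise ValueError(f"f2_hz={cfg.f2_hz} is not below Nyquist {nyquist:.6g} Hz")

    freqs, pxx = signal.periodogram(
        timecourse - timecourse.mean(),
        fs=1.0 / tr_seconds,
        window="boxcar",
        detrend=False,
        scaling="density",
    )
    positive = freqs > 0
    total = pxx[positive].sum()
    if total <= 0.0:
        raise ZeroPowerError("time course has zero power off DC; spectrum undefined")
    p1 = pxx[positive & (freqs < cfg.f1_hz)].sum() / total
    p2 = pxx[positive & (freqs >= cfg.f1_hz) & (freqs < cfg.f2_hz)].sum() / total
    p3 = pxx[positive & (freqs >= cfg.f2_hz)].sum() / total
    return BandPowers(
        p1=float(p1),
        p2=float(p2),
        p3=float(p3),
        nyquist_hz=nyquist,
        n_frequencies=int(positive.sum()),
        total_power=float(total),
    )


def _fails_spectral(bp: BandPowers, cfg: SelectionConfig) -> bool:
    low_p2 = bp.p2 < cfg.p2_min
    low_p12 = (bp.p1 + bp.p2) < cfg.p12_min
    return (low_p2 or low_p12) if cfg.reject_logic == "or" else (low_p2 and low_p12)


def spectral_filter(
    states: list[ComponentState], dec: ICADecomposition, cfg: SelectionConfig
) -> list[ComponentState]:
    """Apply the band-power rejection rule to every remaining candidate.

    A candidate is rejected when P2 < ``p2_min`` or P1 + P2 < ``p12_min``
    (default OR logic; AND mode only rejects when both fail).  Survivors are
    marked selected.  A component whose mean time course has no power is
    rejected with a logged reason rather than aborting the run.  Components
    already rejected at earlier stages are never resurrected.
    """
    for state in states:
        if not state.is_candidate:
            continue
        try:
            tc = reconstruct_mean_timecourse(state, dec, cfg)
            bp = band_powers(tc, dec.tr_seconds, cfg)
        except (ZeroPowerError, ValueError) as exc:
            logger.info("component %d: spectral analysis failed (%s)", state.index, exc)
            state.reject(STATUS_REJECTED_SPECTRAL, stage="spectral", reason=str(exc))
            continue
        state.band_powers = bp
        logger.info(
            "component %d: P1=%.3f P2=%.3f P3=%.3f", state.index, bp.p1, bp.p2, bp.p3
        )
        if _fails_spectral(bp, cfg):
            state.reject(
                STATUS_REJECTED_SPECTRAL,
                stage="spectral",
                reason=f"P2={bp.p2:.3f}, P1+P2={bp.p1 + bp.p2:.3f} below thresholds",
            )
        else:
            state.select()
    return states
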