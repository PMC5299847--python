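"""Trajectory-level corrections, population statistics and protein selection.

Pipeline order: photobleach correction (mono-exponential, fitted on a
0 M KCl control or pre-stimulus data) -> per-time population mean over
valid cells -> log2 normalization to the 30-min pre-stimulus baseline
-> per-strain SNR and fold-change metrics -> selection filter
(SNR > 7 and fold change > 1.2, both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import replace as _dc_replace

import numpy as np
import pandas as pd

from .types import CellTrajectory, NormalizedProfile, PopulationProfile

__all__ = [
    "fit_bleach",
    "correct_bleach",
    "population_mean",
    "normalize_log2",
    "compute_snr",
    "compute_fold_change",
    "select_proteins",
    "DEFAULT_MIN_CELLS",
    "DEFAULT_BASELINE_WINDOW",
    "SNR_THRESHOLD",
    "FOLD_CHANGE_THRESHOLD",
]

DEFAULT_MIN_CELLS = 10
#: baseline = the 30 min (0.5 h) immediately before the stimulus
DEFAULT_BASELINE_WINDOW = (-30.0, 0.0)
SNR_THRESHOLD = 7.0
FOLD_CHANGE_THRESHOLD = 1.2


def _series(control) -> tuple[np.ndarray, np.ndarray]:
    """(elapsed minutes since first frame, values) from a control input."""
    if isinstance(control, PopulationProfile):
        t, v = control.times, control.mean
    elif isinstance(control, CellTrajectory):
        t, v = control.times, control.values
    else:  # list of trajectories: pool into a per-time mean
        prof = population_mean(list(control), min_cells=1)
        t, v = prof.times, prof.mean
    return np.asarray(t, float) - float(np.asarray(t, float)[0]), np.asarray(v, float)


def fit_bleach(control) -> float:
    """Mono-exponential photobleach decay rate (per minute), >= 0.

    Fitted by linear regression of log(value) on elapsed time using the
    positive, finite points of a non-responding control series (0 M KCl
    chamber, or pooled pre-stimulus data). A negative fitted rate is
    clipped to 0 with a warning.
    """
    elapsed, values = _series(control)
    ok = np.isfinite(values) & (values > 0)
    if ok.sum() < 5:
        raise ValueError(f"need >= 5 usable points for the bleach fit, got {int(ok.sum())}")
    slope, _ = np.polyfit(elapsed[ok], np.log(values[ok]), 1)
    rate = -float(slope)
    if abs(rate) < 1e-12:  # numerically flat series
        return 0.0
    if rate < 0:
        warnings.warn(
            f"fitted bleach rate {rate:.3e}/min is negative; clipping to 0",
            stacklevel=2,
        )
        rate = 0.0
    return rate


def correct_bleach(traj: CellTrajectory, rate: float) -> CellTrajectory:
    """Divide values by exp(-rate * elapsed); rate 0 is the identity."""
    if rate < 0:
        raise ValueError("bleach rate must be >= 0")
    elapsed = traj.times - traj.times[0]
    corrected = traj.values * np.exp(rate * elapsed)
    return _dc_replace(traj, values=corrected)


def population_mean(
    trajs: list[CellTrajectory], min_cells: int = DEFAULT_MIN_CELLS
) -> PopulationProfile:
    """Per-time arithmetic mean over cells valid at that time (S̄_t).

    Time points with fewer than ``min_cells`` cells are flagged; points
    with zero valid cells get NaN mean and are flagged missing.
    """
    if not trajs:
        raise ValueError("no trajectories")
    times = trajs[0].times
    V = np.stack([t.values for t in trajs])
    M = np.stack([t.valid for t in trajs]) & np.isfinite(V)
    counts = M.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, np.nansum(np.where(M, V, 0.0), axis=0), np.nan)
        mean = mean / np.where(counts > 0, counts, 1)
    mean = np.where(counts > 0, mean, np.nan)
    if (counts < min_cells).any():
        warnings.warn(
            f"{int((counts < min_cells).sum())} time points have fewer than "
            f"{min_cells} cells",
            stacklevel=2,
        )
    return PopulationProfile(
        strain=trajs[0].strain,
        condition=trajs[0].condition,
        times=times,
        mean=mean,
        counts=counts,
        flagged=counts < min_cells,
    )


def normalize_log2(
    profile: PopulationProfile,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    source: str = "population",
) -> NormalizedProfile:
    """log2 of the profile relative to its pre-stimulus baseline mean.

    value_t = log2(profile_t / baseline_mean) where baseline_mean is
    the geometric mean of the profile over ``baseline_window`` (closed
    on the left, open at the stimulus) — the geometric mean makes the
    baseline-window mean of the log2 output exactly zero. Non-positive
    points become missing (NaN).
    """
    lo, hi = baseline_window
    in_window = (profile.times >= lo) & (profile.times < hi)
    if in_window.sum() < 2:
        raise ValueError("baseline window must contain at least 2 time points")
    base_vals = profile.mean[in_window]
    base_vals = base_vals[np.isfinite(base_vals)]
    if base_vals.size < 2 or (base_vals <= 0).any():
        raise ValueError("baseline window must contain >= 2 positive points")
    # work in log2 space throughout: the baseline-window mean of the
    # output is then exactly zero
    baseline_log2 = float(np.mean(np.log2(base_vals)))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(
            profile.mean > 0, np.log2(np.abs(profile.mean)) - baseline_log2, np.nan
        )
    return NormalizedProfile(
        strain=profile.strain,
        condition=profile.condition,
        times=profile.times,
        log2_values=vals,
        baseline_window=baseline_window,
        source=source,
    )


def compute_snr(
    trajs: list[CellTrajectory],
    background_sd: float,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> float:
    """Signal-to-noise ratio of a strain's readout (dimensionless).

    SNR = mean background-subtracted cell fluorescence over the
    pre-stimulus window, divided by the standard deviation of the
    background pixels. ``trajs`` must already be background-subtracted
    (as produced by the extraction stage).
    """
    if background_sd <= 0:
        raise ValueError("background sd must be positive")
    lo, hi = baseline_window
    vals = []
    for t in trajs:
        m = (t.times >= lo) & (t.times < hi) & t.valid & np.isfinite(t.values)
        vals.append(t.values[m])
    pooled = np.concatenate(vals) if vals else np.array([])
    if pooled.size == 0:
        raise ValueError("no valid baseline measurements")
    return float(pooled.mean() / background_sd)


def compute_fold_change(norm: NormalizedProfile) -> float:
    """Largest post-stimulus deviation from baseline, on the linear scale.

    max over t >= 0 of max(F_t, 1/F_t) with F_t = 2**value_t, so a
    down-regulated trough at 0.5x baseline scores 2.0 — the filter is
    direction-agnostic.
    """
    post = (norm.times >= 0) & np.isfinite(norm.log2_values)
    if not post.any():
        raise ValueError("no usable post-stimulus points")
    f = 2.0 ** norm.log2_values[post]
    return float(np.max(np.maximum(f, 1.0 / f)))


def select_proteins(
    metrics: pd.DataFrame,
    snr_threshold: float = SNR_THRESHOLD,
    fc_threshold: float = FOLD_CHANGE_THRESHOLD,
) -> list[str]:
    """Strains passing SNR > snr_threshold AND fold change > fc_threshold.

    Both inequalities are strict; input order is preserved. ``metrics``
    needs columns strain, snr, fold_change.
    """
    keep = (metrics["snr"] > snr_threshold) & (metrics["fold_change"] > fc_threshold)
    return list(metrics.loc[keep, "strain"])
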