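"""Representative-single-cell statistics M1 and M2.

Population averaging can hide single-cell dynamics (e.g. asynchronous
Hsp12-like bursts). Instead of averaging, pick the one cell whose
trajectory is most similar to all the others and let it represent the
strain's dynamics.

For cell i with series S_t^i on a grid of T time points, against N - 1
other cells, with S̄_t the per-time mean over all N cells:

    M1_i = (1 / (N - 1)) * sum_{j != i} sqrt( (1/T) * sum_t ((S_t^i - S_t^j) / S̄_t)^2 )

i.e. the root-mean-square relative pairwise deviation, averaged over
the other cells. The representative cell minimizes M1 (ties -> lowest
cell id). Its series Sr_t is then compared to the population mean:

    M2 = sqrt( (1/T) * sum_t ((Sr_t - S̄_t) / S̄_t)^2 )

M2 = 0 iff the representative coincides with the population profile;
a high M2 flags dynamics (bursts, oscillations) that population
averaging suppresses. Both statistics are scale-free: multiplying all
trajectories by c > 0 leaves them unchanged. Only full-length
trajectories enter, and S̄_t includes cell i itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CellTrajectory, PopulationProfile, RepresentativeResult

__all__ = [
    "compute_m1",
    "select_representative",
    "compute_m2",
    "rank_m2",
    "representative_analysis",
]


def _full_length_matrix(trajs: list[CellTrajectory]) -> tuple[np.ndarray, np.ndarray]:
    full = [t for t in trajs if t.is_full_length]
    if len(full) < 2:
        raise ValueError(f"need >= 2 full-length trajectories, got {len(full)}")
    full.sort(key=lambda t: t.cell_id)
    S = np.stack([t.values for t in full])  # (N, T)
    ids = np.array([t.cell_id for t in full])
    if S.shape[1] < 2:
        raise ValueError("need >= 2 time points")
    if not np.isfinite(S).all():
        raise ValueError("full-length trajectories contain non-finite values")
    return S, ids


def compute_m1(trajs: list[CellTrajectory]) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell M1 similarity scores over the full-length cells.

    Returns (cell_ids, scores) sorted by cell id. Vectorized over the
    N x N pairwise deviations; requires every per-time mean S̄_t > 0.
    """
    S, ids = _full_length_matrix(trajs)
    N, T = S.shape
    mean_t = S.mean(axis=0)
    if (mean_t <= 0).any():
        raise ValueError("per-time population mean must be positive")
    R = S / mean_t  # relative series, (N, T)
    # pairwise RMS over time: D[i, j] = sqrt(mean_t (R_i - R_j)^2)
    diff = R[:, None, :] - R[None, :, :]
    D = np.sqrt(np.mean(diff**2, axis=2))
    scores = D.sum(axis=1) / (N - 1)  # diagonal is 0
    return ids, scores


def select_representative(cell_ids: np.ndarray, scores: np.ndarray) -> int:
    """Cell id with minimal M1; ties broken by lowest cell id."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores")
    order = np.lexsort((np.asarray(cell_ids), scores))
    return int(np.asarray(cell_ids)[order[0]])


def compute_m2(rep: CellTrajectory, pop: PopulationProfile) -> float:
    """RMS relative deviation of the representative cell from S̄_t."""
    if not np.array_equal(rep.times, pop.times):
        raise ValueError("representative cell and population profile grids differ")
    ok = np.isfinite(rep.values) & np.isfinite(pop.mean)
    if (pop.mean[ok] <= 0).any():
        raise ValueError("population mean must be positive")
    r = (rep.values[ok] - pop.mean[ok]) / pop.mean[ok]
    return float(np.sqrt(np.mean(r**2)))


def representative_analysis(trajs: list[CellTrajectory]) -> RepresentativeResult:
    """M1 scores, representative cell and M2 for one strain's cohort.

    M1/M2 use the full-length cells only; the population mean for M2 is
    taken over those same cells so the two statistics share S̄_t.
    """
    ids, scores = compute_m1(trajs)
    rep_id = select_representative(ids, scores)
    full = sorted((t for t in trajs if t.is_full_length), key=lambda t: t.cell_id)
    rep = next(t for t in full if t.cell_id == rep_id)
    S = np.stack([t.values for t in full])
    pop = PopulationProfile(
        strain=rep.strain,
        condition=rep.condition,
        times=rep.times,
        mean=S.mean(axis=0),
        counts=np.full(S.shape[1], S.shape[0]),
        flagged=np.zeros(S.shape[1], dtype=bool),
    )
    m2 = compute_m2(rep, pop)
    return RepresentativeResult(
        strain=rep.strain,
        cell_ids=ids,
        m1_scores=scores,
        rep_cell_id=rep_id,
        rep_series=rep.values.copy(),
        m2=m2,
        n_cells=S.shape[0],
        n_timepoints=S.shape[1],
    )


def rank_m2(results: list[RepresentativeResult]) -> pd.DataFrame:
    """Panel summary ordered by descending M2 (ties by strain name)."""
    df = pd.DataFrame(
        {
            "strain": [r.strain for r in results],
            "rep_cell_id": [r.rep_cell_id for r in results],
            "m2": [r.m2 for r in results],
            "n_cells": [r.n_cells for r in results],
            "n_timepoints": [r.n_timepoints for r in results],
        }
    )
    return df.sort_values(
        ["m2", "strain"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
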