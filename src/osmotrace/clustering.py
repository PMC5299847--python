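"""Hierarchical clustering of protein dynamic profiles into modules.

Rows are proteins, columns time points, values log2 normalized
expression. Distance is Euclidean on the raw log2 profiles (no row
standardization — response magnitude is biologically meaningful) with
average linkage. The tree is cut either at an explicit k or at the k
in 2..8 maximizing the mean silhouette; the canonical outcome on the
osmotic panel is four modules: rapidly-up-then-adapting,
down-regulated, slowly-up-then-adapting, and late-up-non-adapting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .types import ClusterResult, NormalizedProfile, ProfileMatrix

__all__ = [
    "build_profile_matrix",
    "hcluster",
    "cut_modules",
    "module_summary",
    "linkage_to_newick",
]

MAX_INTERP_GAP = 2  # longest run of missing points a row may have interpolated
K_RANGE = range(2, 9)


def build_profile_matrix(
    profiles: list[NormalizedProfile], source: str = "representative"
) -> ProfileMatrix:
    """Assemble strain profiles into a proteins x time matrix.

    Internal missing points are linearly interpolated when no gap
    exceeds MAX_INTERP_GAP consecutive points; longer gaps (or missing
    endpoints) drop the row with a warning.
    """
    wanted = [p for p in profiles if p.source == source] or profiles
    if not wanted:
        raise ValueError("no profiles to assemble")
    times = wanted[0].times
    rows, labels = [], []
    for p in wanted:
        if not np.array_equal(p.times, times):
            raise ValueError(f"profile {p.strain} is not on the common grid")
        v = p.log2_values.astype(float).copy()
        bad = ~np.isfinite(v)
        if bad.any():
            if bad[0] or bad[-1] or _longest_run(bad) > MAX_INTERP_GAP:
                warnings.warn(
                    f"dropping {p.strain}: gap too long to interpolate", stacklevel=2
                )
                continue
            good = ~bad
            v[bad] = np.interp(times[bad], times[good], v[good])
        rows.append(v)
        labels.append(p.strain)
    if not rows:
        raise ValueError("all rows dropped")
    return ProfileMatrix(np.stack(rows), labels, times)


def _longest_run(flags: np.ndarray) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def hcluster(matrix: ProfileMatrix, metric: str = "euclidean", method: str = "average") -> ClusterResult:
    """Agglomerative clustering of the rows; deterministic given input order."""
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(pdist(matrix.values, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage=Z,
        leaf_order=order,
        modules=np.ones(matrix.values.shape[0], dtype=int),
        k=1,
        row_labels=list(matrix.row_labels),
    )


def cut_modules(
    result: ClusterResult, matrix: ProfileMatrix, k: int | None = None
) -> ClusterResult:
    """Cut the tree into k modules; k=None selects k by mean silhouette.

    Automatic selection scans k in 2..8 (bounded by the row count) and
    keeps the k with the highest silhouette on the same distance the
    tree was built with.
    """
    n = matrix.values.shape[0]
    sil: dict[int, float] = {}
    if k is None:
        best_k, best_s = 2, -np.inf
        for kk in K_RANGE:
            if kk >= n:
                break
            labels = hierarchy.fcluster(result.linkage, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            s = float(silhouette_score(matrix.values, labels, metric="euclidean"))
            sil[kk] = s
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    elif k > n:
        raise ValueError(f"k={k} exceeds the {n} rows")
    if k == 1:
        modules = np.ones(n, dtype=int)
    else:
        modules = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return ClusterResult(
        linkage=result.linkage,
        leaf_order=result.leaf_order,
        modules=modules,
        k=int(k),
        silhouette_by_k=sil,
        row_labels=result.row_labels,
    )


def module_summary(
    result: ClusterResult,
    matrix: ProfileMatrix,
    up_threshold: float = 0.25,
    adapt_fraction: float = 0.5,
    late_fraction: float = 0.5,
) -> pd.DataFrame:
    """Describe each module's mean profile with an archetype label.

    Rules (on the module-mean log2 profile, post-stimulus): net change
    below ``up_threshold`` in magnitude -> "unresponsive"; negative
    extreme -> "down"; otherwise up, split by peak time (before/after
    ``late_fraction`` of the post-stimulus window -> fast/slow prefix,
    late peak -> "up-late") and by whether the profile returns at least
    ``adapt_fraction`` of the way from peak back to baseline
    ("-adapting" / "-non-adapting").
    """
    times = matrix.time_labels
    post = times >= 0
    t_post = times[post]
    rows = []
    for m in np.unique(result.modules):
        sel = result.modules == m
        mean_prof = matrix.values[sel].mean(axis=0)[post]
        i_ext = int(np.argmax(np.abs(mean_prof)))
        extreme = float(mean_prof[i_ext])
        peak_time = float(t_post[i_ext])
        final = float(mean_prof[-1])
        if abs(extreme) < up_threshold:
            label = "unresponsive"
            adapting = False
        elif extreme < 0:
            label = "down"
            adapting = False
        else:
            adapting = (extreme - final) >= adapt_fraction * extreme
            late = peak_time > late_fraction * float(t_post[-1])
            if late and not adapting:
                label = "up-late-non-adapting"
            else:
                speed = "slow" if peak_time > 0.25 * float(t_post[-1]) else "fast"
                label = f"up-{speed}-{'adapting' if adapting else 'non-adapting'}"
        rows.append(
            {
                "module": int(m),
                "n_members": int(sel.sum()),
                "peak_time_min": peak_time,
                "extreme_log2": extreme,
                "final_log2": final,
                "net_sign": int(np.sign(round(final, 6))),
                "adapting": adapting,
                "label": label,
                "members": ";".join(
                    lab for lab, s in zip(matrix.row_labels, sel) if s
                ),
            }
        )
    return pd.DataFrame(rows)


def linkage_to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(result.linkage)
    labels = result.row_labels

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            # quote labels: bare underscores read back as spaces
            return f"'{labels[node.id]}':{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
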