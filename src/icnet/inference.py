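"""Group-level edge inference: one group versus the combined others.

For every ROI pair (edge), the subject-level change in informational
connectivity (post - pre Fisher-z) is contrasted between the target
training group and all remaining subjects with a pooled-variance
two-sample t. Significance comes from a label-permutation null (default
10,000 shuffles of the target-vs-rest dichotomy, preserving group
sizes), and the resulting per-edge p-values are Benjamini-Hochberg
corrected across all edges of the contrast at q < 0.05.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .stats import bh_fdr

__all__ = ["edge_contrast", "permutation_pvalues", "significant_edges"]


def _two_sample_t(deltas: np.ndarray, mask: np.ndarray, welch: bool = False
                  ) -> np.ndarray:
    """Vectorized two-sample t (target mask vs rest) over edge columns."""
    a = deltas[mask]
    b = deltas[~mask]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if welch:
        denom = np.sqrt(va / na + vb / nb)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    zero = denom == 0
    if np.any(zero):
        diff = ma - mb
        t[zero] = np.where(diff[zero] == 0, 0.0, np.sign(diff[zero]) * np.inf)
    return t


def _target_mask(groups, target_group) -> np.ndarray:
    groups = np.asarray(groups)
    mask = groups == target_group
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 subjects on each side of the contrast")
    return mask


def edge_contrast(deltas, groups, target_group, welch: bool = False) -> np.ndarray:
    """Per-edge t of target-group dz versus all other subjects combined.

    ``deltas`` is (n_subjects, n_edges); ``groups`` labels each row.
    Pooled-variance two-sample t by default (``welch=True`` for unequal
    variances). Zero-variance edges yield signed-infinite t (degenerate)
    rather than silent NaN.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim == 1:
        deltas = deltas[:, None]
    mask = _target_mask(groups, target_group)
    return _two_sample_t(deltas, mask, welch)


def permutation_pvalues(deltas, groups, target_group, n_perm: int = 10_000,
                        seed: int = 0, welch: bool = False,
                        return_null: bool = False):
    """Two-sided permutation p-value per edge.

    The target-vs-rest membership is shuffled across subjects (group
    sizes preserved); the edge t is recomputed for each shuffle, and
    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1). When the number of
    distinct target subsets is at most ``n_perm``, exhaustive
    enumeration over all subsets replaces Monte-Carlo sampling (p then
    has no add-one correction).

    Subjects are put into a canonical order internally, so reordering
    the input rows (with their labels) leaves the result bit-identical.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim == 1:
        deltas = deltas[:, None]
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    groups = np.asarray(groups)
    canon = np.lexsort(np.vstack([deltas.T, groups == target_group]))
    deltas = deltas[canon]
    groups = groups[canon]
    mask = _target_mask(groups, target_group)
    n = mask.size
    k = int(mask.sum())
    t_obs = _two_sample_t(deltas, mask, welch)

    n_distinct = comb(n, k)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        count = np.zeros(deltas.shape[1])
        total = 0
        for subset in combinations(range(n), k):
            pm = np.zeros(n, dtype=bool)
            pm[list(subset)] = True
            tp = _two_sample_t(deltas, pm, welch)
            count += np.abs(tp) >= np.abs(t_obs) - 1e-12
            total += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(deltas.shape[1])
        perm = np.arange(n)
        for _ in range(n_perm):
            rng.shuffle(perm)
            pm = np.zeros(n, dtype=bool)
            pm[perm[:k]] = True
            tp = _two_sample_t(deltas, pm, welch)
            count += np.abs(tp) >= np.abs(t_obs)
        p = (1 + count) / (n_perm + 1)
    if return_null:
        return p, t_obs, exhaustive
    return p


def significant_edges(p_perm, t_obs, roi_ids, q_threshold: float = 0.05,
                      context: str = "all", phase: str = "encoding",
                      target_group: str = "") -> pd.DataFrame:
    """BH-FDR over all edges of one contrast; report surviving edges.

    Returns a DataFrame (roi_i, roi_j, t, p_perm, q, direction, context,
    phase, target_group) of edges with q <= threshold, ordered by q then
    descending |t|. ``direction`` is "increase" when the target group's
    mean change exceeds the others' (t > 0), "decrease" otherwise.
    """
    p_perm = np.asarray(p_perm, dtype=float)
    t_obs = np.asarray(t_obs, dtype=float)
    roi_ids = np.asarray(roi_ids)
    ii, jj = np.triu_indices(len(roi_ids), k=1)
    if p_perm.size != ii.size:
        raise ValueError("p-values do not match the edge count for this roster")
    fdr = bh_fdr(p_perm, q_threshold)
    sig = np.flatnonzero(fdr.rejected)
    df = pd.DataFrame({
        "roi_i": roi_ids[ii[sig]],
        "roi_j": roi_ids[jj[sig]],
        "t": t_obs[sig],
        "p_perm": p_perm[sig],
        "q": fdr.q_values[sig],
        "direction": np.where(t_obs[sig] > 0, "increase", "decrease"),
        "context": context,
        "phase": phase,
        "target_group": target_group,
    })
    df = df.sort_values(["q", "t"], key=lambda s: -s.abs() if s.name == "t" else s)
    return df.reset_index(drop=True)
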