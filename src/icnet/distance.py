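"""Multivariate connectivity-profile distance between contexts.

For each ROI, its informational-connectivity profile — the vector of
edges to the remaining n-1 ROIs — is extracted from the spatial ICM and
from the temporal ICM of the same subject/session. The distance between
the two profiles is 1 minus their Pearson (or Spearman) correlation, a
value in [0, 2]: 0 when the ROI relates to the rest of the network
identically under both contexts, larger when its spatial and temporal
connectivity profiles diverge. Training-induced change is assessed per
group with paired pre/post t-tests, FDR-corrected across ROIs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import Icm
from .stats import bh_fdr, paired_t

__all__ = ["connectivity_profile", "profile_distance", "distance_prepost_test"]


def connectivity_profile(icm: Icm, roi) -> np.ndarray:
    """One ROI's edges to all other ROIs, ordered by partner ROI id.

    Length n_roi - 1; the self-edge (diagonal) is excluded. The ordering
    is shared between contexts so profiles are cell-aligned.
    """
    pos = np.flatnonzero(icm.roi_ids == roi)
    if pos.size == 0:
        raise KeyError(f"ROI {roi!r} not in roster")
    i = int(pos[0])
    row = icm.matrix[i]
    return np.delete(row, i)


def profile_distance(spatial: Icm, temporal: Icm, roi,
                     method: str = "pearson") -> float:
    """1 - correlation between a ROI's spatial and temporal profiles."""
    if spatial.subject_id != temporal.subject_id:
        raise ValueError("ICMs belong to different subjects")
    if spatial.session != temporal.session:
        raise ValueError("ICMs belong to different sessions")
    if not np.array_equal(spatial.roi_ids, temporal.roi_ids):
        raise ValueError("ROI roster mismatch between contexts")
    a = connectivity_profile(spatial, roi)
    b = connectivity_profile(temporal, roi)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return float("nan")  # flagged undefined: degenerate profile
    if method == "pearson":
        r = float(np.corrcoef(a, b)[0, 1])
    elif method == "spearman":
        r = float(sps.spearmanr(a, b).statistic)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return 1.0 - r


def distance_prepost_test(distances: pd.DataFrame, group: str,
                          method: str = "pearson",
                          q_threshold: float = 0.05) -> pd.DataFrame:
    """Within-group paired pre/post test of profile distance, per ROI.

    ``distances`` is long-format with columns (subject_id, group, roi,
    session, distance). For each ROI of the requested group a paired t
    over subjects with both sessions is computed; BH-FDR is applied
    across all ROIs of that (group, method) family. The signed t follows
    the post-minus-pre convention (t > 0 when distance grows after
    training); ``post_greater`` restates the direction explicitly.
    """
    sub = distances[distances["group"] == group]
    if sub.empty:
        raise ValueError(f"no subjects in group {group!r}")
    wide = sub.pivot_table(index=["roi", "subject_id"], columns="session",
                           values="distance")
    if not {"pre", "post"}.issubset(wide.columns):
        raise ValueError("need both pre and post sessions")
    wide = wide.dropna()
    rows = []
    for roi, block in wide.groupby(level="roi"):
        pre = block["pre"].to_numpy()
        post = block["post"].to_numpy()
        if pre.size < 2:
            raise ValueError(f"ROI {roi}: <2 complete subjects")
        res = paired_t(pre, post)
        rows.append({
            "roi": roi, "group": group, "method": method,
            "n": pre.size, "mean_pre": pre.mean(), "mean_post": post.mean(),
            "t": res.t, "dof": res.dof, "p": res.p,
            "post_greater": post.mean() > pre.mean(),
            "degenerate": res.degenerate,
        })
    out = pd.DataFrame(rows).sort_values("roi").reset_index(drop=True)
    usable = ~out["p"].isna()
    q = np.full(len(out), np.nan)
    rejected = np.zeros(len(out), dtype=bool)
    if usable.any():
        fdr = bh_fdr(out.loc[usable, "p"].to_numpy(), q_threshold)
        q[usable.to_numpy()] = fdr.q_values
        rejected[usable.to_numpy()] = fdr.rejected
    out["q"] = q
    out["significant"] = rejected
    return out
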