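"""Within-context representational similarity (RSA) over trial t-maps.

For each ROI, trial-pair Pearson correlations are computed across
voxels, restricted to pairs of trials from *different runs* (avoiding
within-run temporal autocorrelation) and the *same context* (spatial or
temporal). Retrieval-phase matrices use only correctly retrieved source
trials. Entries are Fisher z-transformed. The "all" variant pools the
within-spatial and within-temporal pairs; cross-context pairs never
enter any matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import TrialPatternSet
from .stats import fisher_z

__all__ = ["Rsm", "compute_rsm", "rsm_vector", "canonical_pairs"]

CONTEXTS = ("spatial", "temporal", "all")


@dataclass
class Rsm:
    """Long-format representational similarity matrix for one ROI.

    ``entries`` has columns (trial_i, trial_j, z) with trial_i < trial_j,
    sorted ascending — the deterministic canonical ordering shared by all
    ROIs of one subject/session/context.
    """

    roi_id: int
    context: str
    phase: str
    entries: pd.DataFrame


def _valid_trials(patterns: TrialPatternSet, context_filter: str, phase: str
                  ) -> pd.DataFrame:
    meta = patterns.meta
    keep = ~meta["excluded"].to_numpy(dtype=bool)
    if phase == "retrieval":
        keep &= meta["correct"].to_numpy(dtype=bool)
    if context_filter != "all":
        keep &= (meta["context"] == context_filter).to_numpy()
    else:
        keep &= meta["context"].isin(["spatial", "temporal"]).to_numpy()
    return meta[keep]


def canonical_pairs(meta: pd.DataFrame, context_filter: str) -> np.ndarray:
    """Cross-run, same-context trial pairs in canonical (i < j) order.

    ``meta`` must carry trial, run, context columns for the usable
    trials. Returns an (n_pairs, 2) array of trial ids.
    """
    trials = meta.sort_values("trial")
    t = trials["trial"].to_numpy()
    r = trials["run"].to_numpy()
    c = trials["context"].to_numpy()
    ii, jj = np.triu_indices(len(t), k=1)
    ok = (r[ii] != r[jj]) & (c[ii] == c[jj])
    return np.column_stack([t[ii[ok]], t[jj[ok]]])


def compute_rsm(patterns: TrialPatternSet, context_filter: str, phase: str,
                use_tmaps: bool = True) -> Rsm:
    """Build the within-context, cross-run RSM for one ROI.

    Pearson correlation across voxels for every valid trial pair, then
    Fisher z. Excluded trials (motion) and, at retrieval, incorrect
    source judgments never contribute. Raises when fewer than 2 valid
    cross-run pairs exist.
    """
    if context_filter not in CONTEXTS:
        raise ValueError(f"context_filter must be one of {CONTEXTS}")
    meta = _valid_trials(patterns, context_filter, phase)
    pairs = canonical_pairs(meta, context_filter)
    if len(pairs) < 2:
        raise ValueError(
            f"ROI {patterns.roi_id}: <2 usable cross-run {context_filter} "
            f"trial pairs at {phase}"
        )
    X = patterns.tmaps if use_tmaps else patterns.betas
    rows = meta.index.to_numpy()  # positional rows into the pattern matrix
    sub = X[rows]
    corr = np.corrcoef(sub)
    trials_sorted = np.sort(meta["trial"].to_numpy())
    zi = np.searchsorted(trials_sorted, pairs[:, 0])
    zj = np.searchsorted(trials_sorted, pairs[:, 1])
    # corr rows follow meta order; remap to sorted-trial order
    order = np.argsort(meta["trial"].to_numpy(), kind="stable")
    corr = corr[np.ix_(order, order)]
    z = fisher_z(corr[zi, zj])
    # canonical_pairs already emits ascending (trial_i, trial_j)
    entries = pd.DataFrame({
        "trial_i": pairs[:, 0], "trial_j": pairs[:, 1], "z": z,
    })
    return Rsm(patterns.roi_id, context_filter, phase, entries)


def rsm_vector(rsm: Rsm, cell_order: np.ndarray) -> np.ndarray:
    """Emit the RSM's z-values in a shared canonical pair order.

    ``cell_order`` is the (n_pairs, 2) trial-id array every ROI of the
    subject/session/context shares; a pair absent from the RSM is an
    error, since informational connectivity requires cell-aligned
    vectors.
    """
    cells = np.asarray(cell_order, dtype=np.int64)
    lo = np.minimum(cells[:, 0], cells[:, 1])
    hi = np.maximum(cells[:, 0], cells[:, 1])
    ti = rsm.entries["trial_i"].to_numpy(dtype=np.int64)
    tj = rsm.entries["trial_j"].to_numpy(dtype=np.int64)
    width = max(tj.max(), hi.max()) + 1
    have = ti * width + tj
    want = lo * width + hi
    order = np.argsort(have, kind="stable")
    pos = np.searchsorted(have, want, sorter=order)
    bad = (pos >= have.size) | (have[order[np.minimum(pos, have.size - 1)]] != want)
    if np.any(bad):
        k = int(np.flatnonzero(bad)[0])
        raise KeyError(f"pair ({lo[k]}, {hi[k]}) missing from RSM of "
                       f"ROI {rsm.roi_id}")
    return rsm.entries["z"].to_numpy()[order[pos]]
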