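"""Informational connectivity: correlating RSMs across ROI pairs.

Unlike time-series functional connectivity, which correlates averaged
BOLD fluctuations, informational connectivity correlates two regions'
representational-similarity structures: if trial pairs that are similar
in ROI A are also similar in ROI B, the regions carry shared information
about trial identity. Each subject/session/context yields one ROI x ROI
informational connectivity matrix (ICM) of Fisher-z values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import fisher_z

__all__ = ["Icm", "compute_icm", "icm_change", "n_edges", "edge_index"]

#: Minimum number of RSM cells entering each cross-ROI correlation.
MIN_CELLS = 10


def n_edges(n_roi: int) -> int:
    """Unique undirected ROI pairs: n(n-1)/2 (29,161 at 242 ROIs)."""
    return n_roi * (n_roi - 1) // 2


def edge_index(n_roi: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the unique upper-triangle edges."""
    return np.triu_indices(n_roi, k=1)


@dataclass
class Icm:
    """ROI x ROI informational connectivity matrix (Fisher-z)."""

    subject_id: str
    session: str            # "pre" | "post"
    context: str            # "all" | "spatial" | "temporal"
    matrix: np.ndarray      # symmetric, diagonal NaN
    roi_ids: np.ndarray
    flagged: np.ndarray = field(default=None)  # degenerate (zero-variance) entries

    @property
    def n_roi(self) -> int:
        return self.matrix.shape[0]

    def edges(self) -> np.ndarray:
        ii, jj = edge_index(self.n_roi)
        return self.matrix[ii, jj]


def compute_icm(rsm_vectors: dict, subject_id: str = "", session: str = "",
                context: str = "all", min_cells: int = MIN_CELLS) -> Icm:
    """Correlate per-ROI RSM vectors into an ICM.

    ``rsm_vectors`` maps roi_id -> cell-aligned vector of RSM z-values
    (see :func:`icnet.similarity.rsm_vector`). Entry (i, j) is
    fisher_z(Pearson(vector_i, vector_j)). A zero-variance vector yields
    flagged (NaN + flag) entries rather than silent NaNs.
    """
    roi_ids = np.array(sorted(rsm_vectors))
    vecs = [np.asarray(rsm_vectors[r], dtype=float) for r in roi_ids]
    lengths = {v.size for v in vecs}
    if len(lengths) != 1:
        raise ValueError(f"RSM vectors differ in length: {sorted(lengths)}")
    (ncells,) = lengths
    if ncells < min_cells:
        raise ValueError(f"only {ncells} RSM cells; need >= {min_cells}")
    V = np.vstack(vecs)
    sd = V.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V)
    corr = np.clip(corr, -1.0, 1.0)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    mat = np.where(np.isnan(corr), np.nan, 0.0)
    finite = ~np.isnan(corr)
    mat[finite] = fisher_z(corr[finite])
    np.fill_diagonal(mat, np.nan)
    flagged = np.zeros_like(mat, dtype=bool)
    flagged[degenerate, :] = True
    flagged[:, degenerate] = True
    np.fill_diagonal(flagged, False)
    return Icm(subject_id, session, context, mat, roi_ids, flagged)


def icm_change(pre: Icm, post: Icm) -> np.ndarray:
    """Edge-wise post - pre change in informational connectivity (dz)."""
    if pre.subject_id != post.subject_id:
        raise ValueError("ICMs belong to different subjects")
    if pre.context != post.context:
        raise ValueError("ICMs belong to different contexts")
    if not np.array_equal(pre.roi_ids, post.roi_ids):
        raise ValueError("ROI roster mismatch between sessions")
    return post.matrix - pre.matrix
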