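"""Shared statistical primitives.

Fisher's r-to-z transform, Benjamini–Hochberg FDR, plain/partial
correlation with a Shapiro–Wilk normality gate, Fisher's z-test for
comparing two independent correlations, and the paired t-test. Every
downstream stage (similarity, connectivity, inference, distance,
behavior) imports from here so that conventions — two-sided p-values by
default, z-transform clipping, FDR family handling — are defined once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Correlations are clipped to +/-(1 - FISHER_EPS) before atanh so that
#: numerically perfect correlations (common in noiseless synthetic data)
#: map to a large finite z instead of +/-inf.
FISHER_EPS = 1e-7


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its sample size and p-value.

    ``method`` records which estimator was used (``"pearson"`` or
    ``"spearman"``), so a normality-gated choice is auditable downstream.
    """

    r: float
    n: int
    p: float
    method: str = "pearson"

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


@dataclass(frozen=True)
class FdrResult:
    """Benjamini–Hochberg adjustment of a family of p-values."""

    p_values: np.ndarray
    q_values: np.ndarray
    rejected: np.ndarray
    threshold: float = 0.05

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(self.rejected))


def fisher_z(r):
    """Fisher r-to-z transform, ``atanh(r)``, clipped away from +/-1.

    Accepts scalars or arrays. Raises on non-finite input.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("fisher_z: non-finite correlation value")
    z = np.arctanh(np.clip(arr, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def bh_fdr(p_values, q_threshold: float = 0.05) -> FdrResult:
    """Benjamini–Hochberg step-up FDR over one family of tests.

    Returns q-values (adjusted p-values) and the rejection mask at
    ``q_threshold``. Rejections satisfy the classical step-up rule:
    reject ranks 1..k where k is the largest rank with
    p_(k) <= k * q / m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult(p, np.array([]), np.array([], dtype=bool), q_threshold)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("bh_fdr: p-values must lie in [0, 1]")
    if not 0 < q_threshold < 1:
        raise ValueError("bh_fdr: q_threshold must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    rejected = q <= q_threshold
    return FdrResult(p, q, rejected, q_threshold)


def choose_correlation_method(x, y, alpha: float = 0.05) -> str:
    """Pick Pearson vs Spearman by Shapiro–Wilk normality of both variables.

    Pearson when neither variable rejects normality at ``alpha``;
    Spearman (rank-based) otherwise. Applied to both variables as the
    conservative reading of a normality precondition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for v in (x, y):
        if np.ptp(v) == 0:
            return "spearman"
        if sps.shapiro(v).pvalue < alpha:
            return "spearman"
    return "pearson"


def _plain_correlation(x, y, method: str) -> CorrelationResult:
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(res.statistic), len(x), float(res.pvalue), method)


def partial_correlation(x, y, covariates=None, method: str = "pearson") -> CorrelationResult:
    """Correlation of x and y after regressing out nuisance covariates.

    Both variables are residualized on [intercept, covariates] by least
    squares, then correlated. With no covariates this reduces to the
    plain correlation. ``method="spearman"`` rank-transforms x, y and the
    covariates before residualization. ``method="auto"`` applies the
    Shapiro–Wilk gate. The p-value uses n - k residual degrees of
    freedom, where k is the number of covariates.

    Parameters
    ----------
    covariates : array-like, pandas DataFrame or None
        Columns of nuisance variables (e.g. sex, site as 0/1 codes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if method == "auto":
        method = choose_correlation_method(x, y)

    if covariates is None:
        return _plain_correlation(x, y, method)
    names = list(covariates.columns) if hasattr(covariates, "columns") else None
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != x.size:
        raise ValueError("covariates must have one row per observation")
    if cov.shape[1] == 0:
        return _plain_correlation(x, y, method)
    if x.size <= cov.shape[1] + 2:
        raise ValueError("need n > n_covariates + 2 observations")

    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        cov = np.apply_along_axis(sps.rankdata, 0, cov)

    design = np.column_stack([np.ones(x.size), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which added column breaks full rank, for the error message
        culprit = "?"
        for j in range(cov.shape[1]):
            sub = np.column_stack([np.ones(x.size), cov[:, : j + 1]])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                culprit = names[j] if names else f"column {j}"
                break
        raise ValueError(f"rank-deficient covariates: {culprit} is collinear")

    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    # t-test on the partial correlation with dof = n - k - 2
    dof = x.size - cov.shape[1] - 2
    r_c = np.clip(r, -1 + FISHER_EPS, 1 - FISHER_EPS)
    t = r_c * np.sqrt(dof / (1 - r_c**2))
    p = 2 * sps.t.sf(abs(t), dof)
    return CorrelationResult(r, x.size, float(p), method)


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         one_sided: bool = False):
    """Fisher z-test for the difference of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); p from the
    normal tail, halved and direction-consistent if ``one_sided``
    (alternative r1 > r2).

    Returns
    -------
    (z, p) : tuple of floats
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("compare_correlations: need n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("compare_correlations: |r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    if one_sided:
        p = sps.norm.sf(z)
    else:
        p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    dof: int
    p: float
    mean_diff: float
    degenerate: bool = False


def paired_t(pre, post) -> PairedTResult:
    """Two-sided paired t-test on post - pre differences.

    Zero-variance differences are flagged ``degenerate`` (t is +/-inf for
    a nonzero constant difference, 0/NaN-free p is not defined) rather
    than silently reported as significant or null.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D arrays")
    n = pre.size
    if n < 2:
        raise ValueError("paired_t: need at least two pairs")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d[0] == 0 else float(np.sign(d[0]) * np.inf)
        p = 1.0 if d[0] == 0 else float("nan")
        return PairedTResult(t, n - 1, p, float(d.mean()), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), n - 1, float(p), float(d.mean()))
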