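"""Shared statistical primitives: transforms, FDR, correlations, t-tests."""

import numpy as np
import pytest
from scipy import stats as sps

from icnet.stats import (bh_fdr, choose_correlation_method,
                         compare_correlations, fisher_z, paired_t,
                         partial_correlation)


def brute_force_bh(p, q):
    """Step-up definition: largest k with p_(k) <= k q / m; reject ranks <= k."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


class TestFisherZ:
    def test_fixed_points_and_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)
        # perfect correlation is clipped to a large finite value
        z1 = fisher_z(1.0)
        assert np.isfinite(z1)
        assert z1 == pytest.approx(np.arctanh(1 - 1e-7))
        assert 8.0 < z1 < 8.5

    def test_odd_and_strictly_increasing(self):
        r = np.linspace(-0.999, 0.999, 1000)
        z = fisher_z(r)
        assert np.allclose(z, -fisher_z(-r))
        assert np.all(np.diff(z) > 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            fisher_z(np.nan)


class TestBhFdr:
    def test_examples(self):
        res = bh_fdr([0.001, 0.02, 0.03, 0.5], 0.05)
        assert res.rejected.tolist() == [True, True, True, False]
        assert bh_fdr([1.0, 1.0, 1.0], 0.05).n_rejected == 0
        assert bh_fdr([0.01], 0.05).rejected.tolist() == [True]
        assert bh_fdr([], 0.05).n_rejected == 0

    def test_invariants(self, rng):
        p = rng.uniform(size=40)
        res = bh_fdr(p, 0.05)
        assert np.all(res.q_values >= p - 1e-15)
        assert np.all(res.q_values[res.rejected] <= 0.05)
        # step-up consistency: anything with smaller p than a rejected test
        # is rejected too
        if res.n_rejected:
            thr = p[res.rejected].max()
            assert np.all(res.rejected[p <= thr])

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(500):
            m = rng.integers(1, 51)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            res = bh_fdr(p, 0.05)
            assert np.array_equal(res.rejected, brute_force_bh(p, 0.05))
            rej_sm, q_sm, *_ = multipletests(p, 0.05, method="fdr_bh")
            assert np.array_equal(res.rejected, rej_sm)
            assert np.allclose(res.q_values, q_sm, atol=1e-12)

    def test_error_control_under_global_null(self, rng):
        false_prop = []
        for _ in range(1000):
            p = rng.uniform(size=20)
            false_prop.append(1.0 if bh_fdr(p, 0.05).n_rejected else 0.0)
        mc_se = np.sqrt(0.05 * 0.95 / 1000)
        assert np.mean(false_prop) <= 0.05 + 3 * mc_se

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5], q_threshold=0.0)


class TestPartialCorrelation:
    def test_no_covariates_equals_plain(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        res = partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert partial_correlation(x, x).r == pytest.approx(1.0)

    def test_covariate_driven_association_removed(self, rng):
        n = 200
        c = rng.normal(size=n)
        x = c + rng.normal(size=n)
        y = c + rng.normal(size=n)
        plain = sps.pearsonr(x, y).statistic
        res = partial_correlation(x, y, covariates=c)
        assert abs(plain) > 0.3          # confounded without adjustment
        assert abs(res.r) < 0.15
        # naive residual-correlation oracle
        rx = x - np.polyval(np.polyfit(c, x, 1), c)
        ry = y - np.polyval(np.polyfit(c, y, 1), c)
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_collinear_covariate_named(self, rng):
        import pandas as pd

        n = 30
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n)})
        cov["dup"] = cov["sex"]
        with pytest.raises(ValueError, match="dup"):
            partial_correlation(rng.normal(size=n), rng.normal(size=n), cov)

    def test_normality_gate(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        assert choose_correlation_method(x, y) == "pearson"
        assert choose_correlation_method(np.exp(3 * x), y) == "spearman"


class TestCompareCorrelations:
    def test_symmetry_and_closed_form(self):
        z, p = compare_correlations(0.4, 30, 0.4, 50)
        assert z == 0.0
        assert p == pytest.approx(1.0)
        z, p = compare_correlations(0.6, 25, 0.0, 25)
        expected = np.arctanh(0.6) / np.sqrt(2 / 22)
        assert z == pytest.approx(expected, abs=1e-12)
        z2, _ = compare_correlations(0.0, 25, 0.6, 25)
        assert z2 == pytest.approx(-z, abs=1e-12)

    def test_one_sided_direction(self):
        _, p_two = compare_correlations(0.6, 40, 0.1, 40)
        _, p_one = compare_correlations(0.6, 40, 0.1, 40, one_sided=True)
        assert p_one == pytest.approx(p_two / 2, abs=1e-12)

    def test_null_p_uniform(self, rng):
        n = 30
        pvals = []
        for _ in range(2000):
            a = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], size=n)
            b = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], size=n)
            r1 = np.corrcoef(a.T)[0, 1]
            r2 = np.corrcoef(b.T)[0, 1]
            pvals.append(compare_correlations(r1, n, r2, n)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.2, 30)


class TestPairedT:
    def test_degenerate_cases(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate
        res = paired_t([0, 0, 0, 0], [1, 1, 1, 1])
        assert np.isinf(res.t) and res.degenerate

    def test_matches_closed_form(self, rng):
        pre = rng.normal(size=30)
        post = pre + rng.normal(0.5, 1.0, size=30)
        res = paired_t(pre, post)
        d = post - pre
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(30))
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        ref = sps.ttest_rel(post, pre)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.dof == 29
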