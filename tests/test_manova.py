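"""Pillai-trace MANOVA: oracles, reductions, scan behaviour, thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pleioscan as ps
from pleioscan.manova import (
    f_and_chi2_p,
    genomic_lambda,
    manova_statistics,
    pillai_eigen,
    pillai_manova,
    reverse_regression_r2,
    scan,
    significance_thresholds,
)

from conftest import make_panel


def random_instance(rng, n=None, k=None):
    n = n or int(rng.integers(20, 201))
    k = k or int(rng.integers(1, 11))
    if n <= k + 1:
        n = k + 10
    Y = rng.standard_normal((n, k))
    g = rng.binomial(2, 0.3, n).astype(float)
    while np.ptp(g) == 0:
        g = rng.binomial(2, 0.3, n).astype(float)
    return Y, g


class TestOracleEquivalence:
    def test_shortcut_matches_eigen_formulation_on_100_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            Y, g = random_instance(rng)
            assert abs(reverse_regression_r2(Y, g) - pillai_eigen(Y, g)) < 1e-10

    def test_all_single_marker_statistics_share_one_p(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            Y, g = random_instance(rng)
            table = manova_statistics(Y, g)
            p = table["p"].to_numpy()
            assert np.max(np.abs(p - p[0])) < 1e-10

    def test_permutation_oracle_small_instance(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((50, 3))
        g = rng.binomial(2, 0.4, 50).astype(float)
        res = pillai_manova(Y, g)
        n_perm = 10_000
        Yc = Y - Y.mean(axis=0)
        Q, _ = np.linalg.qr(Yc)
        count = 0
        for _ in range(n_perm):
            gp = rng.permutation(g)
            gpc = gp - gp.mean()
            v = float((Q.T @ gpc) @ (Q.T @ gpc)) / float(gpc @ gpc)
            if v >= res.V:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        se = np.sqrt(res.p * (1 - res.p) / n_perm)
        assert abs(p_perm - res.p) < 3 * se + 1e-9


class TestReductions:
    def test_k1_equals_univariate_f_test(self, rng):
        n = 80
        y = rng.standard_normal((n, 1))
        g = rng.binomial(2, 0.25, n).astype(float)
        res = pillai_manova(y, g)
        r = np.corrcoef(g, y[:, 0])[0, 1]
        assert res.V == pytest.approx(r * r, abs=1e-12)
        assert res.df2 == n - 2
        slope = stats.linregress(g, y[:, 0])
        assert res.p == pytest.approx(slope.pvalue, abs=1e-12)

    def test_orthogonal_genotype_gives_null_result(self, rng):
        n = 60
        Y = rng.standard_normal((n, 4))
        g = rng.standard_normal(n)
        Yc = Y - Y.mean(axis=0)
        X = np.column_stack([np.ones(n), Yc])
        g_perp = g - X @ np.linalg.lstsq(X, g, rcond=None)[0]
        res = pillai_manova(Y, g_perp)
        assert res.V < 1e-20
        assert res.p == pytest.approx(1.0)

    def test_monomorphic_variant_flagged_not_raised(self, rng):
        Y = rng.standard_normal((30, 3))
        res = pillai_manova(Y, np.ones(30))
        assert res.monomorphic and np.isnan(res.p)

    def test_too_small_sample_rejected(self, rng):
        Y = rng.standard_normal((4, 3))
        with pytest.raises(ps.ValidationError):
            pillai_manova(Y, np.array([0.0, 1.0, 2.0, 1.0]))


class TestFAndChi2:
    def test_zero_v(self):
        F, p_f, p_chi2 = f_and_chi2_p(0.0, 5, 1000)
        assert F == 0.0 and p_f == 1.0 and p_chi2 == 1.0

    def test_chi2_approximation_large_n(self):
        _, p_f, p_chi2 = f_and_chi2_p(0.005, 5, 10_000)
        assert abs(np.log10(p_f) - np.log10(p_chi2)) < 0.05

    def test_fixed_arithmetic(self):
        F, _, _ = f_and_chi2_p(0.02, 23, 1960)
        assert F == pytest.approx((0.02 / 23) / (0.98 / 1936), rel=1e-12)

    def test_v_out_of_range_rejected(self):
        with pytest.raises(ps.ValidationError):
            f_and_chi2_p(1.0, 3, 100)


class TestScan:
    def test_single_trait_group_reproduces_univariate(self, rng):
        n, m = 120, 30
        panel = make_panel(rng.binomial(2, 0.3, size=(n, m)).astype(float))
        traits = pd.DataFrame({"t1": rng.standard_normal(n), "t2": rng.standard_normal(n)})
        out, _ = scan(traits, panel, group=["t1"], group_name="one")
        for j in range(m):
            lr = stats.linregress(panel.dosages[:, j], traits["t1"])
            assert out.table["p_manova"].iloc[j] == pytest.approx(lr.pvalue, abs=1e-10)

    def test_duplicate_trait_column_dropped_with_warning(self, rng):
        n = 100
        panel = make_panel(rng.binomial(2, 0.3, size=(n, 5)).astype(float))
        t = rng.standard_normal(n)
        traits = pd.DataFrame({"a": t, "b": t.copy(), "c": rng.standard_normal(n)})
        with pytest.warns(UserWarning, match="collinear"):
            out, summary = scan(traits, panel)
        assert summary["k"] == 2

    def test_null_scan_lambda_near_one(self):
        rng = np.random.default_rng(3)
        n, m, k, rho = 1000, 2000, 5, 0.5
        Sigma = np.full((k, k), rho)
        np.fill_diagonal(Sigma, 1.0)
        Y = rng.multivariate_normal(np.zeros(k), Sigma, size=n)
        panel = make_panel(rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float))
        _, summary = scan(pd.DataFrame(Y, columns=[f"t{i}" for i in range(k)]), panel)
        assert 0.9 < summary["lambda"] < 1.1

    def test_empty_group_rejected(self, rng, tiny_panel):
        traits = pd.DataFrame({"t": [0.1, -0.2, 0.5]})
        with pytest.raises(ps.ValidationError):
            scan(traits, tiny_panel, group=[])

    def test_missing_dosages_use_complete_cases(self, rng):
        n = 80
        dos = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        dos[:10, 0] = np.nan
        panel = make_panel(dos)
        traits = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        out, _ = scan(traits, panel)
        assert out.table["n_used"].iloc[0] == n - 10
        assert out.table["n_used"].iloc[1] == n


class TestGenomicLambda:
    def test_all_half_is_exactly_one(self):
        assert genomic_lambda(np.full(500, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_null(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100_000)
        assert 0.99 < genomic_lambda(p) < 1.01

    def test_halving_p_increases_lambda(self, rng):
        p = rng.uniform(0.01, 1.0, 1000)
        assert genomic_lambda(p / 2) > genomic_lambda(p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ps.ValidationError):
            genomic_lambda(np.array([0.5] * 200 + [0.0]))

    def test_few_pvalues_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            genomic_lambda(np.full(10, 0.5))


class TestThresholds:
    def test_discovery_and_replication_values(self):
        disc, rep = significance_thresholds(5e-8, 9, 5)
        assert f"{disc:.1e}" == "5.6e-09"
        assert f"{rep:.1e}" == "1.1e-03"

    def test_single_scan_passthrough(self):
        disc, _ = significance_thresholds(5e-8, 1, 5)
        assert disc == 5e-8

    def test_invalid_counts_rejected(self):
        with pytest.raises(ps.ValidationError):
            significance_thresholds(5e-8, 0, 5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(1, 6))
def test_pillai_invariants_and_sample_permutation(seed, k):
    """V in [0,1), p in (0,1]; jointly permuting samples leaves V unchanged."""
    rng = np.random.default_rng(seed)
    n = k + 15
    Y = rng.standard_normal((n, k))
    g = rng.binomial(2, 0.4, n).astype(float)
    if np.ptp(g) == 0:
        g[0] = 2.0 - g[0]
    res = pillai_manova(Y, g)
    assert 0.0 <= res.V < 1.0
    assert 0.0 < res.p <= 1.0
    perm = rng.permutation(n)
    res2 = pillai_manova(Y[perm], g[perm])
    assert res2.V == pytest.approx(res.V, abs=1e-12)
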