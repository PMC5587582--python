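"""Score estimation, replication testing, pleiotropy-profile consistency."""

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from pleioscan.replication import (
    ScoreModel,
    estimate_score,
    meta_analyze,
    partial_profile,
    profile_consistency,
    score_and_test,
)


def toy_cohort(rng, n=300, k=5, beta=None, maf=0.3):
    g = rng.binomial(2, maf, n).astype(float)
    Y = rng.standard_normal((n, k))
    if beta is not None:
        Y = Y + np.outer(g - g.mean(), beta)
    return pd.DataFrame(Y, columns=[f"t{j}" for j in range(k)]), g


class TestEstimateScore:
    def test_k1_is_simple_regression_coefficient(self, rng):
        Y, g = toy_cohort(rng, k=1, beta=[0.3])
        model = estimate_score(Y, g)
        y = Y["t0"] - Y["t0"].mean()
        gc = g - g.mean()
        assert model.alpha[0] == pytest.approx(float(gc @ y) / float(y @ y), rel=1e-10)

    def test_recovers_generative_direction(self):
        rng = np.random.default_rng(8)
        beta = np.array([0.5, -0.3, 0.4, 0.0, 0.2])
        # g depends on Y: build Y first, then g = Y beta + noise
        n = 2000
        Y = pd.DataFrame(rng.standard_normal((n, 5)), columns=[f"t{j}" for j in range(5)])
        g = Y.to_numpy() @ beta + rng.standard_normal(n)
        g = np.clip(g - g.min(), 0, None)
        g = 2 * g / g.max()
        model = estimate_score(Y, g)
        corr = np.corrcoef(model.alpha, beta)[0, 1]
        assert corr > 0.9

    def test_score_f_test_equals_manova_f(self, rng):
        Y, g = toy_cohort(rng, beta=[0.2, 0.1, 0.0, -0.1, 0.05])
        model = estimate_score(Y, g)
        rec = score_and_test(model, Y, g)  # self-replication
        k, n = 5, rec.n
        F_score = (rec.r2 / k) / ((1 - rec.r2) / (n - k - 1))
        res = ps.pillai_manova(Y.to_numpy(), g)
        assert F_score == pytest.approx(res.F, abs=1e-10)

    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ps.ValidationError):
            ScoreModel("v", "A", ["t1"], np.array([0.0]))

    def test_json_round_trip(self, tmp_path, rng):
        Y, g = toy_cohort(rng)
        model = estimate_score(Y, g, variant_id="rs1", effect_allele="T")
        model.to_json(tmp_path / "m.json")
        back = ScoreModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.alpha, model.alpha)
        assert back.effect_allele == "T"


class TestScoreAndTest:
    def test_self_replication_reproduces_discovery_p(self, rng):
        Y, g = toy_cohort(rng, beta=[0.3, 0.2, 0.0, 0.0, 0.0])
        model = estimate_score(Y, g)
        rec = score_and_test(model, Y, g)
        # discovery regression of S on g has the same p as any OLS fit of S~g
        S = Y.to_numpy() @ model.alpha
        from scipy.stats import linregress

        lr = linregress(g, S)
        assert rec.p_s == pytest.approx(lr.pvalue, rel=1e-10)
        assert rec.beta_s == pytest.approx(lr.slope, rel=1e-12)

    def test_allele_flip_negates_beta_exactly(self, rng):
        Y, g = toy_cohort(rng, beta=[0.3, 0.1, 0.0, 0.0, -0.1])
        model = estimate_score(Y, g, effect_allele="A")
        rec_same = score_and_test(model, Y, g, effect_allele_rep="A")
        rec_flip = score_and_test(model, Y, g, effect_allele_rep="G")
        assert rec_flip.beta_s == pytest.approx(-rec_same.beta_s, rel=1e-12)
        assert rec_flip.p_s == pytest.approx(rec_same.p_s, rel=1e-10)

    def test_null_beta_centered_on_zero(self):
        rng = np.random.default_rng(77)
        Y_disc, g_disc = toy_cohort(rng, n=200)
        model = estimate_score(Y_disc, g_disc)
        betas = []
        for _ in range(300):
            Y_rep, g_rep = toy_cohort(rng, n=200)
            betas.append(score_and_test(model, Y_rep, g_rep).beta_s)
        betas = np.array(betas)
        assert abs(betas.mean()) < 4 * betas.std(ddof=1) / np.sqrt(len(betas))

    def test_missing_traits_named(self, rng):
        Y, g = toy_cohort(rng)
        model = estimate_score(Y, g)
        with pytest.raises(ps.ValidationError, match="t4"):
            score_and_test(model, Y.drop(columns=["t4"]), g)


class TestPartialProfile:
    def test_k1_is_pearson_correlation(self, rng):
        Y, g = toy_cohort(rng, k=1, beta=[0.4])
        with pytest.warns(UserWarning):
            prof = partial_profile(Y, g)
        r = np.corrcoef(g, Y["t0"])[0, 1]
        assert prof.rho[0] == pytest.approx(r, abs=1e-10)

    def test_matrix_inversion_oracle_k2(self, rng):
        n = 40
        Y, g = toy_cohort(rng, n=n, k=2, beta=[0.5, -0.3])
        prof = partial_profile(Y, g)
        R = np.corrcoef(np.column_stack([g, Y.to_numpy()]), rowvar=False)
        Om = np.linalg.inv(R)
        expected = [-Om[0, j] / np.sqrt(Om[0, 0] * Om[j, j]) for j in (1, 2)]
        np.testing.assert_allclose(prof.rho, expected, atol=1e-10)

    def test_null_profile_is_small(self):
        rng = np.random.default_rng(3)
        n = 1000
        Y, g = toy_cohort(rng, n=n, k=6)
        prof = partial_profile(Y, g)
        assert np.max(np.abs(prof.rho)) < 5 / np.sqrt(n)

    def test_z_profile_standardized(self, rng):
        Y, g = toy_cohort(rng, k=8, beta=[0.1, -0.2, 0.3, 0, 0, 0.05, -0.1, 0.2])
        prof = partial_profile(Y, g)
        assert abs(prof.z.mean()) < 1e-10
        assert prof.z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestProfileConsistency:
    def _profile(self, z, names=None):
        k = len(z)
        names = names or [f"t{j}" for j in range(k)]
        z = np.asarray(z, float)
        z = (z - z.mean()) / z.std(ddof=1)
        return ps.PartialCorrelationProfile("v", names, np.tanh(z / 10), np.full(k, 0.1), z)

    def test_identical_profiles_give_r_one(self):
        p = self._profile([0.1, -0.5, 0.3, 0.8, -0.2])
        r, pval = profile_consistency(p, p)
        assert r == pytest.approx(1.0)
        assert pval == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_gives_minus_one(self):
        z = [0.1, -0.5, 0.3, 0.8, -0.2]
        r, _ = profile_consistency(self._profile(z), self._profile([-v for v in z]))
        assert r == pytest.approx(-1.0)

    def test_mismatched_traits_rejected(self):
        a = self._profile([0.1, 0.2, -0.3], names=["a", "b", "c"])
        b = self._profile([0.1, 0.2, -0.3], names=["a", "b", "d"])
        with pytest.raises(ps.ValidationError):
            profile_consistency(a, b)

    def test_consistency_grows_with_replication_n(self):
        """Shared pleiotropic model: r_rho rises toward 1 as replication n grows."""
        rng = np.random.default_rng(99)
        k = 8
        beta = rng.normal(0, 0.15, k)
        n_disc = 2000
        Y_d, g_d = toy_cohort(rng, n=n_disc, k=k, beta=beta)
        prof_d = partial_profile(Y_d, g_d)
        means = []
        for n_rep in (500, 2000, 8000):
            rs = []
            for _ in range(5):
                Y_r, g_r = toy_cohort(rng, n=n_rep, k=k, beta=beta)
                r, _ = profile_consistency(prof_d, partial_profile(Y_r, g_r))
                rs.append(r)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]


class TestMetaAnalyze:
    def test_identical_pair(self):
        beta, se, _ = meta_analyze([(0.4, 0.1), (0.4, 0.1)])
        assert beta == pytest.approx(0.4)
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_single_record_passthrough(self):
        beta, se, _ = meta_analyze([(0.3, 0.05)])
        assert (beta, se) == (pytest.approx(0.3), pytest.approx(0.05))

    def test_two_record_arithmetic(self):
        beta, se, _ = meta_analyze([(1.0, 1.0), (0.0, 1.0)])
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(1 / np.sqrt(2))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ps.ValidationError):
            meta_analyze([(0.4, 0.0)])
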