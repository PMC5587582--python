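"""The synthetic-cohort generator: determinism, genetics, power mechanism."""

import numpy as np
import pytest
from scipy import stats

import pleioscan as ps
from pleioscan.simulate import (
    CausalVariant,
    FamilyBlock,
    SimulationConfig,
    default_trait_groups,
    power_experiment,
    simulate_cohort,
    simulate_cohorts,
)


class TestConfigValidation:
    def test_bad_maf_rejected(self):
        with pytest.raises(ps.ValidationError):
            SimulationConfig(maf=1.5)

    def test_oversized_families_rejected(self):
        with pytest.raises(ps.ValidationError):
            SimulationConfig(n=10, families=[FamilyBlock("sib", 4, 5)])

    def test_non_pd_sigma_rejected(self):
        bad = np.array([[1.0, 1.1], [1.1, 1.0]])
        with pytest.raises(ps.ValidationError):
            SimulationConfig(k=2, sigma_e=bad)

    def test_causal_index_out_of_range_rejected(self):
        with pytest.raises(ps.ValidationError):
            SimulationConfig(m=10, k=2, causal=[CausalVariant(10, [0.1, 0.1])])

    def test_from_dict_round_trip(self):
        cfg = SimulationConfig.from_dict(
            {
                "n": 50,
                "m": 20,
                "k": 3,
                "maf": [0.1, 0.4],
                "families": [{"kind": "sib", "size": 2, "count": 10}],
                "causal": [{"index": 3, "beta": [0.1, 0.0, -0.2]}],
                "h2": 0.3,
            }
        )
        assert cfg.families[0].size == 2
        assert cfg.causal[0].index == 3


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        cfg = SimulationConfig(n=100, m=50, k=3, families=[FamilyBlock("sib", 2, 20)], h2=0.4, seed=5)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_allclose(
            a.phenotypes.traits.to_numpy(), b.phenotypes.traits.to_numpy(), atol=1e-12
        )

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n=100, m=50, k=3, seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg, seed=6)
        assert not np.array_equal(a.genotypes.dosages, b.genotypes.dosages)


class TestGenotypes:
    def test_allele_frequency_matches_target(self):
        cfg = SimulationConfig(n=500, m=2000, k=1, maf=0.3, seed=1)
        coh = simulate_cohort(cfg)
        freqs = coh.genotypes.allele_freq()
        assert abs(freqs.mean() - 0.3) < 0.02

    def test_sib_pairs_share_half_their_genome(self):
        cfg = SimulationConfig(
            n=400, m=3000, k=1, families=[FamilyBlock("sib", 2, 200)], seed=2
        )
        coh = simulate_cohort(cfg)
        K = ps.compute_grm(coh.genotypes)
        sib_mask = coh.kinship.values == 0.5
        assert abs(K.values[sib_mask].mean() - 0.5) < 0.05

    def test_parent_offspring_blocks_related(self):
        cfg = SimulationConfig(
            n=300, m=3000, k=1, families=[FamilyBlock("parent-offspring", 3, 100)], seed=4
        )
        coh = simulate_cohort(cfg)
        roles = coh.pedigree["role"].value_counts()
        assert roles["parent"] == 100 and roles["offspring"] == 200
        K = ps.compute_grm(coh.genotypes)
        rel = K.values[coh.kinship.values == 0.5]
        assert abs(rel.mean() - 0.5) < 0.05

    def test_jitter_sets_info_and_stays_in_range(self):
        cfg = SimulationConfig(n=200, m=100, k=1, dosage_jitter=0.2, seed=3)
        coh = simulate_cohort(cfg)
        d = coh.genotypes.dosages
        assert d.min() >= 0 and d.max() <= 2
        info = coh.genotypes.variants["info_score"]
        assert info.notna().all() and (info < 1).all()


class TestPhenotypes:
    def test_pure_noise_is_standard_normal(self):
        cfg = SimulationConfig(n=2000, m=10, k=2, h2=0.0, sigma_e_rho=0.0, seed=6)
        coh = simulate_cohort(cfg)
        for col in coh.phenotypes.traits.columns:
            _, p = stats.kstest(coh.phenotypes.traits[col], "norm")
            assert p > 0.01

    def test_variance_decomposition_recovers_h2(self):
        cfg = SimulationConfig(n=2000, m=10, k=3, h2=0.5, seed=8,
                               families=[FamilyBlock("sib", 4, 500)])
        coh = simulate_cohort(cfg)
        A = coh.truth["polygenic"]
        for j, col in enumerate(coh.phenotypes.traits.columns):
            y = coh.phenotypes.traits[col].to_numpy()
            r2 = np.corrcoef(y, A[:, j])[0, 1] ** 2  # share of variance explained
            assert abs(r2 - 0.5) < 0.07

    def test_residual_correlation_structure(self):
        cfg = SimulationConfig(n=4000, m=10, k=4, h2=0.0, sigma_e_rho=0.6, seed=9)
        coh = simulate_cohort(cfg)
        R = np.corrcoef(coh.phenotypes.traits.to_numpy(), rowvar=False)
        off = R[~np.eye(4, dtype=bool)]
        assert abs(off.mean() - 0.6) < 0.05

    def test_covariate_effects_added(self):
        cfg = SimulationConfig(n=1000, m=10, k=2, covariates=True, seed=10)
        coh = simulate_cohort(cfg)
        assert list(coh.phenotypes.covariates.columns) == ["age", "sex"]
        r = np.corrcoef(coh.phenotypes.traits["GP1"], coh.phenotypes.covariates["age"])[0, 1]
        assert abs(r) > 0.2

    def test_default_trait_groups_are_valid_subsets(self):
        names = [f"GP{i}" for i in range(1, 24)]
        groups = default_trait_groups(names)
        assert len(groups) == 8
        assert len(groups["galactosylation"]) == 17
        assert len(groups["sialylation"]) == 8
        for members in groups.values():
            assert len(set(members)) == len(members)
            assert set(members) <= set(names)


class TestTwoCohortMode:
    def test_shared_ground_truth_distinct_individuals(self):
        cfg = SimulationConfig(
            n=200, m=100, k=4, h2=0.3,
            causal=[CausalVariant(10, [0.2, -0.2, 0.1, 0.0])], seed=11,
        )
        disc, rep = simulate_cohorts(cfg, ns=[200, 150])
        np.testing.assert_array_equal(disc.truth["mafs"], rep.truth["mafs"])
        assert disc.truth["causal"] is not None
        assert not set(disc.genotypes.sample_ids) & set(rep.genotypes.sample_ids)
        assert rep.genotypes.n == 150


class TestPowerMechanism:
    def test_diffuse_effect_favors_joint_test(self):
        """A causal effect spread over several correlated traits: the joint
        chi-square signal exceeds the best univariate signal in most draws."""
        rng = np.random.default_rng(13)
        wins = 0
        n_seeds = 30
        k = 17
        beta = np.zeros(k)
        beta[:5] = np.array([1, -1, 1, -1, 1]) * 0.12
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n=800, m=20, k=k, sigma_e_rho=0.5, causal=[CausalVariant(0, beta)],
                seed=100 + seed,
            )
            coh = simulate_cohort(cfg)
            Y = coh.phenotypes.traits.to_numpy()
            g = coh.genotypes.dosages[:, 0]
            res = ps.pillai_manova(Y, g)
            chi_manova = stats.chi2.isf(res.p, 1)
            from pleioscan.simulate import _univariate_p

            chi_uni = stats.chi2.isf(_univariate_p(Y, g).min() * k, 1)
            if chi_manova > chi_uni:
                wins += 1
        assert wins > n_seeds / 2

    def test_power_experiment_null_calibration_and_table_shape(self):
        table = power_experiment([0.0], n=400, k=4, rho=0.5, n_reps=120, seed=5)
        assert set(table["method"]) == {"manova", "univariate-bonferroni", "tates"}
        for _, row in table.iterrows():
            # 99% binomial band around alpha = 0.05
            band = 2.576 * np.sqrt(0.05 * 0.95 / row["n_reps"])
            assert abs(row["power"] - 0.05) <= band + 1e-12
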