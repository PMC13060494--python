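import math

import numpy as np
import pytest
from scipy import stats

from radvar.aggregation_tests import (
    DEFAULT_RHO_GRID,
    acat_o_test,
    acat_v_test,
    bonferroni_threshold,
    burden_test,
    cauchy_combine,
    davies_pvalue,
    fit_null,
    liu_pvalue,
    run_gene_tests,
    single_variant_score_pvalues,
    skat_o_test,
    skat_test,
)
from radvar.exceptions import (
    ConfigurationError,
    DegenerateSetError,
    InputError,
    PerfectSeparationError,
)

from conftest import make_qset, random_rare_genotypes


class TestFitNull:
    def test_intercept_only_binary(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        null = fit_null(y, np.zeros((100, 0)), kind="binary")
        assert np.allclose(null.mu, 0.3, atol=1e-10)

    def test_perfect_fit_quantitative(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        null = fit_null(x * 2.0, x[:, None], kind="quantitative")
        assert np.max(np.abs(null.residuals)) < 1e-10

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 5))
        y = (rng.random(400) < 0.4).astype(float)
        null = fit_null(y, X, kind="binary")
        assert np.max(np.abs(null.X.T @ null.residuals)) < 1e-8

    def test_logistic_coefficient_recovery(self):
        rng = np.random.default_rng(2)
        n = 5000
        X = rng.normal(size=(n, 2))
        beta_true = np.array([-0.5, 0.8, -0.3])
        eta = beta_true[0] + X @ beta_true[1:]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        null = fit_null(y, X, kind="binary")
        info = null.X.T @ (null.v[:, None] * null.X)
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        assert np.all(np.abs(null.beta - beta_true) < 3 * se)

    def test_aliased_column_dropped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.warns(UserWarning, match="aliased"):
            null = fit_null(y, X, kind="binary")
        assert null.X.shape[1] == 2  # intercept + one of the pair

    def test_perfect_separation_raises(self):
        x = np.linspace(-3, 3, 60)
        y = (x > 0).astype(float)
        with pytest.raises(PerfectSeparationError, match="Firth"):
            fit_null(y, x[:, None], kind="binary")

    def test_binary_requires_01(self):
        with pytest.raises(InputError):
            fit_null(np.array([0.0, 2.0]), np.zeros((2, 0)), kind="binary")


class TestDavies:
    def test_chi2_1_tail(self):
        assert davies_pvalue([1.0], 3.841459) == pytest.approx(0.05, abs=1e-6)

    def test_q_zero_full_mass(self):
        assert davies_pvalue([1.0], 0.0) == 1.0

    def test_equal_lambdas_match_chi2(self):
        for m in (2, 3, 5, 8):
            q = 1.7 * m
            assert davies_pvalue([1.0] * m, q) == pytest.approx(
                stats.chi2.sf(q, m), abs=1e-8
            )

    def test_scaled_lambda_invariance(self):
        lam = np.array([2.0, 1.0, 0.5])
        assert davies_pvalue(lam, 4.0) == pytest.approx(
            davies_pvalue(10 * lam, 40.0), abs=1e-8
        )

    def test_against_monte_carlo(self):
        lam = np.array([2.0, 1.0, 0.5])
        rng = np.random.default_rng(7)
        draws = rng.chisquare(1, (200_000, 3)) @ lam
        for q in (2.0, 5.0, 10.0):
            p_mc = float((draws > q).mean())
            se = math.sqrt(p_mc * (1 - p_mc) / len(draws))
            assert abs(davies_pvalue(lam, q) - p_mc) < 3 * se

    def test_liu_agreement_in_bulk(self):
        lam = np.array([1.5, 1.0, 0.8, 0.5])
        q = float(lam.sum())
        assert abs(davies_pvalue(lam, q) - liu_pvalue(lam, q)) < 0.02

    def test_non_finite_raises(self):
        with pytest.raises(InputError):
            davies_pvalue([np.nan], 1.0)

    def test_no_positive_eigenvalues(self):
        with pytest.raises(DegenerateSetError):
            davies_pvalue([0.0], 1.0)

    def test_far_tail_uses_fallback_flag(self):
        p, fallback = davies_pvalue([1.0, 0.5], 500.0, return_detail=True)
        assert p < 1e-9
        assert fallback


class TestCauchyCombine:
    def test_single_half(self):
        assert cauchy_combine([0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_identical_components(self):
        assert cauchy_combine([0.1, 0.1]) == pytest.approx(0.1, abs=1e-10)

    def test_closed_form_example(self):
        expected = 0.5 - math.atan(
            (math.tan((0.5 - 0.01) * math.pi) + math.tan((0.5 - 0.99) * math.pi)) / 2
        ) / math.pi
        assert cauchy_combine([0.01, 0.99]) == pytest.approx(expected, rel=1e-10)

    def test_zero_p_rejected(self):
        with pytest.raises(InputError):
            cauchy_combine([0.0, 0.5])

    def test_tiny_p_dominates(self):
        assert cauchy_combine([1e-20, 0.5, 0.5]) < 1e-19

    def test_weights_normalized(self):
        assert cauchy_combine([0.3, 0.7], [2.0, 2.0]) == pytest.approx(
            cauchy_combine([0.3, 0.7], [1.0, 1.0]), abs=1e-12
        )

    def test_large_p_guard(self):
        p = cauchy_combine([0.9999, 0.9999])
        assert 0.99 < p <= 1.0

    def test_floor(self):
        assert cauchy_combine([1e-300, 1e-300]) >= 1e-300


class TestBurden:
    def test_single_variant_equals_score_test(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(8)
        G = random_rare_genotypes(rng, n, 1, (15, 15))
        qset = make_qset(G, weights=np.array([1.0]))
        res = burden_test(qset, null)
        p_single = single_variant_score_pvalues(qset, null)[0]
        assert res.p == pytest.approx(p_single, rel=1e-12)

    def test_planted_risk_direction(self):
        import radvar.synthetic_cohort as sc

        pos = 0
        for seed in range(20):
            cfg = sc.CohortConfig(
                n_per_ancestry={"EUR": 1000},
                case_fraction_per_ancestry={"EUR": 0.5},
                n_genes=2,
                variants_per_gene_mean=10.0,
                planted_genes=[sc.PlantedGene("G0000", "M2", math.log(3.0), "risk")],
                singleton_fraction_target=0.2,
                seed=seed,
            )
            c = sc.simulate_cohort(cfg)
            idx = c.annotations.index[c.annotations.gene == "G0000"].to_numpy()
            G = np.where(c.genotypes[:, idx] < 0, 0, c.genotypes[:, idx])
            keep = G.sum(axis=0) > 0
            null = fit_null(c.case_status, c.covariate_matrix(), "binary")
            res = burden_test(make_qset(G[:, keep]), null)
            pos += res.statistic > 0
        assert pos >= 19

    def test_permutation_null_uniform(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(9)
        G = random_rare_genotypes(rng, n, 5, (10, 30))
        ps = []
        for _ in range(500):
            yp = rng.permutation(y)
            null_p = fit_null(yp, X, kind="binary")
            ps.append(burden_test(make_qset(G), null_p).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_raises(self, balanced_null):
        null, X, y, n = balanced_null
        G = np.ones((n, 1), dtype=np.int8)  # constant dosage: variance 0
        with pytest.raises(DegenerateSetError):
            burden_test(make_qset(G), null)


class TestSkat:
    def test_single_variant_matches_burden(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(10)
        G = random_rare_genotypes(rng, n, 1, (20, 20))
        qset = make_qset(G)
        assert skat_test(qset, null).p == pytest.approx(
            burden_test(qset, null).p, rel=1e-6
        )

    def test_small_set_against_mixture_mc(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(11)
        G = random_rare_genotypes(rng, n, 3, (10, 30))
        qset = make_qset(G)
        res = skat_test(qset, null)
        # Monte Carlo draw from the fitted chi-square mixture
        Gw = G.astype(float) * qset.weights[None, :]
        A = null.score_cross_product(Gw)
        lam = np.linalg.eigvalsh(A)
        lam = lam[lam > 1e-10 * lam.max()]
        draws = rng.chisquare(1, (200_000, len(lam))) @ lam
        p_mc = float((draws > res.statistic).mean())
        se = math.sqrt(max(p_mc * (1 - p_mc), 1e-12) / len(draws))
        assert abs(res.p - p_mc) < 3 * se + 1e-6


class TestSkatO:
    def test_endpoint_grid_identities(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(12)
        G = random_rare_genotypes(rng, n, 4, (10, 25))
        qset = make_qset(G)
        assert skat_o_test(qset, null, [1.0]).p == pytest.approx(
            burden_test(qset, null).p, rel=1e-10
        )
        assert skat_o_test(qset, null, [0.0]).p == pytest.approx(
            skat_test(qset, null).p, rel=1e-10
        )

    def test_bonferroni_bound_and_floor(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(13)
        for _ in range(100):
            G = random_rare_genotypes(rng, n, int(rng.integers(2, 7)), (5, 30))
            qset = make_qset(G)
            res = skat_o_test(qset, null)
            comp = res.detail["component_p"]
            min_p = min(comp.values())
            assert min_p - 1e-12 <= res.p <= min_p * len(DEFAULT_RHO_GRID) + 1e-12

    def test_empty_grid_rejected(self, balanced_null):
        null, *_ = balanced_null
        G = random_rare_genotypes(np.random.default_rng(1), len(null.y), 2)
        with pytest.raises(ConfigurationError):
            skat_o_test(make_qset(G), null, [])


class TestAcat:
    def test_single_common_variant_identity(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(14)
        G = random_rare_genotypes(rng, n, 1, (25, 25))  # MAC 25 > threshold 10
        qset = make_qset(G)
        res = acat_v_test(qset, null)
        assert res.p == pytest.approx(single_variant_score_pvalues(qset, null)[0],
                                      rel=1e-10)

    def test_all_collapsed_equals_burden_of_rare(self, balanced_null):
        null, X, y, n = balanced_null
        rng = np.random.default_rng(15)
        G = random_rare_genotypes(rng, n, 4, (2, 5))  # all MAC <= 10
        qset = make_qset(G)
        assert acat_v_test(qset, null).p == pytest.approx(
            burden_test(qset, null).p, rel=1e-10
        )

    def test_acat_o_symmetry(self):
        assert acat_o_test("g", "M1", [0.5, 0.5, 0.5]).p == pytest.approx(0.5, abs=1e-10)

    def test_acat_o_identity(self):
        assert acat_o_test("g", "M1", [0.123]).p == pytest.approx(0.123, abs=1e-10)

    def test_acat_o_small_component(self):
        assert acat_o_test("g", "M1", [1e-6, 0.5, 0.5]).p < 1e-5

    def test_acat_o_no_components(self):
        with pytest.raises(DegenerateSetError):
            acat_o_test("g", "M1", [])


class TestBonferroni:
    def test_study_threshold(self):
        t = bonferroni_threshold(0.05, 30_276)
        assert f"{t:.3g}" == "1.65e-06"

    def test_single_gene(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_arithmetic(self):
        assert bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(0.05, 0)


class TestDeterminismAndCollapse:
    def test_all_tests_deterministic(self, balanced_null):
        null, X, y, n = balanced_null
        G = random_rare_genotypes(np.random.default_rng(16), n, 5, (8, 25))
        qset = make_qset(G)
        r1 = {r.test: r.p for r in run_gene_tests(qset, null)}
        r2 = {r.test: r.p for r in run_gene_tests(qset, null)}
        assert r1 == r2

    def test_single_variant_collapse_all_tests_agree(self, balanced_null):
        null, X, y, n = balanced_null
        G = random_rare_genotypes(np.random.default_rng(17), n, 1, (20, 20))
        qset = make_qset(G)
        pb = burden_test(qset, null).p
        assert skat_test(qset, null).p == pytest.approx(pb, rel=1e-6)
        assert acat_v_test(qset, null).p == pytest.approx(pb, rel=1e-6)


class TestPowerOrdering:
    """Burden beats SKAT for same-direction effects; reverses when mixed."""

    @staticmethod
    def _power(flip_half: bool, n=400, m=6, reps=120, effect=0.55):
        rng = np.random.default_rng(18 if flip_half else 19)
        rej_b = rej_s = 0
        for _ in range(reps):
            G = random_rare_genotypes(rng, n, m, (8, 20))
            beta = np.full(m, effect)
            if flip_half:
                beta[::2] *= -1
            y = G @ beta + rng.normal(size=n)
            null = fit_null(y, np.zeros((n, 0)), kind="quantitative")
            qset = make_qset(G)
            rej_b += burden_test(qset, null).p < 0.05
            rej_s += skat_test(qset, null).p < 0.05
        return rej_b / reps, rej_s / reps

    def test_same_direction_burden_wins(self):
        pb, ps = self._power(flip_half=False)
        assert pb >= ps - 0.05

    def test_mixed_direction_skat_wins(self):
        pb, ps = self._power(flip_half=True)
        assert ps >= pb + 0.1
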