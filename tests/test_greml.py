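"""Variance-component core: REML optima against dense grid-search
oracles, degenerate inputs, invariances, and the covariance identity."""

import numpy as np
import pytest

from snpherit import (
    BivariateGREML,
    ConfigError,
    GREML,
    SimConfig,
    compute_grm,
    genetic_contribution,
    mediation_decomposition,
    reml_bivariate,
    reml_univariate,
    simulate_cohort,
)


def random_grm(n, m, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, m))
    z = (z - z.mean(0)) / z.std(0)
    return z @ z.T / m


def dense_uni_loglik(a, y, x, vg, ve):
    """Naive restricted log-likelihood, no rotation tricks."""
    n = len(y)
    v = vg * a + ve * np.eye(n)
    if np.linalg.eigvalsh(v)[0] <= 0:
        return -np.inf
    sign, ld = np.linalg.slogdet(v)
    vi = np.linalg.inv(v)
    xtvx = x.T @ vi @ x
    s2, ld2 = np.linalg.slogdet(xtvx)
    if s2 <= 0:
        return -np.inf
    p = vi - vi @ x @ np.linalg.inv(xtvx) @ x.T @ vi
    return -0.5 * (ld + ld2 + y @ p @ y)


def dense_biv_loglik(a, y1, y2, x, theta):
    vg1, vg2, cg, ve1, ve2, ce = theta
    n = len(y1)
    g = np.array([[vg1, cg], [cg, vg2]])
    e = np.array([[ve1, ce], [ce, ve2]])
    v = np.kron(g, a) + np.kron(e, np.eye(n))
    if np.linalg.eigvalsh(v)[0] <= 0:
        return -np.inf
    sign, ld = np.linalg.slogdet(v)
    xs = np.kron(np.eye(2), x)
    vi = np.linalg.inv(v)
    xtvx = xs.T @ vi @ xs
    s2, ld2 = np.linalg.slogdet(xtvx)
    if s2 <= 0:
        return -np.inf
    p = vi - vi @ xs @ np.linalg.inv(xtvx) @ xs.T @ vi
    y = np.concatenate([y1, y2])
    return -0.5 * (ld + ld2 + y @ p @ y)


class TestUnivariate:
    def test_optimum_matches_dense_grid_search(self):
        rng = np.random.default_rng(0)
        n = 40
        a = random_grm(n, 80, 1)
        y = rng.standard_normal(n)
        x = np.ones((n, 1))
        est = GREML().fit(a, y)
        # the rotated likelihood agrees with the naive dense formula
        for vg, ve in [(0.3, 0.7), (0.1, 0.9), (est.vg_, est.ve_)]:
            assert abs(est.loglik_at(vg, ve)
                       - dense_uni_loglik(a, y, x, vg, ve)) < 1e-8
        # and the fit dominates a dense grid around the optimum
        grid = np.linspace(-0.3, 1.5, 120)
        best = max(dense_uni_loglik(a, y, x, vg, ve)
                   for vg in grid for ve in np.linspace(0.05, 1.5, 120))
        assert est.loglik_ >= best - 1e-6

    def test_identity_grm_not_identifiable(self):
        with pytest.raises(ConfigError, match="identity"):
            GREML().fit(np.eye(60), np.random.default_rng(2).standard_normal(60))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        n = 80
        a = random_grm(n, 150, 4)
        y = rng.standard_normal(n)
        c = rng.standard_normal(n)
        r1 = reml_univariate(y, a, c)
        perm = rng.permutation(n)
        r2 = reml_univariate(y[perm], a[np.ix_(perm, perm)], c[perm])
        assert abs(r1.v_g - r2.v_g) < 1e-8
        assert abs(r1.loglik - r2.loglik) < 1e-8

    def test_variance_components_sum_near_total(self, small_cohort):
        co = small_cohort
        grm = compute_grm(co.children)
        r = reml_univariate(co.phenotypes["achievement"], grm)
        assert abs((r.v_g + r.v_e) - 1.0) < 0.05
        assert r.se_vg > 0 and r.converged

    def test_constrained_mode_nonnegative(self):
        rng = np.random.default_rng(5)
        n = 100
        a = random_grm(n, 400, 6)
        y = rng.standard_normal(n)  # no genetic signal
        r = reml_univariate(y, a, constrained=True)
        assert r.v_g >= 0.0


class TestBivariate:
    def test_optimum_matches_dense_grid_search(self):
        n = 30
        a = random_grm(n, 60, 7)
        rng = np.random.default_rng(8)
        y1 = rng.standard_normal(n)
        y2 = 0.5 * y1 + 0.8 * rng.standard_normal(n)
        x = np.ones((n, 1))
        est = BivariateGREML().fit(a, np.column_stack([y1, y2]))
        th = np.array([est.vg1_, est.vg2_, est.cg_, est.ve1_, est.ve2_, est.ce_])
        assert abs(est.loglik_ - dense_biv_loglik(a, y1, y2, x, th)) < 1e-8
        # coarse 6-parameter grid, refined locally around the optimum
        best = -np.inf
        for dv in np.linspace(-0.2, 0.2, 5):
            for dc in np.linspace(-0.15, 0.15, 5):
                for de in np.linspace(-0.2, 0.2, 5):
                    cand = th + np.array([dv, -dv, dc, de, -de, -dc])
                    best = max(best, dense_biv_loglik(a, y1, y2, x, cand))
        for trial in range(200):
            cand = th + np.random.default_rng(trial).uniform(-0.1, 0.1, 6)
            best = max(best, dense_biv_loglik(a, y1, y2, x, cand))
        assert est.loglik_ >= best - 1e-5

    def test_identical_traits_degenerate(self):
        n = 60
        a = random_grm(n, 120, 9)
        y = np.random.default_rng(10).standard_normal(n)
        r = reml_bivariate(y, y, a)
        assert r.degenerate_identical_traits
        assert abs(r.r_g - 1.0) < 1e-6
        assert abs(r.v_g1 - r.v_g2) < 1e-12
        assert abs(r.c_g - r.v_g1) < 1e-12

    def test_null_genetic_correlation(self):
        # disjoint causal sets generate r_g = 0; single-replicate
        # estimates are noisy (se ~ 0.3 at this size), so test the
        # replicate mean against the null
        rgs, ses = [], []
        for r in range(5):
            cfg = SimConfig(n_individuals=600, n_snps=1200, n_causal_shared=0,
                            n_causal_specific_per_trait=150, rg_target=0.0,
                            r_p_target=0.3, parental_mode=False, seed=600 + r)
            co = simulate_cohort(cfg)
            grm = compute_grm(co.children)
            res = reml_bivariate(co.phenotypes["achievement"],
                                 co.phenotypes["ses"], grm)
            if np.isfinite(res.r_g):
                rgs.append(res.r_g)
                ses.append(res.se_rg)
        assert len(rgs) >= 3
        tol = 2 * np.mean(ses) / np.sqrt(len(rgs)) + 0.05
        assert abs(np.mean(rgs)) < tol

    def test_identity_recomputed(self, small_cohort):
        grm = compute_grm(small_cohort.children)
        r = reml_bivariate(small_cohort.phenotypes["achievement"],
                           small_cohort.phenotypes["ses"], grm)
        assert np.isclose(r.genetic_contribution,
                          r.r_g * np.sqrt(r.v_g1 * r.v_g2))
        assert np.isclose(r.proportion_tagged,
                          r.genetic_contribution / r.phenotypic_correlation)


class TestGeneticContribution:
    def test_worked_example(self):
        assert round(genetic_contribution(1.02, 0.31, 0.20), 2) == 0.25

    def test_zero_correlation(self):
        assert genetic_contribution(0.0, 0.4, 0.9) == 0.0

    def test_equal_variances_identity(self):
        assert np.isclose(genetic_contribution(1.0, 0.37, 0.37), 0.37)

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            genetic_contribution(0.5, -0.1, 0.2)


@pytest.fixture(scope="module")
def cohort_grm():
    cfg = SimConfig(n_individuals=500, n_snps=800, n_causal_shared=150,
                    seed=12)
    co = simulate_cohort(cfg)
    return co, compute_grm(co.children)


class TestMediation:
    def test_null_mediator_changes_nothing(self, cohort_grm):
        co, grm = cohort_grm
        rng = np.random.default_rng(13)
        noise = rng.standard_normal(grm.n)
        med = mediation_decomposition(co.phenotypes["achievement"],
                                      co.phenotypes["ses"], noise, grm)
        tol = 2 * (med.before.se_cg + med.after.se_cg)
        assert abs(med.delta_cg) < tol
        assert abs(med.delta_phenotypic_correlation) < 0.1

    def test_total_mediation_leaves_noise(self, cohort_grm):
        # a mediator carrying (almost) all of y1: the residual is the
        # small independent remainder, so the genetic covariance vanishes
        co, grm = cohort_grm
        y1 = co.phenotypes["achievement"].to_numpy()
        rng = np.random.default_rng(14)
        mediator = y1 + 0.05 * rng.standard_normal(y1.size)
        med = mediation_decomposition(y1, co.phenotypes["ses"], mediator, grm)
        assert abs(med.after.c_g) < 3 * med.after.se_cg + 0.02

    def test_mediator_without_residual_rejected(self, cohort_grm):
        co, grm = cohort_grm
        y1 = co.phenotypes["achievement"]
        with pytest.raises(ConfigError, match="residual"):
            mediation_decomposition(y1, co.phenotypes["ses"], y1, grm)

    def test_printed_pair_arithmetic(self):
        # proportion mediated from a covariance drop 0.25 -> 0.17
        assert np.isclose((0.25 - 0.17) / 0.25, 0.32)

    def test_constant_mediator_rejected(self, cohort_grm):
        co, grm = cohort_grm
        with pytest.raises(ConfigError, match="constant"):
            mediation_decomposition(co.phenotypes["achievement"],
                                    co.phenotypes["ses"],
                                    np.ones(grm.n), grm)

    def test_shared_factor_mediator_reduces_cg(self, cohort_grm):
        # the generator routes a third of the shared factor through IQ
        co, grm = cohort_grm
        med = mediation_decomposition(co.phenotypes["achievement"],
                                      co.phenotypes["ses"],
                                      co.phenotypes["iq"], grm)
        assert med.after.c_g < med.before.c_g + med.before.se_cg
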