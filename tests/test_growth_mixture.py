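import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

import ltagmm
from ltagmm.growth_mixture import (
    EStepResult,
    GMMParams,
    StageSpec,
    _e_step_matrix,
    _pattern_groups,
    _run_em,
    canonicalize,
    count_params,
    e_step,
    fit_gmm,
    implied_moments,
    m_step,
    marginal_loglik,
)


def two_class_params(**kw):
    defaults = dict(
        weights=[0.6, 0.4],
        means=[[-1.10, 0.93], [-1.58, 0.89]],
        covs=[[[0.18, -0.05], [-0.05, 0.04]], [[0.16, -0.05], [-0.05, 0.09]]],
        resid_var=[0.09, 0.09, 0.09],
        cov_equal_across_classes=True,
    )
    defaults.update(kw)
    return GMMParams(**defaults)


class TestStageSpec:
    def test_time_scores_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            StageSpec(1, ("a", "b"), (0.5, 1.0))
        with pytest.raises(ValueError):
            StageSpec(1, ("a", "b"), (0.0, 0.0))

    def test_loadings_matrix(self, toy_spec):
        np.testing.assert_allclose(
            toy_spec.loadings, [[1, 0], [1, 0.5], [1, 1.5]]
        )


class TestImpliedMoments:
    def test_deterministic_limit(self, toy_spec):
        p = GMMParams(
            weights=[1.0], means=[[2.0, 1.0]],
            covs=[np.zeros((2, 2))], resid_var=[1e-8, 1e-8, 1e-8],
        )
        spec = StageSpec(1, ("a", "b"), (0.0, 1.0), K=1)
        p2 = GMMParams(
            weights=[1.0], means=[[2.0, 1.0]],
            covs=[np.zeros((2, 2))], resid_var=[1e-8, 1e-8],
        )
        mean, cov = implied_moments(p2, spec, 0)
        np.testing.assert_allclose(mean, [2.0, 3.0])
        np.testing.assert_allclose(cov, np.zeros((2, 2)), atol=1e-7)

    def test_high_class_trajectory_means(self, toy_spec):
        mean, _ = implied_moments(two_class_params(), toy_spec, 0)
        np.testing.assert_allclose(mean, [-1.10, -0.635, 0.295])

    def test_covariance_hand_expansion(self, toy_spec):
        p = two_class_params(resid_var=[0.1, 0.1, 0.1])
        _, cov = implied_moments(p, toy_spec, 0)
        # cov(y1, y3) = var(INT) + 1.5 cov(INT, SLP)
        assert cov[0, 2] == pytest.approx(0.18 + 1.5 * -0.05)
        assert cov[0, 0] == pytest.approx(0.18 + 0.1)

    def test_out_of_range_class_rejected(self, toy_spec):
        with pytest.raises(IndexError):
            implied_moments(two_class_params(), toy_spec, 5)


class TestMarginalLoglik:
    def test_single_class_equals_direct_mvn(self, toy_spec):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((5, 3))
        p = two_class_params(weights=[1 - 1e-12, 1e-12])
        p1 = GMMParams(
            weights=[1.0], means=[p.means[0]], covs=[p.covs[0]],
            resid_var=p.resid_var[:1],
        )
        mean, cov = implied_moments(p1, toy_spec, 0)
        direct = multivariate_normal(mean, cov).logpdf(Y).sum()
        assert marginal_loglik(p1, toy_spec, Y) == pytest.approx(direct, abs=1e-8)

    def test_two_class_matches_brute_force_density_sum(self, toy_spec):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((5, 3)) - 1.0
        p = two_class_params()
        dens = np.zeros(5)
        for c, w in enumerate(p.weights):
            mean, cov = implied_moments(p, toy_spec, c)
            dens += w * multivariate_normal(mean, cov).pdf(Y)
        assert marginal_loglik(p, toy_spec, Y) == pytest.approx(
            np.log(dens).sum(), abs=1e-8
        )

    def test_missing_entries_use_observed_subvector(self, toy_spec):
        Y = np.array([[-1.0, np.nan, 0.3], [np.nan, -0.5, np.nan]])
        p = two_class_params()
        total = 0.0
        for row in Y:
            o = ~np.isnan(row)
            dens = 0.0
            for c, w in enumerate(p.weights):
                mean, cov = implied_moments(p, toy_spec, c)
                dens += w * multivariate_normal(
                    mean[o], cov[np.ix_(o, o)]
                ).pdf(row[o])
            total += np.log(dens)
        assert marginal_loglik(p, toy_spec, Y) == pytest.approx(total, abs=1e-8)

    def test_duplicating_units_doubles_loglik(self, toy_spec):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((4, 3))
        p = two_class_params()
        assert marginal_loglik(p, toy_spec, np.vstack([Y, Y])) == pytest.approx(
            2 * marginal_loglik(p, toy_spec, Y), abs=1e-8
        )

    def test_unit_with_no_observed_indicators_rejected(self, toy_spec):
        Y = np.array([[np.nan, np.nan, np.nan], [0.0, 0.1, 0.2]])
        with pytest.raises(ValueError, match="no observed indicators"):
            marginal_loglik(two_class_params(), toy_spec, Y)

    def test_unit_order_invariance(self, toy_spec):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((20, 3))
        p = two_class_params()
        perm = rng.permutation(20)
        assert marginal_loglik(p, toy_spec, Y[perm]) == pytest.approx(
            marginal_loglik(p, toy_spec, Y), abs=1e-8
        )


class TestEStep:
    def test_identical_classes_give_uniform_responsibilities(self, toy_spec):
        p = two_class_params(
            weights=[0.5, 0.5],
            means=[[-1.1, 0.9], [-1.1, 0.9]],
            covs=[[[0.18, -0.05], [-0.05, 0.04]]] * 2,
        )
        Y = np.array([[-1.0, -0.6, 0.3], [0.0, 0.2, 0.4]])
        est = e_step(p, toy_spec, Y)
        np.testing.assert_allclose(est.responsibilities, 0.5, atol=1e-12)

    def test_degenerate_prior_pins_posterior_factor_mean(self, toy_spec):
        p = two_class_params(
            covs=[np.zeros((2, 2))] * 2, cov_equal_across_classes=True
        )
        Y = np.array([[5.0, 5.0, 5.0]])
        est = e_step(p, toy_spec, Y)
        np.testing.assert_allclose(est.post_mean[0, 0], p.means[0], atol=1e-10)
        np.testing.assert_allclose(est.post_mean[0, 1], p.means[1], atol=1e-10)

    def test_responsibilities_match_bayes_arithmetic(self, toy_spec):
        p = two_class_params(weights=[0.7, 0.3])
        y = np.array([[-1.3, -0.8, 0.0]])
        d = []
        for c in range(2):
            mean, cov = implied_moments(p, toy_spec, c)
            d.append(p.weights[c] * multivariate_normal(mean, cov).pdf(y[0]))
        expected = d[0] / (d[0] + d[1])
        est = e_step(p, toy_spec, y)
        assert est.responsibilities[0, 0] == pytest.approx(expected, abs=1e-10)
        assert est.responsibilities.sum(axis=1) == pytest.approx(1.0, abs=1e-10)


class TestMStep:
    def test_noise_free_truth_is_fixed_point(self, toy_spec):
        # deterministic trajectories: all mass on the class means
        p = two_class_params(
            covs=[np.zeros((2, 2))] * 2, resid_var=[1e-4] * 3,
            weights=[0.75, 0.25],
        )
        L = toy_spec.loadings
        Y = np.vstack([np.tile(L @ p.means[0], (3, 1)), L @ p.means[1]])
        est = e_step(p, toy_spec, Y)
        new = m_step(Y, toy_spec, est, True, True, prev_covs=p.covs)
        np.testing.assert_allclose(new.weights, p.weights, atol=1e-10)
        np.testing.assert_allclose(new.means, p.means, atol=1e-8)
        np.testing.assert_allclose(new.covs, p.covs, atol=1e-8)

    def test_single_class_reduces_to_lgm_update(self, toy_spec):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((50, 3))
        spec1 = StageSpec(1, toy_spec.indicators, toy_spec.time_scores, K=1)
        p = GMMParams(
            weights=[1.0], means=[[0.0, 0.0]],
            covs=[np.eye(2) * 0.5], resid_var=[1.0, 1.0, 1.0],
        )
        est = e_step(p, spec1, Y)
        new = m_step(Y, spec1, est, False, True)
        # single class: mean update is the responsibility-free average
        np.testing.assert_allclose(
            new.means[0], est.post_mean[:, 0, :].mean(axis=0), atol=1e-10
        )


class TestEMDriver:
    def test_loglik_trace_monotone_over_seeded_microdata(self):
        spec = StageSpec(1, ("y1", "y2", "y3"), (0.0, 0.5, 1.5), K=2)
        bad = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((40, 3)) + rng.choice(
                [-1.0, 0.5], size=(40, 1)
            )
            trace = []
            p0 = two_class_params(weights=[0.5, 0.5])
            try:
                _run_em(Y, spec, p0, 1e-5, 60, True, True, trace)
            except Exception:
                bad += 1
                continue
            t = np.asarray(trace)
            assert np.all(np.diff(t) >= -1e-6 * (1 + np.abs(t[:-1])))
        assert bad == 0

    def test_k1_matches_direct_structured_ml(self, toy_spec):
        rng = np.random.default_rng(5)
        n = 120
        eta = rng.multivariate_normal([-1.0, 0.9], [[0.2, -0.04], [-0.04, 0.05]], n)
        Y = eta[:, [0]] + np.outer(eta[:, 1], [0, 0.5, 1.5])
        Y += 0.3 * rng.standard_normal(Y.shape)
        spec1 = StageSpec(1, toy_spec.indicators, toy_spec.time_scores, K=1)
        fit = fit_gmm(Y, spec1, n_starts=2, seed=0, tol=1e-9)

        # independent oracle: direct ML over the structured MVN parameters
        L = spec1.loadings

        def nll(x):
            mu = x[:2]
            a, b, r = np.exp(x[2]), np.exp(x[3]), x[4]
            if r**2 >= a * b:
                return 1e10
            psi = np.array([[a, r], [r, b]])
            th = np.exp(x[5:8])
            cov = L @ psi @ L.T + np.diag(th)
            return -multivariate_normal(L @ mu, cov).logpdf(Y).sum()

        res = minimize(
            nll,
            np.array([-1, 0.9, np.log(0.2), np.log(0.05), -0.04, *np.log([0.09] * 3)]),
            method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10},
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=0.05)
        assert fit.loglik >= -res.fun - 1e-6

    def test_recovery_on_well_separated_stage2(self):
        cfg = ltagmm.final_model_null(n=2000, seed=31)
        panel = ltagmm.generate(cfg)
        _, s2 = ltagmm.stage_specs(cfg)
        fit = fit_gmm(panel, s2, n_starts=8, seed=1)
        assert fit.params.weights[0] == pytest.approx(0.952, abs=0.02)
        np.testing.assert_allclose(
            fit.params.means, [[0.41, 0.12], [-0.48, 0.19]], atol=0.03
        )

    def test_permuting_units_leaves_loglik_unchanged(self, small_two_class_data):
        cfg = ltagmm.final_model_null(n=600, seed=11)
        _, s2 = ltagmm.stage_specs(cfg)
        Y = small_two_class_data.values(s2.indicators)
        fit = fit_gmm(Y, s2, n_starts=4, seed=2)
        perm = np.random.default_rng(0).permutation(len(Y))
        assert marginal_loglik(fit.params, s2, Y[perm]) == pytest.approx(
            fit.loglik, abs=1e-8
        )

    def test_canonical_labels_invariant_to_start_seed(self, small_two_class_data):
        cfg = ltagmm.final_model_null(n=600, seed=11)
        _, s2 = ltagmm.stage_specs(cfg)
        fits = [
            fit_gmm(small_two_class_data, s2, n_starts=4, seed=s) for s in (3, 4)
        ]
        np.testing.assert_allclose(
            fits[0].params.weights, fits[1].params.weights, atol=1e-3
        )
        np.testing.assert_allclose(
            fits[0].params.means, fits[1].params.means, atol=1e-2
        )

    def test_canonicalize_is_idempotent(self):
        p = two_class_params(weights=[0.3, 0.7])
        c1, _ = canonicalize(p)
        c2, order = canonicalize(c1)
        assert c1.weights[0] == 0.7
        np.testing.assert_array_equal(order, [0, 1])
        np.testing.assert_allclose(c1.means, c2.means)


class TestCountParams:
    @pytest.mark.parametrize(
        "K,cov_eq,resid_eq,expected",
        [
            (1, False, True, 8),  # 2 means + 3 Psi + 3 theta
            (2, True, True, 13),  # 1 + 4 + (4 var + 1 cov) + 3
            (3, True, True, 18),  # one more class adds 2 means + 2 var + 1 weight
            (2, False, False, 15),  # 1 + 4 + 6 + 4... on 3 indicators: 1+4+6+6=17
        ],
    )
    def test_enumerated_counts(self, toy_spec, K, cov_eq, resid_eq, expected):
        spec = StageSpec(1, toy_spec.indicators, toy_spec.time_scores, K=K)
        if (K, cov_eq, resid_eq) == (2, False, False):
            expected = 1 + 4 + 6 + 6
        assert count_params(spec, cov_eq, resid_eq) == expected
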