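import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import log_expit

from irtmiss.datagen import DesignCell, generate_dataset
from irtmiss.irt2pl import (
    default_grid,
    fit_2pl,
    fit_2pl_latent_regression,
    person_posterior,
)
from irtmiss.scoring import score_as_wrong


def marginal_loglik(x_matrix, a, b, grid=None):
    """Independent evaluation of the 2PL marginal log-likelihood."""
    grid = grid or default_grid()
    r = ~np.isnan(x_matrix)
    x = np.nan_to_num(x_matrix)
    eta = np.asarray(a)[:, None] * (grid.points[None, :] - np.asarray(b)[:, None])
    lp, lq = log_expit(eta), log_expit(-eta)
    logl = (x * r) @ lp + ((1 - x) * r) @ lq + np.log(grid.prior_weights)
    m = logl.max(axis=1, keepdims=True)
    return float((np.log(np.exp(logl - m).sum(axis=1)) + m[:, 0]).sum())


@pytest.fixture(scope="module")
def toy_binary():
    rng = np.random.default_rng(77)
    theta = rng.standard_normal(50)
    a_true, b_true = np.array([1.2, 0.8]), np.array([-0.5, 0.7])
    p = 1 / (1 + np.exp(-a_true * (theta[:, None] - b_true)))
    return (rng.random((50, 2)) < p).astype(float)


class TestFit2PL:
    def test_em_beats_brute_force_grid(self, toy_binary):
        fit = fit_2pl(toy_binary)
        rng = np.random.default_rng(5)
        best = -np.inf
        for _ in range(4000):
            a = rng.uniform(0.1, 4.0, size=2)
            b = rng.uniform(-3.0, 3.0, size=2)
            best = max(best, marginal_loglik(toy_binary, a, b))
        for a1 in np.linspace(0.3, 3, 7):
            for b1 in np.linspace(-2, 2, 7):
                for a2 in np.linspace(0.3, 3, 7):
                    for b2 in np.linspace(-2, 2, 7):
                        best = max(
                            best, marginal_loglik(toy_binary, [a1, a2], [b1, b2])
                        )
        assert fit.loglik >= best - 1e-9

    def test_matches_direct_optimization(self, toy_binary):
        fit = fit_2pl(toy_binary, tol_ll=1e-12, tol_par=1e-8, max_iter=5000)

        def neg(par):
            return -marginal_loglik(toy_binary, par[:2], par[2:])

        res = minimize(neg, [1.0, 1.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_loglik_monotone_over_iterations(self, small_dataset):
        data, truth, _ = small_dataset
        fit = fit_2pl(score_as_wrong(data))
        assert np.all(np.diff(fit.loglik_history) > -1e-7)

    def test_consistency_at_truth(self):
        rng = np.random.default_rng(8)
        theta = rng.standard_normal(10_000)
        p = 1 / (1 + np.exp(-theta))
        x = (rng.random((10_000, 2)) < p[:, None]).astype(float)
        fit = fit_2pl(x)
        assert np.all(np.abs(fit.difficulty) < 3 * 0.05)
        assert np.all(np.abs(fit.discrimination - 1) < 0.15)

    def test_default_grid_is_21_points_on_pm5(self):
        g = default_grid()
        assert g.size == 21 and g.points[0] == -5 and g.points[-1] == 5

    def test_fractional_entries_match_stacked_imputations(self):
        # pseudo-likelihood with cells at 1/K operationally agrees with
        # scaling a large stack of Bernoulli(1/K) imputations of those cells;
        # the two estimators coincide only approximately, the agreement
        # improving with test length, so a realistic length is used
        rng = np.random.default_rng(11)
        n, n_items = 2000, 20
        theta = rng.standard_normal(n)
        b = np.linspace(-1.5, 1.5, n_items)
        p = 1 / (1 + np.exp(-(theta[:, None] - b)))
        x = (rng.random((n, n_items)) < p).astype(float)
        miss = rng.random((n, n_items)) < 0.10
        frac = x.copy()
        frac[miss] = 0.25
        fit_frac = fit_2pl(frac)
        stacks = []
        for _ in range(60):
            imp = x.copy()
            imp[miss] = (rng.random(miss.sum()) < 0.25).astype(float)
            stacks.append(imp)
        fit_stack = fit_2pl(np.vstack(stacks))
        assert np.allclose(fit_frac.difficulty, fit_stack.difficulty, atol=0.08)
        assert np.allclose(fit_frac.discrimination, fit_stack.discrimination,
                           atol=0.08)

    def test_degenerate_item_bounded_not_fatal(self):
        x = np.column_stack([np.ones(60), np.random.default_rng(3).integers(0, 2, 60)])
        fit = fit_2pl(x.astype(float))
        assert 0 in fit.boundary_items
        assert np.isfinite(fit.loglik)

    def test_weights_scale_invariance(self, toy_binary):
        f1 = fit_2pl(toy_binary, weights=np.ones(50))
        f2 = fit_2pl(toy_binary, weights=np.full(50, 7.0))
        assert np.allclose(f1.difficulty, f2.difficulty, atol=1e-6)


class TestPersonPosterior:
    def test_all_missing_returns_prior(self, toy_binary):
        fit = fit_2pl(toy_binary)
        post = person_posterior(fit, [np.nan, np.nan])
        assert np.allclose(post, fit.grid.prior_weights)

    def test_normalization(self, toy_binary):
        fit = fit_2pl(toy_binary)
        post = person_posterior(fit, [1.0, 0.0])
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_correct_answer_raises_posterior_mean(self, toy_binary):
        fit = fit_2pl(toy_binary)
        post = person_posterior(fit, [1.0, np.nan])
        assert post @ fit.grid.points > 0


class TestLatentRegression:
    def test_constant_covariate_falls_back(self, toy_binary):
        lr = fit_2pl_latent_regression(toy_binary, np.ones(50))
        plain = fit_2pl(toy_binary)
        assert np.allclose(lr.difficulty, plain.difficulty)

    def test_recovers_regression_slope(self):
        rng = np.random.default_rng(21)
        n = 4000
        z = rng.random(n)
        theta = 0.5 * z + np.sqrt(1 - 0.25 * np.var(z)) * rng.standard_normal(n)
        theta = (theta - theta.mean())  # population centered
        b = np.linspace(-1.5, 1.5, 8)
        p = 1 / (1 + np.exp(-(theta[:, None] - b)))
        x = (rng.random((n, 8)) < p).astype(float)
        fit = fit_2pl_latent_regression(x, z)
        # slope on the standardized metric: gamma1 * sd(theta_marginal) ~ 0.5
        sd_marg = np.std(theta)
        assert fit.gamma1 * sd_marg == pytest.approx(0.5, abs=3 * 0.06)

    def test_null_slope_when_independent(self):
        rng = np.random.default_rng(22)
        n = 3000
        z = rng.random(n)
        theta = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-theta))
        x = (rng.random((n, 6)) < p[:, None]).astype(float)
        fit = fit_2pl_latent_regression(x, z)
        assert fit.gamma1 == pytest.approx(0.0, abs=3 * 0.07)
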