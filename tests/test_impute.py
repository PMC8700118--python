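import numpy as np
import pytest
from scipy.special import expit

from irtmiss.datagen import DesignCell, generate_dataset
from irtmiss.impute import (
    draw_posterior_latents,
    fcs_impute,
    imputation_probability,
    impute_model_based,
    impute_partial_guess,
    stack_and_scale,
)
from irtmiss.irt2pl import fit_2pl
from irtmiss.jointirt import fit_joint
from tests.conftest import make_response_data

nan = np.nan


@pytest.fixture(scope="module")
def fitted_joint():
    cell = DesignCell(n_persons=800, delta=-1.0, missing_rate=0.15)
    data, truth = generate_dataset(cell, 40)
    fit = fit_joint(data, formats=truth.bank.format, spec="MM1", max_iter=120)
    return data, truth, fit


class TestImputationProbability:
    def test_scalar_value_matches_bayes_arithmetic(self, fitted_joint):
        _, _, fit = fitted_joint
        fit2 = fit  # evaluate at hand-set parameters through a copy
        fit2.discrimination[0], fit2.difficulty[0] = 1.0, 0.0
        fit2.beta[0], fit2.delta[0] = 0.0, -2.0
        p = imputation_probability(fit2, 0.0, 0.0, 0)
        # numerator (1-psi(2)) * psi(0); denominator adds (1-psi(0))*(1-psi(0))
        num = (1 - expit(2.0)) * 0.5
        den = num + 0.5 * 0.5
        assert p == pytest.approx(num / den, abs=1e-12)
        assert p == pytest.approx(0.1925, abs=2e-4)

    def test_delta_zero_reduces_to_2pl(self, fitted_joint):
        _, _, fit = fitted_joint
        fit.discrimination[1], fit.difficulty[1] = 1.3, 0.4
        fit.delta[1] = 0.0
        theta = 0.8
        p = imputation_probability(fit, theta, -0.3, 1)
        assert p == pytest.approx(expit(1.3 * (theta - 0.4)), abs=1e-12)

    def test_extreme_delta_forbids_correct(self, fitted_joint):
        _, _, fit = fitted_joint
        fit.beta[2], fit.delta[2] = 0.0, -10.0
        assert imputation_probability(fit, 0.0, 0.0, 2) < 1e-3


class TestPosteriorDraws:
    def test_frequencies_match_posterior(self, fitted_joint):
        data, _, fit = fitted_joint
        rng = np.random.default_rng(1)
        counts = np.zeros(fit.posterior.shape[1])
        n_draws = 4000
        for _ in range(n_draws):
            lat = draw_posterior_latents(fit, data, rng)
            counts[lat.node_index[0]] += 1
        # total-variation distance between empirical and true posterior
        tv = 0.5 * np.abs(counts / n_draws - fit.posterior[0]).sum()
        assert tv < 0.05

    def test_fixed_seed_reproducible(self, fitted_joint):
        data, _, fit = fitted_joint
        l1 = draw_posterior_latents(fit, data, rng=123)
        l2 = draw_posterior_latents(fit, data, rng=123)
        assert np.array_equal(l1.node_index, l2.node_index)


class TestModelBasedImputation:
    def test_no_missing_identity(self, fitted_joint):
        _, truth, fit = fitted_joint
        complete = make_response_data(np.ones((5, 20)))
        imps = impute_model_based(fit, complete, m=3, rng=2)
        for d in imps.datasets:
            assert np.array_equal(d, complete.observed)

    def test_observed_cells_never_altered(self, fitted_joint):
        data, _, fit = fitted_joint
        imps = impute_model_based(fit, data, m=3, rng=3)
        obs = data.indicators == 1
        for d in imps.datasets:
            assert np.array_equal(d[obs], data.observed[obs])
            assert not np.isnan(d).any()

    def test_wrong_model_imputes_only_zeros(self):
        cell = DesignCell(n_persons=600, delta=-10.0, missing_rate=0.20)
        data, truth = generate_dataset(cell, 41)
        fit = fit_joint(data, spec="MW", max_iter=120)
        imps = impute_model_based(fit, data, m=3, rng=4)
        miss = data.indicators == 0
        for d in imps.datasets:
            assert np.all(d[miss] == 0.0)

    def test_cell_frequencies_match_bayes_probability(self, fitted_joint):
        data, _, fit = fitted_joint
        person, item = np.argwhere(data.indicators == 0)[0]
        rng = np.random.default_rng(5)
        m = 400
        vals = np.array(
            [impute_model_based(fit, data, m=1, rng=rng).datasets[0][person, item]
             for _ in range(m)]
        )
        # oracle: average the Bayes probability over fresh posterior draws
        probs = []
        for _ in range(m):
            lat = draw_posterior_latents(fit, data, rng)
            probs.append(
                imputation_probability(fit, lat.theta[person], lat.xi[person], item)
            )
        expected = float(np.mean(probs))
        assert vals.mean() == pytest.approx(expected, abs=4 * np.sqrt(0.25 / m) + 0.02)


class TestPartialGuess:
    def test_guessing_frequency(self, mixed_bank):
        data = make_response_data(np.array([[1.0, 0.0, nan, 0.0]] * 2000))
        imps = impute_partial_guess(data, mixed_bank, m=5, rng=6)
        vals = np.concatenate([d[:, 2] for d in imps.datasets])
        assert vals.mean() == pytest.approx(0.25, abs=0.013)

    def test_cr_missing_always_zero(self, mixed_bank):
        data = make_response_data(np.array([[nan, 1.0, 1.0, 1.0]] * 50))
        imps = impute_partial_guess(data, mixed_bank, m=4, rng=7)
        for d in imps.datasets:
            assert np.all(d[:, 0] == 0.0)

    def test_no_missing_identity(self, mixed_bank):
        data = make_response_data([[1.0, 0.0, 1.0, 0.0]])
        imps = impute_partial_guess(data, mixed_bank, m=3, rng=8)
        for d in imps.datasets:
            assert np.array_equal(d, data.observed)


class TestFCS:
    def test_imputed_values_are_observed_values(self):
        cell = DesignCell(n_persons=300, n_items=8, delta=-1.0, missing_rate=0.15)
        data, _ = generate_dataset(cell, 42)
        for flag in (False, True):
            imps = fcs_impute(data, include_indicators=flag, m=2, n_cycles=3, rng=9)
            for d in imps.datasets:
                assert set(np.unique(d)) <= {0.0, 1.0}
                obs = data.indicators == 1
                assert np.array_equal(d[obs], data.observed[obs])

    def test_duplicate_column_is_copied(self):
        # noiseless toy: the incomplete column duplicates an observed one,
        # so PMM donors carry the right value almost always
        rng = np.random.default_rng(10)
        base = (rng.random((400, 1)) < 0.5).astype(float)
        other = (rng.random((400, 6)) < 0.5).astype(float)
        x = np.hstack([base, base.copy(), other])
        miss = rng.random(400) < 0.3
        x_obs = x.copy()
        x_obs[miss, 1] = nan
        data = make_response_data(x_obs)
        imps = fcs_impute(data, m=1, n_cycles=4, rng=11)
        agreement = (imps.datasets[0][miss, 1] == base[miss, 0]).mean()
        assert agreement >= 0.95

    def test_no_missing_is_identity(self):
        data = make_response_data((np.random.default_rng(1).random((50, 5)) < 0.5)
                                  .astype(float))
        for flag in (False, True):
            imps = fcs_impute(data, include_indicators=flag, m=2, rng=12)
            for d in imps.datasets:
                assert np.array_equal(d, data.observed)

    def test_fully_missing_column_rejected(self):
        x = np.array([[1.0, nan], [0.0, nan]])
        with pytest.raises(ValueError):
            fcs_impute(make_response_data(x), m=1, rng=13)


class TestStackAndScale:
    def test_m1_no_missing_equals_direct_fit(self):
        rng = np.random.default_rng(14)
        x = (rng.random((300, 5)) < 0.5).astype(float)
        data = make_response_data(x)
        imps = fcs_impute(data, m=1, rng=15)
        stacked = stack_and_scale(imps)
        direct = fit_2pl(x)
        assert np.allclose(stacked.difficulty, direct.difficulty, atol=1e-10)
        assert stacked.loglik == pytest.approx(direct.loglik, abs=1e-8)

    def test_stacked_person_count(self, fitted_joint):
        data, _, fit = fitted_joint
        imps = impute_model_based(fit, data, m=5, rng=16)
        assert imps.stacked().shape[0] == 5 * data.n_persons

    def test_weight_scale_invariance(self, fitted_joint):
        data, _, fit = fitted_joint
        imps = impute_model_based(fit, data, m=2, rng=17)
        w = np.ones(data.n_persons)
        f1 = stack_and_scale(imps, weights=w)
        f2 = stack_and_scale(imps, weights=5 * w)
        assert np.allclose(f1.difficulty, f2.difficulty, atol=1e-8)
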