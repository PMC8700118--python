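import numpy as np
import pytest

from irtmiss.datagen import (
    CalibrationError,
    DesignCell,
    InvalidDesignError,
    ItemBank,
    calibrate_beta,
    draw_latents,
    expected_missing_rate,
    generate_dataset,
    make_item_bank,
    read_item_bank_csv,
    read_response_csv,
    simulate_complete,
    simulate_indicators,
    write_item_bank_csv,
    write_response_csv,
)
from scipy.special import expit


class TestItemBank:
    def test_equidistant_difficulties(self):
        bank = make_item_bank(20)
        assert np.allclose(bank.difficulty[:3], [-2.000, -1.78947368, -1.57894737])
        assert np.allclose(bank.difficulty[-1], 2.0)

    @pytest.mark.parametrize(
        "n,expected",
        [(2, [-2, 2]), (5, [-2, -1, 0, 1, 2])],
    )
    def test_endpoints_and_spacing(self, n, expected):
        assert np.allclose(make_item_bank(n).difficulty, expected)

    def test_too_few_items_rejected(self):
        with pytest.raises(InvalidDesignError):
            make_item_bank(1)

    def test_mc_items_need_options(self):
        with pytest.raises(InvalidDesignError):
            make_item_bank(3, format="MC")
        bank = make_item_bank(3, format="MC", n_options=4)
        assert np.all(bank.n_options == 4)


class TestLatents:
    def test_zero_correlation(self):
        lat = draw_latents(100_000, 0.0, rng=1)
        assert abs(np.corrcoef(lat.theta, lat.xi)[0, 1]) < 3 / np.sqrt(100_000)

    def test_target_correlation_large_sample(self):
        n = 400_000
        lat = draw_latents(n, 0.5, rng=2)
        assert np.corrcoef(lat.theta, lat.xi)[0, 1] == pytest.approx(0.5, abs=0.005)
        assert np.std(lat.theta) == pytest.approx(1.0, abs=3 / np.sqrt(2 * n))
        assert np.std(lat.xi) == pytest.approx(1.0, abs=3 / np.sqrt(2 * n))

    def test_invalid_correlation(self):
        with pytest.raises(InvalidDesignError):
            draw_latents(10, 1.0)


class TestCompleteResponses:
    def test_rate_half_at_matched_difficulty(self):
        bank = make_item_bank(2, difficulty_range=(0.5, 0.5 + 1e-9))
        lat = draw_latents(50_000, 0.0, rng=3)
        lat.theta[:] = 0.5  # theta pinned at the items' difficulty
        x = simulate_complete(lat, bank, rng=4)
        assert x.mean() == pytest.approx(0.5, abs=0.01)

    def test_logistic_rate_at_offset(self):
        # a=1, theta-b=2: success probability is the logistic value at 2
        bank = make_item_bank(2, difficulty_range=(0.0, 1e-9))
        lat = draw_latents(50_000, 0.0, rng=5)
        lat.theta[:] = 2.0
        x = simulate_complete(lat, bank, rng=6)
        assert x.mean() == pytest.approx(expit(2.0), abs=0.01)

    def test_marginal_symmetry(self):
        bank = make_item_bank(4, difficulty_range=(0.0, 1e-9))
        lat = draw_latents(50_000, 0.0, rng=7)
        x = simulate_complete(lat, bank, rng=8)
        assert x.mean() == pytest.approx(0.5, abs=0.01)


class TestIndicators:
    def test_delta_zero_removes_x_dependence(self):
        bank = make_item_bank(10)
        bank.beta[:] = -1.0
        lat = draw_latents(40_000, 0.0, rng=9)
        x = simulate_complete(lat, bank, rng=10)
        r = simulate_indicators(x, lat, bank, rng=11)
        # stratify on xi to remove the person effect
        stratum = np.abs(lat.xi) < 0.2
        miss1 = (r[stratum] == 0)[x[stratum] == 1].mean()
        miss0 = (r[stratum] == 0)[x[stratum] == 0].mean()
        assert miss1 == pytest.approx(miss0, abs=0.02)

    def test_extreme_delta_spares_correct_responses(self):
        bank = make_item_bank(10)
        bank.delta[:] = -10.0
        lat = draw_latents(20_000, 0.5, rng=12)
        x = simulate_complete(lat, bank, rng=13)
        r = simulate_indicators(x, lat, bank, rng=14)
        assert (r[x == 1] == 0).mean() < 1e-3

    def test_missing_implies_incorrect_at_extreme_delta(self):
        cell = DesignCell(n_persons=20_000, delta=-10.0, missing_rate=0.30)
        data, truth, x = generate_dataset(cell, 15, return_complete=True)
        frac_wrong = (x[data.indicators == 0] == 0).mean()
        assert frac_wrong >= 0.999


class TestCalibration:
    def test_rate_matches_quadrature_and_simulation(self):
        bank = make_item_bank(20)
        beta = calibrate_beta(0.0, 0.10, 0.5, bank)
        assert expected_missing_rate(beta, 0.0, 0.5, bank) == pytest.approx(
            0.10, abs=1e-4
        )
        cell = DesignCell(n_persons=50_000, delta=0.0, missing_rate=0.10)
        data, _ = generate_dataset(cell, 16)
        assert data.missing_rate() == pytest.approx(0.10, abs=0.003)

    def test_rate_increasing_in_beta(self):
        bank = make_item_bank(20)
        grid = np.linspace(-6, 4, 15)
        rates = [expected_missing_rate(b, -2.0, 0.5, bank) for b in grid]
        assert np.all(np.diff(rates) > 0)

    def test_tiny_rate_needs_very_negative_beta(self):
        bank = make_item_bank(20)
        assert calibrate_beta(0.0, 0.001, 0.5, bank) < -5

    def test_delta_zero_rate_item_independent(self):
        # with delta=0 the expected rate does not involve the item bank
        b1 = make_item_bank(20)
        b2 = make_item_bank(5, difficulty_range=(-0.5, 0.5))
        r1 = expected_missing_rate(-2.0, 0.0, 0.5, b1)
        r2 = expected_missing_rate(-2.0, 0.0, 0.5, b2)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_impossible_target_raises(self):
        bank = make_item_bank(20)
        with pytest.raises(CalibrationError):
            calibrate_beta(0.0, 0.0, 0.5, bank)


class TestGenerateDataset:
    def test_shapes_and_rate(self):
        cell = DesignCell()
        data, truth = generate_dataset(cell, 17)
        assert data.observed.shape == (1500, 20)
        se = np.sqrt(0.10 * 0.90 / (1500 * 20))
        assert data.missing_rate() == pytest.approx(0.10, abs=5 * se)

    def test_determinism(self):
        cell = DesignCell(delta=-2.0, missing_rate=0.20)
        d1, t1 = generate_dataset(cell, 18)
        d2, t2 = generate_dataset(cell, 18)
        assert np.array_equal(d1.observed, d2.observed, equal_nan=True)
        assert np.array_equal(d1.indicators, d2.indicators)
        assert t1.bank.beta[0] == t2.bank.beta[0]

    def test_csv_round_trip(self, tmp_path):
        cell = DesignCell(n_persons=50, n_items=5)
        data, truth = generate_dataset(cell, 19)
        write_response_csv(data, truth.bank, tmp_path / "x.csv")
        write_item_bank_csv(truth.bank, tmp_path / "items.csv")
        back = read_response_csv(tmp_path / "x.csv")
        assert np.array_equal(back.observed, data.observed, equal_nan=True)
        bank = read_item_bank_csv(tmp_path / "items.csv")
        assert np.allclose(bank.difficulty, truth.bank.difficulty)
        assert list(bank.format) == list(truth.bank.format)
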