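import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posdev.indicators import performance_matrix
from posdev.io_config import PipelineConfig
from posdev.relative_performance import (
    check_loss,
    fit_median_regression,
    market_access_proxy,
    quantreg_aic,
    relative_performance,
    select_model,
)

from conftest import make_table


def brute_force_min_check_loss(y: np.ndarray, X: np.ndarray) -> float:
    """Independent oracle: the optimal median fit interpolates p+1 points,
    so enumerate all interpolating hyperplanes and take the minimum loss."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    m = design.shape[1]
    best = np.inf
    for idx in itertools.combinations(range(n), m):
        sub = design[list(idx)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, y[list(idx)])
        best = min(best, check_loss(y - design @ beta))
    return best


class TestMarketAccess:
    def test_village_mean_shared_by_members(self):
        df = pd.DataFrame(
            {"village_id": ["a", "a", "b"], "market_orientation": [0.2, 0.4, 0.7]}
        )
        ma = market_access_proxy(df)
        np.testing.assert_allclose(ma, [0.3, 0.3, 0.7])

    def test_mean_is_idempotent_on_constant_village(self):
        df = pd.DataFrame({"village_id": ["a"] * 3, "market_orientation": [0.5] * 3})
        np.testing.assert_allclose(market_access_proxy(df), 0.5)


class TestMedianFit:
    def test_perfect_linear_fit_has_zero_residuals(self):
        x = np.arange(10, dtype=float)
        fit = fit_median_regression(2 * x, pd.DataFrame({"x": x}))
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-6)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-6)

    def test_intercept_only_attains_median_loss(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        fit = fit_median_regression(y, pd.DataFrame(index=range(len(y))))
        assert fit.check_loss_sum == pytest.approx(check_loss(y - np.median(y)), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_attains_brute_force_check_loss_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 13))
        p = int(rng.integers(0, 3))
        X = rng.normal(size=(n, p))
        y = X.sum(axis=1) + rng.normal(size=n)
        fit = fit_median_regression(y, pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]))
        assert fit.check_loss_sum <= brute_force_min_check_loss(y, X) + 1e-6

    def test_median_residual_sign_property(self, survey_500):
        records, _ = survey_500
        config = PipelineConfig()
        perf, _, _ = performance_matrix(records, config)
        residuals, _ = relative_performance(perf, records, config)
        n = len(records)
        for col in residuals.columns:
            pos = (residuals[col] > 0).mean()
            assert 0.5 - 2 / np.sqrt(n) <= pos <= 0.5 + 2 / np.sqrt(n)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(8, dtype=float)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            fit_median_regression(x, X)


class TestAic:
    def test_parameter_penalty_is_two_per_coefficient(self):
        fit = fit_median_regression(
            np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0, 8.0]),
            pd.DataFrame(index=range(8)),
        )
        base = fit.aic
        bumped = quantreg_aic(
            type(fit)(**{**fit.__dict__, "k": fit.k + 1})
        )
        assert bumped - base == pytest.approx(2.0)

    def test_halving_loss_beats_penalty_at_n100(self):
        # 2 extra parameters vs 2n ln 2 loss reduction
        assert 2 - 2 * 100 * np.log(2) < 0

    def test_perfect_fit_gets_sentinel(self):
        x = np.arange(10, dtype=float)
        with pytest.warns(UserWarning, match="perfect"):
            fit = fit_median_regression(2 * x, pd.DataFrame({"x": x}))
        assert fit.aic == float("-inf")


class TestModelSelection:
    def _records(self, n, seed):
        df = make_table(n=n, seed=seed)
        return df

    def test_planted_covariate_selected(self):
        rng = np.random.default_rng(3)
        records = make_table(n=120, seed=3)
        y = 5.0 * records["land_ha"].to_numpy() + rng.normal(0, 0.5, 120)
        fit = select_model(y, records, candidates=["land_ha", "livestock_tlu", "mae"])
        assert "land_ha" in fit.covariates

    def test_empty_candidates_give_intercept_only(self, small_table):
        y = small_table["farm_income"].to_numpy()
        fit = select_model(y, small_table, candidates=[])
        assert fit.covariates == () and fit.k == 1

    def test_noise_covariate_selected_in_minority(self):
        rng = np.random.default_rng(12)
        picked = 0
        reps = 30
        records = make_table(n=200, seed=1)
        for _ in range(reps):
            y = rng.normal(size=200)
            fit = select_model(y, records, candidates=["livestock_tlu"])
            picked += "livestock_tlu" in fit.covariates
        assert picked < reps / 2

    def test_selected_aic_not_worse_than_intercept_only(self, survey_500):
        records, _ = survey_500
        sub = records.iloc[:150].reset_index(drop=True)
        y = sub["farm_income"].to_numpy()
        best, table = select_model(y, sub, return_table=True)
        intercept_aic = [t["aic"] for t in table if t["covariates"] == []][0]
        assert best.aic <= intercept_aic


class TestResidualMatrix:
    def test_outcome_equal_to_covariate_gives_zero_residuals(self, small_table):
        config = PipelineConfig(candidate_covariates=["land_ha"], cap_percentile=100)
        perf = pd.DataFrame(
            {c: small_table["land_ha"].to_numpy() for c in ["a", "b"]},
            index=small_table["household_id"],
        )
        residuals, models = relative_performance(perf, small_table, config)
        np.testing.assert_allclose(residuals.to_numpy(), 0, atol=1e-6)

    def test_shift_equivariance(self, small_table):
        config = PipelineConfig(candidate_covariates=["land_ha", "mae"])
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            {"y": rng.normal(size=len(small_table))}, index=small_table["household_id"]
        )
        r1, _ = relative_performance(base, small_table, config)
        r2, _ = relative_performance(base + 100.0, small_table, config)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-5)

    def test_permutation_equivariance(self):
        records = make_table(n=40, seed=9)
        config = PipelineConfig(candidate_covariates=["land_ha", "mae"])
        rng = np.random.default_rng(1)
        y = pd.DataFrame(
            {"y": records["land_ha"].to_numpy() * 2 + rng.normal(size=40)},
            index=records["household_id"],
        )
        r1, _ = relative_performance(y, records, config)
        perm = rng.permutation(40)
        records_p = records.iloc[perm].reset_index(drop=True)
        y_p = y.iloc[perm]
        r2, _ = relative_performance(y_p, records_p, config)
        np.testing.assert_allclose(
            r1.to_numpy()[perm], r2.to_numpy(), atol=1e-5
        )

    def test_planted_residual_shifts_recovered(self, survey_500):
        """Households given a positive outcome shift independent of their
        endowments must surface with systematically higher residuals."""
        records, truth = survey_500
        config = PipelineConfig(candidate_covariates=["land_ha", "mae", "market_access"])
        rng = np.random.default_rng(21)
        shift = rng.normal(0, 2.0, len(records))
        y = pd.DataFrame(
            {"y": 300 * records["land_ha"].to_numpy() + 50 * shift + rng.normal(0, 30, len(records))},
            index=records["household_id"],
        )
        residuals, _ = relative_performance(y, records, config)
        rho = stats.spearmanr(shift, residuals["y"].to_numpy()).statistic
        assert rho > 0.8
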