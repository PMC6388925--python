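import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posdev.deviance_profile import (
    assign_strata,
    compare_groups,
    deviance_correlations,
    stratum_mean_deviance,
    z_transform,
)


class TestZTransform:
    def test_hand_computed_example(self):
        scaled, constants = z_transform(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(scaled["a"], [-1, 0, 1])
        assert constants.loc["a", "sd"] == pytest.approx(1.0)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=50)})
        once, _ = z_transform(x)
        twice, _ = z_transform(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.lognormal(size=(200, 5)), columns=list("abcde"))
        scaled, _ = z_transform(x)
        np.testing.assert_allclose(scaled.mean(), 0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(ddof=1), 1, atol=1e-9)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            z_transform(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestStrata:
    def test_twenty_strata_of_size_one(self):
        # distinct land values; livestock 0/1 alternating within each decile
        land = np.arange(20, dtype=float)
        livestock = np.tile([0.0, 1.0], 10)
        a = assign_strata(land, livestock)
        assert set(zip(a.land_decile, a.livestock_class)) == {
            (d, c) for d in range(1, 11) for c in ("low", "high")
        }
        counts = pd.Series(a.stratum_id).value_counts()
        assert (counts == 1).all() and len(counts) == 20

    def test_decile_sizes_balanced_for_distinct_land(self):
        rng = np.random.default_rng(2)
        land = rng.permutation(np.linspace(0.1, 10, 103))
        a = assign_strata(land, np.zeros(103))
        sizes = pd.Series(a.land_decile).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_all_zero_livestock_goes_low(self):
        a = assign_strata(np.arange(12, dtype=float), np.zeros(12))
        assert set(a.livestock_class) == {"low"}
        assert a.livestock_median == 0.0

    def test_tied_land_shares_lower_decile(self):
        with pytest.warns(UserWarning, match="tied"):
            a = assign_strata(np.ones(10), np.zeros(10))
        assert set(a.land_decile) == {1}

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        land = rng.lognormal(size=60)
        a = assign_strata(land, np.zeros(60))
        b = assign_strata(np.log(land), np.zeros(60))
        np.testing.assert_array_equal(a.land_decile, b.land_decile)


class TestMeanDeviance:
    def _setup(self):
        rng = np.random.default_rng(5)
        residuals = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        assignment = assign_strata(rng.permutation(np.arange(40.0)), np.repeat([0.0, 2.0], 20))
        mask = np.zeros(40, dtype=bool)
        mask[[0, 7, 15, 23, 31]] = True
        return residuals, assignment, mask

    def test_single_deviant_stratum_row_equals_its_residuals(self):
        residuals, assignment, _ = self._setup()
        mask = np.zeros(40, dtype=bool)
        mask[4] = True
        profile = stratum_mean_deviance(residuals, assignment, mask)
        d, c = assignment.land_decile[4], assignment.livestock_class[4]
        row = profile[(profile["group"] == "stratum") & (profile["stratum"] == f"D{d}-{c}")]
        assert row["n"].iloc[0] == 1
        assert row["a"].iloc[0] == pytest.approx(residuals.loc[4, "a"])

    def test_overall_row_is_mean_over_all_deviants(self):
        residuals, assignment, mask = self._setup()
        profile = stratum_mean_deviance(residuals, assignment, mask)
        overall = profile[profile["group"] == "overall"].iloc[0]
        assert overall["a"] == pytest.approx(residuals.loc[mask, "a"].mean())
        assert overall["n"] == mask.sum()

    def test_empty_stratum_rows_emitted_with_zero_count(self):
        residuals, assignment, mask = self._setup()
        profile = stratum_mean_deviance(residuals, assignment, mask)
        strata_rows = profile[profile["group"] == "stratum"]
        assert len(strata_rows) == 20
        empties = strata_rows[strata_rows["n"] == 0]
        assert len(empties) > 0 and empties["a"].isna().all()

    def test_z_columns_use_full_sample_standardization(self):
        residuals, assignment, mask = self._setup()
        profile = stratum_mean_deviance(residuals, assignment, mask)
        overall = profile[profile["group"] == "overall"].iloc[0]
        scaled, _ = z_transform(residuals)
        assert overall["a_z"] == pytest.approx(scaled.loc[mask, "a"].mean())


class TestCorrelations:
    def test_hand_oracle_on_five_points(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 1, 4, 3, 6]})
        r, p = deviance_correlations(x, np.ones(5, dtype=bool))

        def pearson_by_hand(u, v):
            u, v = np.asarray(u) - np.mean(u), np.asarray(v) - np.mean(v)
            return float(np.sum(u * v) / np.sqrt(np.sum(u**2) * np.sum(v**2)))

        assert r.loc["a", "b"] == pytest.approx(pearson_by_hand(x["a"], x["b"]))
        assert r.loc["a", "a"] == 1.0

    def test_exact_negative_relation(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [8.0, 6, 4, 2]})
        r, _ = deviance_correlations(x, np.ones(4, dtype=bool))
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        r, p = deviance_correlations(x, np.ones(30, dtype=bool))
        pd.testing.assert_frame_equal(r, r.T)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert ((r.to_numpy() >= -1) & (r.to_numpy() <= 1)).all()
        pd.testing.assert_frame_equal(p, p.T)


class TestGroupComparison:
    def _records(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "mae": rng.normal(4, 1, n),
                "land_ha": rng.lognormal(1, 0.5, n),
                "livestock_tlu": rng.random(n),
                "crop_diversity": rng.integers(1, 8, n),
                "livestock_diversity": rng.integers(0, 3, n),
                "region": rng.choice(["r1", "r2"], n),
                "household_type": rng.choice(["couple", "single_woman"], n),
            }
        )

    def test_identical_groups_not_flagged(self):
        records = pd.concat([self._records(30)] * 2, ignore_index=True)
        perf = pd.DataFrame({"p": np.tile(np.arange(30.0), 2)})
        mask = np.array([True] * 30 + [False] * 30)
        table = compare_groups(records, perf, mask)
        numeric = table[table["kind"] == "numeric_mean"]
        np.testing.assert_allclose(numeric["p_value"], 1.0, atol=1e-9)
        assert not table["significant"].any()

    def test_planted_mean_shift_flagged(self):
        records = self._records(80, seed=1)
        mask = np.zeros(80, dtype=bool)
        mask[:20] = True
        records.loc[mask, "land_ha"] += 15.0
        perf = pd.DataFrame({"p": np.zeros(80) + np.arange(80)})
        table = compare_groups(records, perf, mask)
        row = table[table["characteristic"] == "land_ha"].iloc[0]
        assert row["p_value"] < 0.05 and row["significant"]

    def test_diagonal_contingency_is_significant(self):
        # 2x2 table {10,0;0,10} has chi-square p < .05
        p = stats.chi2_contingency([[10, 0], [0, 10]]).pvalue
        assert p < 0.05
        records = self._records(40, seed=2)
        records["region"] = ["r1"] * 20 + ["r2"] * 20
        mask = np.array([True] * 20 + [False] * 20)
        perf = pd.DataFrame({"p": np.arange(40.0)})
        table = compare_groups(records, perf, mask)
        region_rows = table[table["characteristic"].str.startswith("region=")]
        assert (region_rows["p_value"] < 0.05).all()

    def test_performance_medians_reported_per_group(self):
        records = self._records(40, seed=3)
        mask = np.array([True] * 10 + [False] * 30)
        perf = pd.DataFrame({"p": np.arange(40.0)})
        table = compare_groups(records, perf, mask)
        med = table[table["kind"] == "performance_median"].iloc[0]
        assert med["deviants"] == pytest.approx(np.median(np.arange(10.0)))
        assert med["others"] == pytest.approx(np.median(np.arange(10.0, 40.0)))
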