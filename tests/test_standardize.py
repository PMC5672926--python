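import numpy as np
import pandas as pd
import pytest

from lifelost import LifeTable, Profile
from lifelost.expectancy import LifeExpectancyResult
from lifelost.standardize import (
    WeightScheme,
    internal_weights,
    pooled_weights,
    read_weights_csv,
    standardized_average,
    summary_table,
    total_years_lost,
)

from conftest import make_registry


def result_at(age, lel, pll=None, e_star=20.0):
    if pll is None:
        pll = lel / e_star
    return LifeExpectancyResult(
        profile=Profile(float(age), "F", 1, 2013.0),
        e_star=e_star, e_obs=e_star - lel, lel=lel, pll=pll,
        tau=100.0, quad_order=15, n_segments=1)


class TestWeightScheme:
    def test_counts_normalise(self):
        scheme = WeightScheme("internal", {60: 100, 70: 300})
        assert scheme.weights == {60: 0.25, 70: 0.75}
        assert sum(scheme.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_stratum(self):
        assert WeightScheme("internal", {65: 7}).weights == {65: 1.0}

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightScheme("internal", {60: -1.0})

    def test_internal_weights_from_cohort(self):
        reg = make_registry([
            ("a", "lung", 2, 60.2, 2013.1, 2014.0, 0),
            ("b", "lung", 2, 60.9, 2013.5, 2014.0, 0),
            ("c", "lung", 2, 70.4, 2013.9, 2014.0, 0),
            ("d", "lung", 2, 70.0, 2012.9, 2014.0, 0),  # 2012 diagnosis: ignored
            ("e", "lung", 3, 80.0, 2013.2, 2014.0, 0),  # other group: ignored
        ])
        scheme = internal_weights(reg, dep=2)
        assert scheme.weights == {60: 2 / 3, 70: 1 / 3}

    def test_internal_weights_invariant_to_record_order(self):
        rows = [("a", "lung", 1, 60.2, 2013.1, 2014.0, 0),
                ("b", "lung", 1, 71.9, 2013.5, 2014.0, 0),
                ("c", "lung", 1, 60.7, 2013.9, 2014.0, 0)]
        w1 = internal_weights(make_registry(rows), 1)
        w2 = internal_weights(make_registry(rows[::-1]), 1)
        assert w1.weights == w2.weights

    def test_empty_group_rejected(self):
        reg = make_registry([("a", "lung", 1, 60.0, 2010.0, 2014.0, 0)])
        with pytest.raises(ValueError, match="no 2013"):
            internal_weights(reg, 1)

    def test_custom_band_csv(self, tmp_path):
        path = tmp_path / "icss.csv"
        pd.DataFrame({"lo": [15, 45, 55, 65, 75], "hi": [45, 55, 65, 75, 120],
                      "weight": [0.07, 0.12, 0.23, 0.29, 0.29]}).to_csv(path, index=False)
        scheme = read_weights_csv(path)
        assert scheme.kind == "external_custom"
        assert scheme.evaluation_age((65.0, 75.0)) == 70.0
        assert sum(scheme.weights.values()) == pytest.approx(1.0, abs=1e-12)


class TestStandardizedAverage:
    def test_constant_lel_any_weights(self):
        scheme = WeightScheme("internal", {60: 1, 70: 3})
        results = {60: result_at(60, 5.0), 70: result_at(70, 5.0)}
        mean_lel, _ = standardized_average(results, scheme)
        assert mean_lel == pytest.approx(5.0)

    def test_weighted_mean_arithmetic(self):
        scheme = WeightScheme("x", {60: 0.25, 70: 0.75})
        results = {60: result_at(60, 10.0), 70: result_at(70, 20.0)}
        mean_lel, _ = standardized_average(results, scheme)
        assert mean_lel == pytest.approx(17.5)

    def test_mismatched_strata_lists_difference(self):
        scheme = WeightScheme("x", {60: 0.5, 70: 0.5})
        results = {60: result_at(60, 10.0), 75: result_at(75, 8.0)}
        with pytest.raises(ValueError, match="70"):
            standardized_average(results, scheme)

    def test_pll_mode_ratio_of_means(self):
        scheme = WeightScheme("x", {60: 0.5, 70: 0.5})
        results = {60: result_at(60, 10.0, e_star=40.0),
                   70: result_at(70, 10.0, e_star=10.0)}
        _, mor = standardized_average(results, scheme, pll_mode="mean_of_ratios")
        _, rom = standardized_average(results, scheme, pll_mode="ratio_of_means")
        assert mor == pytest.approx(0.5 * 0.25 + 0.5 * 1.0)
        assert rom == pytest.approx(10.0 / 25.0)


class TestTotals:
    def test_product(self):
        assert total_years_lost(2525, 12.84) == pytest.approx(2525 * 12.84)
        assert total_years_lost(0, 12.84) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            total_years_lost(-1, 5.0)


class FlatRelSurv:
    """Stand-in results object with a constant-excess-hazard survival curve."""

    def __init__(self, lam_by_dep):
        self.lam_by_dep = lam_by_dep

    def predict_relative_survival(self, profile, t):
        lam = self.lam_by_dep[profile.deprivation]
        return np.exp(-lam * np.asarray(t, dtype=float))


def synthetic_cohort(ages_by_dep):
    rows = []
    i = 0
    for dep, ages in ages_by_dep.items():
        for a in ages:
            rows.append((f"p{i}", "siteA", dep, a, 2013.5, 2014.0, 0))
            i += 1
    return make_registry(rows)


@pytest.fixture(scope="module")
def table():
    return LifeTable.constant(0.02)


class TestSummaryTable:

    def test_internal_equals_pooled_when_age_mixes_match(self, table):
        """Identical age distributions across groups: weighting choice is moot."""
        ages = [60.0, 60.4, 70.2, 70.8]
        cohort = synthetic_cohort({d: ages for d in range(1, 6)})
        models = {("siteA", "F"): FlatRelSurv({d: 0.1 for d in range(1, 6)})}
        internal = summary_table(models, table, cohort, weights="internal")
        pooled = summary_table(models, table, cohort, weights="pooled")
        np.testing.assert_allclose(internal["mean_lel"], pooled["mean_lel"], atol=1e-9)
        np.testing.assert_allclose(internal["mean_pll"], pooled["mean_pll"], atol=1e-9)

    def test_dep_ordering_follows_excess_hazard(self, table):
        cohort = synthetic_cohort({d: [65.0, 75.0] for d in range(1, 6)})
        lam = {1: 0.05, 2: 0.08, 3: 0.11, 4: 0.14, 5: 0.17}
        models = {("siteA", "F"): FlatRelSurv(lam)}
        out = summary_table(models, table, cohort).sort_values("deprivation")
        assert out["mean_lel"].is_monotonic_increasing
        assert out["mean_pll"].is_monotonic_increasing

    def test_zero_excess_hazard_zero_totals(self, table):
        cohort = synthetic_cohort({d: [65.0] for d in range(1, 6)})
        models = {("siteA", "F"): FlatRelSurv({d: 0.0 for d in range(1, 6)})}
        out = summary_table(models, table, cohort)
        np.testing.assert_allclose(out["total_years_lost"], 0.0, atol=1e-6)

    def test_row_count_and_decomposition_identity(self, table):
        cohort = synthetic_cohort({d: [65.0, 70.0, 75.0] for d in range(1, 6)})
        models = {("siteA", "F"): FlatRelSurv({d: 0.1 for d in range(1, 6)})}
        out = summary_table(models, table, cohort)
        assert len(out) == 5  # one cancer x one sex x five quintiles
        total = (out["n_ref_year"] * out["mean_lel"]).sum()
        assert out["total_years_lost"].sum() == pytest.approx(total, rel=1e-12)

    def test_missing_model_for_stratum(self, table):
        cohort = synthetic_cohort({1: [65.0]})
        with pytest.raises(ValueError, match="siteA"):
            summary_table({}, table, cohort)

    def test_per_patient_mode_matches_by_age_on_integer_ages(self, table):
        cohort = synthetic_cohort({d: [65.0, 70.0] for d in range(1, 6)})
        models = {("siteA", "F"): FlatRelSurv({d: 0.1 for d in range(1, 6)})}
        by_age = summary_table(models, table, cohort, average="by-age")
        per_pat = summary_table(models, table, cohort, average="per-patient")
        np.testing.assert_allclose(by_age["mean_lel"], per_pat["mean_lel"], rtol=1e-9)


class TestEqualRelativeSurvivalMechanism:
    def test_equal_relsurv_gives_deprived_lower_lel_and_lower_pll(self):
        """With identical R, a shorter expected life means fewer absolute years
        lost AND a smaller proportion lost: the weights S*(t) concentrate on
        early follow-up where R is still high."""
        frame = LifeTable.constant(0.02).to_frame()
        frame.loc[frame.dep == 5, "rate"] = 0.05
        table = LifeTable.from_frame(frame)
        cohort = synthetic_cohort({d: [65.0, 70.0] for d in range(1, 6)})
        models = {("siteA", "F"): FlatRelSurv({d: 0.1 for d in range(1, 6)})}
        out = summary_table(models, table, cohort).set_index("deprivation")
        assert out.loc[1, "mean_lel"] > out.loc[5, "mean_lel"]
        assert out.loc[1, "mean_pll"] > out.loc[5, "mean_pll"]
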