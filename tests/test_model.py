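import numpy as np
import pandas as pd
import pytest

from lifelost import FitConfig, FlexParamRelSurv, LifeTable, Profile
from lifelost.model import DesignInfo, build_design, log_likelihood
from lifelost.period import first_tumour_filter, make_period_dataset
from lifelost.simulate import exponential_scenario, make_life_table, simulate_registry
from lifelost.splines import SplineSpec

from conftest import constant_hazard_frame

CONST_KNOTS = (np.log(0.05), np.log(20.0))
EXP_CFG = FitConfig(df_baseline=1, df_age=0, td=(), dep_effects=False,
                    interaction=False, standardize=False)


def constant_hazard_model(frame, table, lam=None):
    """Model whose eta = ln(lam) + ln t encodes a constant excess hazard."""
    return FlexParamRelSurv(frame, table, EXP_CFG, baseline_knots=CONST_KNOTS)


class TestDesignLayout:
    def test_column_count_matches_documented_layout(self):
        kb, ka, ktd = 6, 4, 4  # 5 df baseline, 3 df age, 3 df TD
        info = DesignInfo(
            baseline=SplineSpec(tuple(np.linspace(-2, 2, kb))),
            age_spec=SplineSpec(tuple(np.linspace(40, 90, ka))),
            td_dep=SplineSpec(tuple(np.linspace(-2, 2, ktd))),
            td_age=SplineSpec(tuple(np.linspace(-2, 2, ktd))),
        )
        expected = (1 + (kb - 1) + 4 + (ka - 1) + 4 * (ka - 1)
                    + 4 * (ktd - 1) + (ka - 1) * (ktd - 1))
        assert info.n_columns == expected
        X, dX = build_design(info, [1.0, 2.0], [3, 5], [55.0, 70.0])
        assert X.shape == (2, expected) == dX.shape
        assert info.column_names[0] == "const"
        assert len(set(info.column_names)) == expected

    def test_reference_pattern_hits_baseline_only(self):
        info = DesignInfo(
            baseline=SplineSpec((-1.0, 0.0, 1.0)),
            age_spec=SplineSpec((40.0, 60.0, 90.0)),
            td_dep=SplineSpec((-1.0, 0.0, 1.0)),
            td_age=None,
        )
        X, _ = build_design(info, np.exp(0.5), 1, 40.0)
        names = info.column_names
        # dep 1: every dummy, interaction and TD-dep column is zero
        for j, name in enumerate(names):
            if name.startswith("dep"):
                assert X[0, j] == 0.0
        # age at the first age knot: nonlinear age columns are zero
        assert X[0, names.index("age_b2")] == 0.0

    def test_time_at_first_knot_zeroes_nonlinear_baseline(self):
        info = DesignInfo(baseline=SplineSpec((-1.0, 0.0, 1.0)), age_spec=None,
                          dep_effects=False, interaction=False)
        X, _ = build_design(info, np.exp(-1.0), 1, 50.0)
        assert X[0, info.column_names.index("lnt_b2")] == 0.0

    def test_invalid_time_rejected(self):
        info = DesignInfo(baseline=SplineSpec((-1.0, 1.0)), age_spec=None,
                          dep_effects=False, interaction=False)
        with pytest.raises(ValueError):
            build_design(info, 0.0, 1, 50.0)


class TestLogLikelihood:
    def test_censored_only_is_minus_total_cumulative_hazard(self, constant_table):
        lam = 0.1
        t = np.array([1.0, 2.5, 7.0])
        frame = constant_hazard_frame(t, d=0)
        model = constant_hazard_model(frame, constant_table)
        ll = model.loglike([np.log(lam), 1.0])
        assert ll == pytest.approx(-lam * t.sum(), rel=1e-12)

    def test_single_event_hand_formula(self, constant_table):
        mu, lam, t = 0.02, 0.1, 3.0
        frame = constant_hazard_frame([t], d=1)
        model = constant_hazard_model(frame, constant_table)
        ll = model.loglike([np.log(lam), 1.0])
        assert ll == pytest.approx(np.log(mu + lam) - lam * t, rel=1e-12)

    def test_zero_exposure_row_changes_nothing(self, constant_table):
        lam = 0.1
        base = constant_hazard_frame([2.0, 5.0], d=0)
        extra = constant_hazard_frame([4.0], d=0, t0=[4.0])
        both = pd.concat([base, extra], ignore_index=True)
        m1 = constant_hazard_model(base, constant_table)
        m2 = constant_hazard_model(both, constant_table)
        params = [np.log(lam), 1.0]
        assert m2.loglike(params) == pytest.approx(m1.loglike(params), rel=1e-12)

    def test_left_truncation_credits_entry_hazard(self, constant_table):
        lam = 0.07
        frame = constant_hazard_frame([6.0], d=0, t0=[2.0])
        model = constant_hazard_model(frame, constant_table)
        ll = model.loglike([np.log(lam), 1.0])
        assert ll == pytest.approx(-lam * (6.0 - 2.0), rel=1e-12)

    def test_non_finite_params_rejected(self, constant_table):
        frame = constant_hazard_frame([1.0], d=0)
        model = constant_hazard_model(frame, constant_table)
        with pytest.raises(ValueError):
            model.loglike([np.nan, 1.0])

    def test_functional_wrapper_agrees(self, constant_table):
        frame = constant_hazard_frame([1.0, 4.0], d=[1, 0])
        model = constant_hazard_model(frame, constant_table)
        params = [np.log(0.2), 1.0]
        assert log_likelihood(
            params, frame, constant_table, config=EXP_CFG,
            baseline_knots=CONST_KNOTS,
        ) == pytest.approx(model.loglike(params))


class TestScore:
    def test_analytic_gradient_matches_finite_differences(self):
        """Full model (TD effects + interaction) on simulated data."""
        config = exponential_scenario(7, n=1500)
        registry = simulate_registry(config)
        registry["dep"] = 1 + (np.arange(len(registry)) % 5)  # spread over quintiles
        table = make_life_table(config)
        period = make_period_dataset(first_tumour_filter(registry))
        model = FlexParamRelSurv(
            period, table,
            FitConfig(df_baseline=3, df_age=2, df_td=2, td=("dep", "age")))
        rng = np.random.default_rng(11)
        theta = model._start_values() + 0.05 * rng.standard_normal(model.info.n_columns)
        analytic = model.score(theta)
        fd = np.empty_like(analytic)
        for j in range(len(theta)):
            h = 1e-6 * (1 + abs(theta[j]))
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            fd[j] = (model.loglike(up) - model.loglike(dn)) / (2 * h)
        np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-4)


@pytest.fixture(scope="module")
def exp_fit():
    """Exponential-excess data with a 2-knot baseline: known truth lam=0.1."""
    config = exponential_scenario(20130101, n=20000)
    registry = simulate_registry(config)
    table = make_life_table(config)
    period = make_period_dataset(first_tumour_filter(registry))
    model = FlexParamRelSurv(period, table, EXP_CFG)
    return model, model.fit(), table


class TestFit:
    def test_recovers_constant_excess_hazard_within_5pct(self, exp_fit):
        _, results, _ = exp_fit
        profile = Profile(50.0, "F", 1, 2010.0)
        t = np.linspace(0.1, 10.0, 100)
        lam_hat = results.predict_excess_hazard(profile, t)
        assert np.all(np.abs(lam_hat - 0.1) < 0.005)

    def test_convergence_diagnostics_recorded(self, exp_fit):
        _, results, _ = exp_fit
        assert results.converged
        assert results.grad_norm < 1e-3
        assert results.niter > 0
        assert results.n_guard_violations == 0

    def test_duplicated_rows_leave_estimates_unchanged(self, constant_table):
        config = exponential_scenario(3, n=1200)
        registry = simulate_registry(config)
        table = make_life_table(config)
        period = make_period_dataset(first_tumour_filter(registry)).frame
        doubled = pd.concat([period, period], ignore_index=True)
        r1 = FlexParamRelSurv(period, table, EXP_CFG).fit()
        r2 = FlexParamRelSurv(doubled, table, EXP_CFG).fit()
        np.testing.assert_allclose(r1.params, r2.params, atol=1e-5)

    def test_row_order_irrelevant(self):
        config = exponential_scenario(3, n=1200)
        registry = simulate_registry(config)
        table = make_life_table(config)
        period = make_period_dataset(first_tumour_filter(registry)).frame
        shuffled = period.sample(frac=1.0, random_state=5).reset_index(drop=True)
        r1 = FlexParamRelSurv(period, table, EXP_CFG).fit()
        r2 = FlexParamRelSurv(shuffled, table, EXP_CFG).fit()
        np.testing.assert_allclose(r1.params, r2.params, atol=1e-5)

    def test_too_many_parameters_rejected(self, constant_table):
        frame = constant_hazard_frame([1.0, 2.0, 3.0], d=[1, 0, 0])
        model = constant_hazard_model(frame, constant_table)
        with pytest.raises(ValueError, match="events"):
            model.fit()

    def test_standardisation_does_not_change_predictions(self):
        config = exponential_scenario(3, n=1500)
        registry = simulate_registry(config)
        table = make_life_table(config)
        period = make_period_dataset(first_tumour_filter(registry))
        base = dict(df_baseline=2, df_age=1, td=(), dep_effects=False,
                    interaction=False)
        r_std = FlexParamRelSurv(period, table, FitConfig(**base, standardize=True)).fit()
        r_raw = FlexParamRelSurv(period, table, FitConfig(**base, standardize=False)).fit()
        profile = Profile(55.0, "F", 1, 2010.0)
        t = np.array([0.5, 2.0, 8.0, 30.0])
        np.testing.assert_allclose(
            r_std.predict_relative_survival(profile, t),
            r_raw.predict_relative_survival(profile, t), rtol=1e-4)


class TestTimeDependentModel:
    def test_full_model_fits_and_extrapolates(self):
        """TD deprivation+age effects with interaction: converges, monotone tail."""
        from dataclasses import replace as dc_replace

        from lifelost.simulate import default_scenario

        config = dc_replace(default_scenario(2),
                            counts_per_year_dep=(150.0,) * 5)
        registry = simulate_registry(config)
        table = make_life_table(config)
        period = make_period_dataset(first_tumour_filter(registry))
        model = FlexParamRelSurv(period, table, FitConfig())
        results = model.fit()
        assert results.converged
        assert results.n_guard_violations == 0
        profile = Profile(70.0, "F", 5, 2013.0)
        assert results.tail_slope(profile) > 0
        t = np.linspace(0.05, 80.0, 300)
        r = results.predict_relative_survival(profile, t)
        assert np.all(np.diff(r) <= 1e-10)
        assert np.all((r >= 0) & (r <= 1))


class TestPredictions:
    def test_constant_hazard_closed_form(self, constant_table):
        from lifelost.model import RelSurvResults

        frame = constant_hazard_frame([1.0, 2.0, 3.0, 4.0], d=[1, 1, 0, 0])
        model = constant_hazard_model(frame, constant_table)
        results = RelSurvResults(info=model.info,
                                 params=np.array([np.log(0.1), 1.0]),
                                 llf=0.0, grad_norm=0.0, niter=0, converged=True)
        profile = Profile(50.0, "F", 1, 2010.0)
        assert results.predict_relative_survival(profile, 5.0) == pytest.approx(
            np.exp(-0.5), rel=1e-10)
        assert results.predict_excess_hazard(profile, 5.0) == pytest.approx(0.1, rel=1e-10)
        assert results.tail_slope(profile) == pytest.approx(1.0)

    def test_relative_survival_approaches_one_at_zero(self, exp_fit):
        _, results, _ = exp_fit
        profile = Profile(50.0, "F", 1, 2010.0)
        assert results.predict_relative_survival(profile, 1e-8) > 0.999999
        with pytest.raises(ValueError):
            results.predict_relative_survival(profile, 0.0)

    def test_extrapolated_survival_monotone_when_tail_positive(self, exp_fit):
        _, results, _ = exp_fit
        profile = Profile(50.0, "F", 1, 2010.0)
        assert results.tail_slope(profile) > 0
        t = np.linspace(16.0, 80.0, 200)  # far beyond follow-up
        r = results.predict_relative_survival(profile, t)
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all((r >= 0) & (r <= 1))

    def test_age_extrapolation_warns_not_errors(self):
        config = exponential_scenario(3, n=1500)
        registry = simulate_registry(config)
        table = make_life_table(config)
        period = make_period_dataset(first_tumour_filter(registry))
        results = FlexParamRelSurv(
            period, table,
            FitConfig(df_baseline=2, df_age=2, td=(), dep_effects=False,
                      interaction=False)).fit()
        young = Profile(20.0, "F", 1, 2010.0)
        with pytest.warns(UserWarning, match="age"):
            results.predict_relative_survival(young, 1.0)


class TestSerialisation:
    def test_json_round_trip_preserves_predictions(self, exp_fit, tmp_path):
        from lifelost.model import RelSurvResults

        _, results, _ = exp_fit
        path = tmp_path / "model.json"
        results.to_json(path)
        loaded = RelSurvResults.from_json(path)
        profile = Profile(50.0, "F", 1, 2010.0)
        t = np.array([0.5, 3.0, 12.0, 40.0])
        np.testing.assert_allclose(
            loaded.predict_relative_survival(profile, t),
            results.predict_relative_survival(profile, t), rtol=1e-12)

    def test_summary_mentions_key_diagnostics(self, exp_fit):
        _, results, _ = exp_fit
        text = results.summary()
        assert "log-likelihood" in text
        assert "const" in text
        assert "converged" in text

    def test_standard_errors_reasonable(self, exp_fit):
        _, results, _ = exp_fit
        bse = results.bse
        assert np.all(np.isfinite(bse)) and np.all(bse > 0)
        # intercept of a ~7000-event fit is tightly determined
        assert bse[0] < 0.1
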