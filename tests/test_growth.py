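"""Growth-model fitting and trait derivation against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from growthgwas import (
    IndividualCurve,
    derive_ap,
    derive_ar,
    derive_peak_velocity,
    fit_childhood_bmi_model,
    fit_infancy_bmi_model,
    fit_reed1,
    individual_curves,
    reed1_velocity,
)
from growthgwas.growth import bmi_loglike_at
from growthgwas.synthetic import (
    CHILDHOOD_TRUE,
    CohortConfig,
    INFANCY_TRUE,
    simulate_study,
)

from conftest import reed1_measurements


def _curve(intercept=2.86, linear=0.0, quadratic=-0.4, cubic=0.0,
           center=0.75, sex=0, sid="x"):
    return IndividualCurve(subject_id=sid, sex=sex, intercept=intercept,
                           linear=linear, quadratic=quadratic, cubic=cubic,
                           center_age=center)


def _grid_extremum(curve, window, mode, step=1e-5):
    ages = np.arange(window[0], window[1] + step / 2, step)
    vals = curve.log_bmi(ages)
    i = int(np.argmax(vals)) if mode == "max" else int(np.argmin(vals))
    return float(ages[i])


class TestAdiposityPeak:
    def test_symmetric_quadratic_peaks_at_center(self):
        ext = derive_ap(_curve(linear=0.0, quadratic=-0.4, cubic=0.0))
        assert ext.age_years == pytest.approx(0.75)
        assert ext.bmi == pytest.approx(np.exp(2.86))
        assert not ext.boundary

    def test_cubic_example_matches_grid_search(self):
        curve = _curve(linear=0.05, quadratic=-0.4, cubic=0.02)
        ext = derive_ap(curve)
        assert ext.age_years == pytest.approx(0.813, abs=5e-4)
        grid = _grid_extremum(curve, (0.25, 1.25), "max")
        assert ext.age_years == pytest.approx(grid, abs=1e-4)

    def test_monotone_increasing_hits_upper_boundary(self):
        ext = derive_ap(_curve(linear=0.3, quadratic=0.0, cubic=0.0))
        assert ext.age_years == pytest.approx(1.25)
        assert ext.boundary

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            derive_ap(_curve(linear=np.nan))

    def test_bmi_is_exact_exponential_of_log_prediction(self):
        curve = _curve(linear=0.05, quadratic=-0.4, cubic=0.02)
        ext = derive_ap(curve)
        assert ext.bmi == np.exp(curve.log_bmi(ext.age_years))


class TestAdiposityRebound:
    def test_symmetric_convex_minimum_at_center(self):
        ext = derive_ar(_curve(linear=0.0, quadratic=0.05, cubic=0.0, center=7.25))
        assert ext.age_years == pytest.approx(7.25)
        assert not ext.boundary

    def test_monotone_decreasing_hits_upper_boundary(self):
        ext = derive_ar(_curve(linear=-0.05, quadratic=0.0, cubic=0.0, center=7.25))
        assert ext.age_years == pytest.approx(8.5)
        assert ext.boundary

    @pytest.mark.parametrize("mode,derive,window,center", [
        ("max", derive_ap, (0.25, 1.25), 0.75),
        ("min", derive_ar, (2.5, 8.5), 7.25),
    ])
    def test_agrees_with_grid_oracle_on_random_curves(self, mode, derive,
                                                      window, center):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            if mode == "max":
                curve = _curve(linear=rng.normal(0, 0.1),
                               quadratic=rng.normal(-0.3, 0.2),
                               cubic=rng.normal(0.1, 0.15), center=center)
            else:
                curve = _curve(linear=rng.normal(0.017, 0.01),
                               quadratic=rng.normal(0.0033, 0.003),
                               cubic=rng.normal(-0.0002, 0.0005), center=center)
            ext = derive(curve)
            grid = _grid_extremum(curve, window, mode)
            assert abs(ext.age_years - grid) < 1e-4


class TestBmiMixedModels:
    def _simulate(self, n, seed, noise=0.03, re_scale=1.0, fixed_ga=False):
        # fixed_ga holds gestational age constant: GA shifts the infancy
        # intercept per child, so it must not vary in noiseless exact tests
        ga = {40: 1.0} if fixed_ga else None
        kwargs = {"ga_distribution": ga} if ga else {}
        cfg = CohortConfig(n_individuals=n, n_studies=1, snp_panel=(),
                           noise_log_bmi=noise, noise_height_cm=0.0 if noise == 0 else 0.5,
                           random_effect_scale=re_scale, seed=seed, **kwargs)
        return simulate_study(cfg, "s", seed).measurements

    def test_noiseless_limit_recovers_fixed_effects_exactly(self):
        meas = self._simulate(60, 5, noise=0.0, re_scale=0.0, fixed_ga=True)
        fit = fit_infancy_bmi_model(meas)
        truth = [INFANCY_TRUE[k] for k in ("b0", "b1", "b2", "b3", "b_sex")]
        # intercept absorbs the (constant) GA effect
        np.testing.assert_allclose(fit.params[1:], truth[1:], atol=1e-6)
        assert fit.params[0] == pytest.approx(truth[0] + 0.008, abs=1e-6)
        assert fit.resid_var == 0.0
        assert (fit.random_effects.to_numpy() == 0).all()

    def test_childhood_noiseless_limit(self):
        meas = self._simulate(60, 6, noise=0.0, re_scale=0.0, fixed_ga=True)
        fit = fit_childhood_bmi_model(meas)
        truth = [CHILDHOOD_TRUE[k] for k in
                 ("b0", "b1", "b2", "b3", "b_sex", "b_age_sex", "b_age2_sex")]
        np.testing.assert_allclose(fit.params, truth, atol=1e-6)

    @pytest.mark.parametrize("fitter,names,truth_map", [
        (fit_infancy_bmi_model, ("b0", "b1", "b2", "b3", "b_sex"), INFANCY_TRUE),
        (fit_childhood_bmi_model,
         ("b0", "b1", "b2", "b3", "b_sex", "b_age_sex", "b_age2_sex"),
         CHILDHOOD_TRUE),
    ])
    def test_parameter_recovery_within_three_se(self, fitter, names, truth_map):
        meas = self._simulate(500, 11)
        fit = fitter(meas)
        for i, name in enumerate(names):
            truth = truth_map[name]
            if name == "b0":
                continue  # intercept absorbs the gestational-age population mean
            assert abs(fit.params[i] - truth) < 3 * fit.params_se[i], name

    def test_ml_loglike_dominates_generating_parameters(self):
        from growthgwas.synthetic import INFANCY_RE_COV
        meas = self._simulate(150, 12)
        fit = fit_infancy_bmi_model(meas)
        # evaluate at the generating parameters (intercept offset by the
        # mean GA effect so the comparison is at the same population mean)
        truth = np.array([INFANCY_TRUE[k] for k in ("b0", "b1", "b2", "b3", "b_sex")])
        ga_mean = (meas.drop_duplicates("id")["ga_weeks"] - 39).mean()
        truth[0] += 0.008 * ga_mean
        ll_truth = bmi_loglike_at(meas, "infancy", truth, INFANCY_RE_COV, 0.03**2)
        assert fit.loglike >= ll_truth - 1e-6

    def test_too_few_subjects_is_refused(self):
        meas = self._simulate(10, 13)
        with pytest.raises(ValueError, match="at least 20 subjects"):
            fit_infancy_bmi_model(meas)

    def test_individual_curve_reproduces_model_prediction(self):
        meas = self._simulate(80, 14)
        fit = fit_infancy_bmi_model(meas)
        sex = meas.drop_duplicates("id").set_index("id")["sex"]
        curve = individual_curves(fit, sex)[0]
        p = dict(zip(fit.param_names, fit.params))
        u = fit.random_effects.loc[curve.subject_id]
        for age in (0.1, 0.5, 1.0, 1.4):
            x = age - fit.center_age
            expected = (p["b0"] + p["b_sex"] * curve.sex + u["u0"]
                        + (p["b1"] + u["u1"]) * x + p["b2"] * x**2 + p["b3"] * x**3)
            assert curve.log_bmi(age) == pytest.approx(expected, abs=1e-12)


class TestReed1:
    def test_noiseless_parameters_recovered_exactly(self):
        t = np.array([0.5, 1, 2, 4, 8, 12, 18, 24])
        meas = reed1_measurements({"a": (50.0, 1.5, 3.0, -2.0),
                                   "b": (48.0, 1.8, 2.0, -1.0)}, t)
        fit = fit_reed1(meas, "weight_kg", sex_stratum=0)
        # (c, d) are shared: construct both subjects with distinct (a, b)
        # but common (c, d) for exact recovery
        meas2 = reed1_measurements({"a": (50.0, 1.5, 3.0, -2.0),
                                    "b": (48.0, 1.8, 3.0, -2.0)}, t)
        fit2 = fit_reed1(meas2, "weight_kg", sex_stratum=0)
        assert fit2.c == pytest.approx(3.0, abs=1e-8)
        assert fit2.d == pytest.approx(-2.0, abs=1e-8)
        np.testing.assert_allclose(fit2.subjects.loc["a", ["a", "b"]],
                                   [50.0, 1.5], atol=1e-8)
        np.testing.assert_allclose(fit2.subjects.loc["b", ["a", "b"]],
                                   [48.0, 1.8], atol=1e-8)

    def test_slope_error_within_linear_model_theory(self, rng):
        t = np.linspace(0.5, 24, 12)
        c, d, sigma = 3.0, -2.0, 0.1
        params = {f"s{i}": (rng.normal(50, 2), rng.normal(1.5, 0.2), c, d)
                  for i in range(300)}
        meas = reed1_measurements(params, t, noise_sd=sigma, rng=rng)
        fit = fit_reed1(meas, "weight_kg", sex_stratum=0)
        D = np.column_stack([np.ones(len(t)), t])
        se_b = sigma * np.sqrt(np.linalg.inv(D.T @ D)[1, 1])
        errors = [abs(fit.subjects.loc[s, "b"] - params[s][1]) for s in params]
        assert np.mean(errors) < 3 * se_b

    def test_subject_with_two_timepoints_flagged_missing(self):
        t = np.array([0.5, 1, 2, 4, 8, 12])
        meas = reed1_measurements({"ok": (50.0, 1.5, 3.0, -2.0)}, t)
        short = reed1_measurements({"short": (50.0, 1.5, 3.0, -2.0)}, t[:2])
        fit = fit_reed1(pd.concat([meas, short]), "weight_kg", sex_stratum=0)
        assert "short" in fit.missing
        assert "short" not in fit.subjects.index

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="measure"):
            fit_reed1(pd.DataFrame(), "head_circumference", 0)


class TestPeakVelocity:
    def test_interior_stationary_point(self):
        pv, t_at, boundary = derive_peak_velocity(1.0, 2.0, 1.0, (0.25, 24.0))
        assert t_at == pytest.approx(1.0)
        assert pv == pytest.approx(2.0)
        assert not boundary

    def test_finite_difference_oracle(self):
        b, c, d = 1.0, 2.0, 1.0
        t = np.linspace(0.5, 23.5, 200)
        h = 1e-4
        def y(tt):
            return b * tt + c * np.log(tt) + d / tt
        fd = (y(t + h) - y(t - h)) / (2 * h)
        np.testing.assert_allclose(reed1_velocity(b, c, d, t), fd, rtol=1e-6)

    def test_constant_velocity_when_c_and_d_zero(self):
        pv, _, boundary = derive_peak_velocity(1.3, 0.0, 0.0)
        assert pv == 1.3
        assert not boundary

    def test_no_interior_stationary_point_hits_boundary(self):
        # d/c < 0: velocity is monotone on the window
        pv, t_at, boundary = derive_peak_velocity(1.0, 2.0, -1.0, (0.25, 24.0))
        assert boundary
        assert t_at in (0.25, 24.0)
        grid = np.linspace(0.25, 24.0, 100000)
        assert pv == pytest.approx(reed1_velocity(1.0, 2.0, -1.0, grid).max(),
                                   abs=1e-6)

    def test_window_outside_range_rejected(self):
        with pytest.raises(ValueError, match="window"):
            derive_peak_velocity(1.0, 2.0, 1.0, (0.0, 24.0))


class TestPopulationDerivation:
    def test_population_mean_age_ap_near_generating_peak(self, small_derived):
        derived, _ = small_derived
        assert 0.6 <= derived["age_ap"].mean() <= 0.9

    def test_derived_table_has_all_traits_and_flags(self, small_derived):
        derived, _ = small_derived
        for trait in ("phv", "pwv", "age_ap", "bmi_ap", "age_ar", "bmi_ar"):
            assert trait in derived.columns
            assert f"{trait}_missing" in derived.columns
        assert derived["age_ap"].dropna().between(0.25, 1.25).all()
        assert derived["age_ar"].dropna().between(2.5, 8.5).all()
        assert (derived["bmi_ap"].dropna() > 0).all()
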