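"""Multinomial likelihood, background hazard, two-step fits, profile CIs."""

import math

import numpy as np
import pytest

from gutspulse import (
    ExposureProfile,
    ITParameters,
    ModelVariant,
    SDParameters,
    SurvivalDataset,
    calibrate,
    compare_models,
    fit_background_hazard,
    generate_study_survival,
    log_likelihood,
    mean_percentage_error,
)
from gutspulse.calibration import (
    PROFILE_DROP_95,
    _interval_log_likelihood,
    _profile_bounds,
)
from conftest import H_B, IT_REDUCED_BOTH, SD_REDUCED_BOTH


class TestIntervalLikelihood:
    """Closed-form worked examples of the interval-censored likelihood."""

    def test_no_deaths_before_censoring(self):
        # all 10 animals alive at the last observation die in (t_n, inf)
        assert _interval_log_likelihood([10, 10], [1.0, 0.5]) == pytest.approx(
            10 * math.log(0.5), abs=1e-10
        )

    def test_all_die_within_interval(self):
        assert _interval_log_likelihood([10, 0], [1.0, 0.5]) == pytest.approx(
            10 * math.log(0.5), abs=1e-10
        )

    def test_zero_probability_interval_with_no_deaths_contributes_zero(self):
        # 0 * ln(0) := 0 on the flat piece; censoring term uses S_n
        ll = _interval_log_likelihood([10, 6, 6], [1.0, 0.6, 0.6])
        assert ll == pytest.approx(4 * math.log(0.4) + 6 * math.log(0.6), abs=1e-10)
        assert ll == pytest.approx(-6.7301, abs=1e-4)

    def test_deaths_in_impossible_interval_give_minus_infinity(self):
        assert _interval_log_likelihood([10, 5], [1.0, 1.0]) == -math.inf

    def test_single_interval_reduces_to_binomial_kernel(self):
        # up to the binomial coefficient: k ln p + (n-k) ln (1-p)
        S1 = 0.73
        y = [10, 7]
        ll = _interval_log_likelihood(y, [1.0, S1])
        assert ll == pytest.approx(3 * math.log(1 - S1) + 7 * math.log(S1), abs=1e-12)

    def test_invariant_to_splitting_interval_without_deaths(self):
        # inserting an observation with no deaths and intermediate S
        ll_a = _interval_log_likelihood([10, 4], [1.0, 0.5])
        ll_b = _interval_log_likelihood([10, 10, 4], [1.0, 1.0, 0.5])
        assert ll_a == pytest.approx(ll_b, abs=1e-12)


class TestModelLogLikelihood:
    def test_sums_over_treatments(self, pulse_profile):
        v = ModelVariant("sd", "reduced")
        p = SDParameters(1.7, 0.126, 16.4, 0.01)
        ds = SurvivalDataset(
            "A", pulse_profile, (0.0, 1.0, 4.0, 10.0), (10, 9, 7, 6)
        )
        one = log_likelihood(v, p, [ds])
        two = log_likelihood(v, p, [ds, ds])
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestBackgroundHazard:
    def test_one_death_in_ten_over_ten_days(self):
        profile = ExposureProfile.constant(0.0, 10.0)
        ds = SurvivalDataset("ctrl", profile, (0.0, 10.0), (10, 9))
        fit = fit_background_hazard([ds])
        # d/dh [ln(1-e^{-10h}) - 90h] = 0  =>  e^{-10h} = 9/10
        assert fit.h_b == pytest.approx(math.log(10 / 9) / 10, rel=1e-4)
        assert not fit.at_boundary

    def test_no_deaths_gives_boundary_zero(self):
        profile = ExposureProfile.constant(0.0, 10.0)
        ds = SurvivalDataset("ctrl", profile, (0.0, 5.0, 10.0), (10, 10, 10))
        fit = fit_background_hazard([ds])
        assert fit.h_b == 0.0
        assert fit.at_boundary

    def test_pooling_two_identical_controls_matches_single(self):
        profile = ExposureProfile.constant(0.0, 10.0)
        ds = SurvivalDataset("ctrl", profile, (0.0, 10.0), (10, 9))
        one = fit_background_hazard([ds])
        two = fit_background_hazard([ds, ds])
        assert two.h_b == pytest.approx(one.h_b, rel=1e-5)


class TestProfileBounds:
    def test_quadratic_profile_gives_chi_square_bounds(self):
        # ln L(theta) = -(theta - 2)^2: bounds at 2 -/+ sqrt(1.9207)
        f = lambda th: -((th - 2.0) ** 2)
        lo, hi = _profile_bounds(f, 2.0, 0.0)
        assert lo == pytest.approx(2.0 - math.sqrt(PROFILE_DROP_95), abs=2e-3)
        assert hi == pytest.approx(2.0 + math.sqrt(PROFILE_DROP_95), abs=2e-3)

    def test_flat_profile_reports_not_determined(self):
        lo, hi = _profile_bounds(lambda th: 0.0, 1.0, 0.0, max_steps=10)
        assert lo is None and hi is None

    def test_one_sided_flat_profile(self):
        # likelihood indifferent to increases (threshold above all dose metrics)
        f = lambda th: -((th - 2.0) ** 2) if th < 2.0 else 0.0
        lo, hi = _profile_bounds(f, 2.0, 0.0, max_steps=15)
        assert lo is not None
        assert hi is None


@pytest.fixture(scope="module")
def sd_study():
    v = ModelVariant("sd", "reduced")
    truth = SDParameters(
        SD_REDUCED_BOTH.k_d, SD_REDUCED_BOTH.k_k, SD_REDUCED_BOTH.z, H_B
    )
    data = generate_study_survival(v, truth, seed=101, n_per_treatment=700)
    return v, truth, data


class TestCalibrate:

    def test_recovers_sd_generating_parameters(self, sd_study):
        v, truth, data = sd_study
        fit = calibrate(v, data, "both", h_b=H_B, seed=7, n_starts=3)
        assert fit.converged
        assert fit.estimates["k_d"] == pytest.approx(truth.k_d, rel=0.10)
        assert fit.estimates["k_k"] == pytest.approx(truth.k_k, rel=0.10)
        assert fit.estimates["z"] == pytest.approx(truth.z, rel=0.10)

    def test_recovers_it_generating_parameters(self):
        v = ModelVariant("it", "reduced")
        truth = ITParameters(
            IT_REDUCED_BOTH.k_d, IT_REDUCED_BOTH.alpha, IT_REDUCED_BOTH.beta, H_B
        )
        data = generate_study_survival(v, truth, seed=202, n_per_treatment=700)
        fit = calibrate(v, data, "both", h_b=H_B, seed=7, n_starts=3)
        assert fit.converged
        assert fit.estimates["k_d"] == pytest.approx(truth.k_d, rel=0.10)
        assert fit.estimates["alpha"] == pytest.approx(truth.alpha, rel=0.10)
        assert fit.estimates["beta"] == pytest.approx(truth.beta, rel=0.15)

    def test_zero_mortality_data_flagged_unidentifiable(self, pulse_profile):
        v = ModelVariant("sd", "reduced")
        times = tuple(float(t) for t in range(11))
        ds = SurvivalDataset("A", pulse_profile, times, (10,) * 11)
        fit = calibrate(v, [ds], "all", h_b=0.0, seed=1, n_starts=2, maxfev=200)
        # threshold runs above every dose metric: model predicts S == 1
        # exactly, the best attainable likelihood for all-alive data
        assert fit.log_likelihood == pytest.approx(0.0, abs=1e-9)
        # the fitted threshold sits above everything the dose metric reaches,
        # i.e. the data carry no signal to bound it from above
        from gutspulse import dose_metric
        fitted = SDParameters(fit.estimates["k_d"], fit.estimates["k_k"], fit.estimates["z"])
        m = dose_metric(v, fitted, pulse_profile, np.linspace(0, 10, 201))
        assert fit.estimates["z"] >= m.max() - 1e-9

    def test_likelihood_step_improves_on_least_squares_start(self, sd_study):
        v, truth, data = sd_study
        fit = calibrate(v, data, "both", h_b=H_B, seed=7, n_starts=2)
        ll_truth = log_likelihood(
            v,
            SDParameters(truth.k_d, truth.k_k, truth.z, H_B),
            list(data["pulsed"]) + list(data["acute"]),
        )
        assert fit.log_likelihood >= ll_truth - 1e-6  # MLE at least as good as truth


class TestMeanPercentageError:
    def test_identical_vectors_give_zero(self):
        assert mean_percentage_error([0.9, 0.4], [0.9, 0.4]) == 0.0

    def test_single_point(self):
        assert mean_percentage_error([1.0], [0.5]) == pytest.approx(100.0)

    def test_two_point_average(self):
        assert mean_percentage_error([0.9, 0.4], [1.0, 0.5]) == pytest.approx(15.0)

    def test_zero_model_survival_rejected(self):
        with pytest.raises(Exception):
            mean_percentage_error([0.5], [0.0])


class TestCompareModels:
    def test_single_cell_total_equals_fit_likelihood(self, pulse_profile):
        v = ModelVariant("sd", "reduced")
        p = SDParameters(1.7, 0.126, 16.4, 0.01)
        ds = SurvivalDataset("A", pulse_profile, (0.0, 1.0, 10.0), (10, 8, 6))
        table = compare_models([(v, "pulsed", p)], {"pulsed": [ds]})
        row = table.iloc[0]
        assert row["total_log_likelihood"] == pytest.approx(
            log_likelihood(v, p, [ds]), rel=1e-12
        )

    def test_perfect_predictions_dominate(self, pulse_profile):
        """A parameter set whose predictions match the observed fractions
        exactly has a total likelihood at least that of any other set."""
        v = ModelVariant("sd", "reduced")
        good = SDParameters(1.7, 0.126, 16.4, H_B)
        data = generate_study_survival(v, good, seed=5, n_per_treatment=200)
        groups = {"pulsed": data["pulsed"], "acute": data["acute"]}
        bad = SDParameters(0.4, 0.02, 5.0, H_B)
        table = compare_models([(v, "both", good), (v, "both", bad)], groups)
        assert (
            table.iloc[0]["total_log_likelihood"]
            > table.iloc[1]["total_log_likelihood"]
        )
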