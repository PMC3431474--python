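"""Forward survival simulation: closed-form correctness and model invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutspulse import (
    ExposureProfile,
    ITParameters,
    ModelVariant,
    SDParameters,
    background_survival,
    dose_metric,
    survival_it,
    survival_sd,
)
from conftest import TK, td_params_for
from euler_oracle import euler_survival_at


def random_scenario(rng):
    """A study-realistic random profile, variant and parameter set."""
    n = int(rng.integers(1, 5))
    edges = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 9.5, n - 1)), [10.0]])
    profile = ExposureProfile(tuple(edges[:-1]), tuple(rng.uniform(0, 35, n)), 10.0)
    full = rng.random() < 0.5
    mech = "sd" if rng.random() < 0.5 else "it"
    variant = ModelVariant(mech, "full" if full else "reduced", TK if full else None)
    scale = TK.k_in / TK.k_out if full else 1.0
    k_d = rng.uniform(0.3, 6.0)
    h_b = rng.uniform(0, 0.02)
    if mech == "sd":
        params = SDParameters(
            k_d, rng.uniform(0.01, 0.2) / scale, rng.uniform(2, 25) * scale, h_b
        )
    else:
        params = ITParameters(
            k_d, rng.uniform(5, 25) * scale, rng.uniform(2, 8), h_b
        )
    return variant, params, profile


class TestDoseMetric:
    def test_reduced_steady_state_reaches_external_concentration(self):
        v = ModelVariant("sd", "reduced")
        p = SDParameters(k_d=2.0, k_k=1.0, z=100.0)
        m = dose_metric(v, p, ExposureProfile.constant(7.0, 30.0), [30.0])
        assert m[0] == pytest.approx(7.0, rel=1e-9)

    def test_full_metric_tracks_internal_equilibrium_for_fast_damage(self, tk_params):
        v = ModelVariant("sd", "full", tk_params)
        p = SDParameters(k_d=500.0, k_k=1.0, z=1e9)
        m = dose_metric(v, p, ExposureProfile.constant(5.0, 30.0), [30.0])
        assert m[0] == pytest.approx(tk_params.k_in * 5.0 / tk_params.k_out, rel=1e-4)

    def test_full_metric_peaks_after_pulse_end(self, tk_params, pulse_profile):
        # slow damage recovery: D* keeps rising ~0.126 d into the clean-water phase
        v = ModelVariant("it", "full", tk_params)
        p = ITParameters(k_d=0.6, alpha=1.0, beta=1.0)
        t = np.linspace(0.9, 1.6, 7001)
        m = dose_metric(v, p, pulse_profile, t)
        t_peak = t[np.argmax(m)]
        assert t_peak == pytest.approx(1.1262, abs=2e-4)
        # decays at the damage-recovery rate afterwards
        tail = dose_metric(v, p, pulse_profile, [5.0, 6.0])
        assert np.log(tail[0] / tail[1]) == pytest.approx(0.6, rel=0.02)

    def test_equal_rate_degeneracy_is_continuous(self, tk_params, pulse_profile):
        v = ModelVariant("sd", "full", tk_params)
        t = np.linspace(0, 10, 97)
        near = dose_metric(v, SDParameters(6.9 * (1 + 1e-7), 1, 1), pulse_profile, t)
        limit = dose_metric(v, SDParameters(6.9, 1, 1), pulse_profile, t)
        assert np.allclose(near, limit, rtol=1e-5, atol=1e-8)


class TestSurvivalSD:
    def test_metric_below_threshold_means_no_mortality(self, pulse_profile):
        v = ModelVariant("sd", "reduced")
        p = SDParameters(k_d=1.0, k_k=0.5, z=100.0, h_b=0.0)
        traj = survival_sd(v, p, pulse_profile, np.linspace(0, 10, 11))
        assert np.allclose(traj.survival, 1.0)

    def test_zero_killing_rate_reduces_to_background(self, pulse_profile):
        v = ModelVariant("sd", "reduced")
        p = SDParameters(k_d=1.0, k_k=1e-300, z=0.0, h_b=0.05)
        traj = survival_sd(v, p, pulse_profile, [0.0, 2.0, 10.0])
        assert np.allclose(traj.survival, np.exp(-0.05 * np.array([0, 2, 10])), rtol=1e-10)

    def test_constant_exposure_closed_form_oracle(self):
        """Frozen fine-grid value for the reduced model under constant 30 nmol/mL."""
        v = ModelVariant("sd", "reduced")
        p = SDParameters(k_d=1.7, k_k=0.126, z=16.4, h_b=0.0)
        traj = survival_sd(v, p, ExposureProfile.constant(30.0, 4.0), [4.0])
        assert traj.survival[0] == pytest.approx(0.0064002393, abs=1e-9)

    def test_grid_independence(self, two_pulse_profile, tk_params):
        """Doubling output density must not change S at shared times."""
        v = ModelVariant("sd", "full", tk_params)
        p = SDParameters(k_d=1.2, k_k=0.005, z=40.0, h_b=0.01)
        coarse = np.linspace(0, 10, 21)
        fine = np.linspace(0, 10, 41)
        s1 = survival_sd(v, p, two_pulse_profile, coarse).survival
        s2 = survival_sd(v, p, two_pulse_profile, fine).survival[::2]
        assert np.max(np.abs(s1 - s2)) < 1e-6


class TestSurvivalIT:
    def test_constant_exposure_limit_is_threshold_cdf(self):
        v = ModelVariant("it", "reduced")
        p = ITParameters(k_d=2.0, alpha=10.0, beta=4.0, h_b=0.0)
        c = 8.0
        traj = survival_it(v, p, ExposureProfile.constant(c, 60.0), [60.0])
        expected = 1.0 - 1.0 / (1.0 + (c / 10.0) ** (-4.0))
        assert traj.survival[0] == pytest.approx(expected, rel=1e-6)

    def test_cdf_frozen_after_exposure_peak(self, pulse_profile):
        v = ModelVariant("it", "reduced")
        p = ITParameters(k_d=2.0, alpha=10.0, beta=4.0, h_b=0.0)
        traj = survival_it(v, p, pulse_profile, [2.0, 5.0, 10.0])
        assert traj.threshold_cdf[0] == pytest.approx(traj.threshold_cdf[2], rel=1e-12)

    def test_identical_second_pulse_causes_no_extra_it_mortality(self, tk_params):
        """With full damage recovery between equal pulses the tolerance
        distribution is already exhausted below the running max: no new deaths."""
        v = ModelVariant("it", "full", tk_params)
        p = ITParameters(k_d=2.0, alpha=40.0, beta=4.0, h_b=0.0)
        one = ExposureProfile.pulses([0.0], 1.0, 28.0, 40.0)
        two = ExposureProfile.pulses([0.0, 30.0], 1.0, 28.0, 40.0)
        s_one = survival_it(v, p, one, [29.5, 40.0]).survival
        s_two = survival_it(v, p, two, [29.5, 40.0]).survival
        assert s_two[1] == pytest.approx(s_two[0], rel=1e-9)  # no deaths in 2nd pulse
        assert s_two[1] == pytest.approx(s_one[1], rel=1e-9)

    def test_appending_submaximal_exposure_leaves_cdf_unchanged(self):
        """Metamorphic running-max property: extra exposure below the running
        maximum of the dose metric cannot change F."""
        v = ModelVariant("it", "reduced")
        p = ITParameters(k_d=1.5, alpha=12.0, beta=5.0, h_b=0.0)
        base = ExposureProfile.from_segments([(0, 1, 30.0), (1, 12, 0.0)])
        tail = ExposureProfile.from_segments([(0, 1, 30.0), (1, 8, 0.0), (8, 12, 4.0)])
        f1 = survival_it(v, p, base, [12.0]).threshold_cdf[0]
        f2 = survival_it(v, p, tail, [12.0]).threshold_cdf[0]
        assert f2 == pytest.approx(f1, rel=1e-10)


class TestBackgroundSurvival:
    def test_zero_hazard(self):
        assert background_survival(0.0, 123.0) == 1.0

    def test_ninety_percent_over_ten_days(self):
        h = -np.log(0.9) / 10.0
        assert background_survival(h, 10.0) == pytest.approx(0.9, rel=1e-12)

    def test_closed_form_value(self):
        assert background_survival(0.01054, 4.0) == pytest.approx(0.9587, abs=5e-5)

    def test_negative_time_rejected(self):
        with pytest.raises(Exception):
            background_survival(0.1, -1.0)


class TestConsistencyAndOracles:
    def test_reduced_with_elimination_rate_matches_scaled_internal_conc(
        self, tk_params, two_pulse_profile
    ):
        """Lumped-model consistency: the reduced metric with k_d = k_out is
        exactly the internal concentration divided by the bioaccumulation
        factor (substituting u = C_int/BAF into the one-compartment ODE
        gives du/dt = k_out (C_ext - u), the reduced equation)."""
        from gutspulse import simulate_internal

        vr = ModelVariant("sd", "reduced")
        t = np.linspace(0, 10, 101)
        mr = dose_metric(
            vr, SDParameters(tk_params.k_out, 1.0, 1.0), two_pulse_profile, t
        )
        cint = simulate_internal(two_pulse_profile, tk_params, t)
        baf = tk_params.k_in / tk_params.k_out
        assert np.allclose(cint, mr * baf, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_euler_oracle_on_random_scenarios(self, seed):
        from gutspulse import survival as survival_dispatch
        rng = np.random.default_rng(1000 + seed)
        variant, params, profile = random_scenario(rng)
        times = np.linspace(0, 10, 21)
        traj = survival_dispatch(variant, params, profile, times)
        oracle = euler_survival_at(variant, params, profile, times)
        assert np.max(np.abs(traj.survival - oracle)) < 1e-4


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 10**6))
def test_survival_is_monotone_and_bounded(seed):
    """S(0)=1, S non-increasing, 0 <= S <= 1, H/F monotone for all variants."""
    from gutspulse import survival as survival_dispatch

    rng = np.random.default_rng(seed)
    variant, params, profile = random_scenario(rng)
    times = np.linspace(0, 10, 41)
    traj = survival_dispatch(variant, params, profile, times)
    s = traj.survival
    assert s[0] == pytest.approx(1.0)
    assert np.all(s <= 1.0 + 1e-12) and np.all(s >= 0.0)
    assert np.all(np.diff(s) <= 1e-10)
    cum = traj.cumulative_hazard if traj.cumulative_hazard is not None else traj.threshold_cdf
    assert np.all(np.diff(cum) >= -1e-10)
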