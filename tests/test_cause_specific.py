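import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crsafety import (
    EVENT_AE,
    Condition,
    EstimationError,
    SeedInfo,
    cox_partial_loglik,
    fit_cox_cause_specific,
    simulate_trial,
)
from conftest import brute_force_mle, brute_force_partial_loglik, make_dataset


def toy_four_subjects():
    # interleaved arm events (an all-control-first ordering would make the
    # partial likelihood monotone, with no interior maximum to recover)
    return make_dataset([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [0, 1, 0, 1])


class TestPartialLoglik:
    def test_null_value_is_log_risk_set_sizes(self):
        # two events with risk sets of sizes 4 and 3; at beta=0 every
        # exp term is 1 so the loglik is -log 4 - log 3
        ds = make_dataset([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], [0, 1, 0, 1])
        assert cox_partial_loglik(ds, EVENT_AE, 0.0) == pytest.approx(
            -math.log(4) - math.log(3)
        )

    def test_matches_brute_force_at_arbitrary_beta(self):
        ds = toy_four_subjects()
        for beta in (-1.5, 0.0, 0.7, 2.0):
            expected = brute_force_partial_loglik(ds.time, ds.event, ds.group, 1, beta)
            assert cox_partial_loglik(ds, EVENT_AE, beta) == pytest.approx(expected)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            cox_partial_loglik(toy_four_subjects(), EVENT_AE, math.inf)


class TestFitAgainstOracle:
    def test_four_subject_toy_matches_grid_search(self):
        ds = toy_four_subjects()
        fit = fit_cox_cause_specific(ds)
        oracle = brute_force_mle(ds.time, ds.event, ds.group, 1)
        assert fit.log_hr == pytest.approx(oracle, abs=1e-6)
        assert fit.converged

    def test_estimate_is_stationary_point(self):
        ds = toy_four_subjects()
        fit = fit_cox_cause_specific(ds)
        eps = 1e-5
        deriv = (
            cox_partial_loglik(ds, EVENT_AE, fit.log_hr + eps)
            - cox_partial_loglik(ds, EVENT_AE, fit.log_hr - eps)
        ) / (2 * eps)
        assert abs(deriv) < 1e-6

    def test_maximum_dominates_grid(self):
        ds = toy_four_subjects()
        fit = fit_cox_cause_specific(ds)
        best = cox_partial_loglik(ds, EVENT_AE, fit.log_hr)
        for beta in np.linspace(-5, 5, 41):
            assert best >= cox_partial_loglik(ds, EVENT_AE, float(beta)) - 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_small_fixtures_match_brute_force(self, data):
        n = data.draw(st.integers(4, 8))
        times = data.draw(
            st.lists(
                st.floats(0.5, 29.0),
                min_size=n, max_size=n, unique=True,
            )
        )
        events = data.draw(st.lists(st.sampled_from([0, 1, 1, 2]), min_size=n, max_size=n))
        groups = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n))
        # need events of interest in both arms for an interior maximum
        d1 = sum(e == 1 and g == 1 for e, g in zip(events, groups))
        d0 = sum(e == 1 and g == 0 for e, g in zip(events, groups))
        if d1 == 0 or d0 == 0:
            return
        ds = make_dataset(times, events, groups)
        fit = fit_cox_cause_specific(ds)
        oracle = brute_force_mle(ds.time, ds.event, ds.group, 1)
        if abs(oracle) > 8.0:
            return  # effectively monotone likelihood; no interior maximum
        assert fit.log_hr == pytest.approx(oracle, abs=1e-5)


class TestInvariances:
    def test_symmetric_arms_give_null_fit(self):
        # identical (time, event) multisets per arm force the score to
        # vanish at beta = 0
        times = [1.0, 2.5, 4.0, 8.0]
        ds = make_dataset(times + times, [1, 1, 2, 0] * 2, [0] * 4 + [1] * 4)
        fit = fit_cox_cause_specific(ds)
        assert fit.log_hr == pytest.approx(0.0, abs=1e-9)
        assert fit.p_value == pytest.approx(1.0, abs=1e-9)

    def test_time_scale_invariance(self, small_trial):
        fit = fit_cox_cause_specific(small_trial)
        scaled = make_dataset(small_trial.time * 3.7, small_trial.event, small_trial.group)
        fit_scaled = fit_cox_cause_specific(scaled)
        assert fit_scaled.log_hr == pytest.approx(fit.log_hr, abs=1e-9)
        assert fit_scaled.se == pytest.approx(fit.se, abs=1e-9)


class TestAgainstLifelines:
    def test_coefficient_and_se_match_reference(self, small_trial):
        lifelines = pytest.importorskip("lifelines")
        df = small_trial.to_frame()
        df["status"] = (df["event"] == EVENT_AE).astype(int)
        cph = lifelines.CoxPHFitter().fit(
            df[["time", "status", "group"]], "time", "status"
        )
        fit = fit_cox_cause_specific(small_trial)
        assert fit.log_hr == pytest.approx(cph.params_["group"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["group"], abs=1e-6)


class TestLargeSampleRecovery:
    def test_hr_consistent_for_two_to_one_design(self):
        # verum AE median 5, control 10, no deaths -> true cs HR = 2
        cond = Condition(5, 10, median_death_verum=math.inf,
                         median_death_control=math.inf)
        ds = simulate_trial(cond, 50_000, seed_info=SeedInfo(29, 0, 0))
        fit = fit_cox_cause_specific(ds)
        assert abs(fit.log_hr - math.log(2.0)) < 3 * fit.se


class TestDegenerateInputs:
    def test_zero_events_raises(self):
        ds = make_dataset([30.0, 30.0], [0, 0], [0, 1])
        with pytest.raises(EstimationError):
            fit_cox_cause_specific(ds)

    def test_monotone_likelihood_capped_and_flagged(self):
        ds = make_dataset([1.0, 2.0, 30.0, 30.0], [1, 1, 0, 0], [1, 1, 0, 0])
        fit = fit_cox_cause_specific(ds)
        assert fit.log_hr == pytest.approx(15.0)
        assert not fit.converged

    def test_wald_interval_brackets_estimate(self, small_trial):
        fit = fit_cox_cause_specific(small_trial)
        assert fit.ci_low < fit.hr < fit.ci_high
        assert 0.0 <= fit.p_value <= 1.0
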