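import math

import numpy as np
import pytest
from scipy import integrate

from crsafety import (
    EVENT_AE,
    EVENT_CENSORED,
    EVENT_DEATH,
    GROUP_CONTROL,
    GROUP_VERUM,
    Condition,
    SeedInfo,
    condition_grid,
    dataset_from_frame,
    hazard_from_median,
    simulate_trial,
    summarize_condition,
    true_cif,
    true_cs_hr,
    true_death_hr,
)
from conftest import make_dataset


class TestHazardFromMedian:
    @pytest.mark.parametrize(
        "median, expected",
        [
            (math.log(2.0), 1.0),
            (20.0, math.log(2.0) / 20.0),
            (math.inf, 0.0),
        ],
    )
    def test_formula(self, median, expected):
        assert hazard_from_median(median) == pytest.approx(expected, abs=1e-12)

    def test_inverse_proportionality(self):
        assert hazard_from_median(10.0) / hazard_from_median(20.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0, -math.inf])
    def test_nonpositive_median_rejected(self, bad):
        with pytest.raises(ValueError):
            hazard_from_median(bad)


class TestTrueHazardRatios:
    def test_equal_medians_give_unity(self):
        assert true_cs_hr(Condition(10, 10)) == pytest.approx(1.0)

    def test_death_hr_is_half_by_design(self):
        # medians 20 (verum) vs 10 (control) -> exp-rate ratio exactly 0.5
        assert true_death_hr(Condition(5, 5)) == pytest.approx(0.5, abs=0)

    def test_extreme_cell(self):
        assert true_cs_hr(Condition(20, 1)) == pytest.approx(0.05)


class TestGrid:
    def test_grid_size_and_truth_partition(self):
        grid = condition_grid()
        assert len(grid) == 400
        hr = np.array([true_cs_hr(c) for c in grid])
        assert (hr < 1).sum() == 190
        assert (hr > 1).sum() == 190
        assert (hr == 1).sum() == 20

    def test_condition_invariants(self):
        with pytest.raises(ValueError):
            Condition(0.0, 10.0)
        with pytest.raises(ValueError):
            Condition(10.0, 10.0, censor_time=-1.0)


class TestSimulateTrial:
    def test_construction_invariants(self, null_condition):
        ds = simulate_trial(null_condition, 250, seed_info=SeedInfo(3, 1, 2))
        assert len(ds) == 500
        assert (ds.group == GROUP_VERUM).sum() == 250
        assert (ds.group == GROUP_CONTROL).sum() == 250
        assert np.all(ds.time > 0)
        assert np.all(ds.time <= null_condition.censor_time)
        censored = ds.event == EVENT_CENSORED
        assert np.all(ds.time[censored] == null_condition.censor_time)
        assert np.all(ds.time[~censored] < null_condition.censor_time)

    def test_identical_seed_bit_identical(self, null_condition):
        a = simulate_trial(null_condition, 100, seed_info=SeedInfo(11, 4, 9))
        b = simulate_trial(null_condition, 100, seed_info=SeedInfo(11, 4, 9))
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.event, b.event)
        c = simulate_trial(null_condition, 100, seed_info=SeedInfo(11, 4, 10))
        assert not np.array_equal(a.time, c.time)

    def test_rate_zero_sentinel_suppresses_adverse_events(self):
        cond = Condition(math.inf, math.inf)
        ds = simulate_trial(cond, 200, seed_info=SeedInfo(5, 0, 0))
        assert set(np.unique(ds.event)) <= {EVENT_CENSORED, EVENT_DEATH}

    def test_event_fraction_matches_closed_form_and_quadrature(self, null_condition):
        """Cause-1 frequency at the horizon vs the analytic CIF, two ways."""
        n = 100_000
        ds = simulate_trial(null_condition, n, seed_info=SeedInfo(17, 0, 0))
        verum = ds.group == GROUP_VERUM
        frac = (ds.event[verum] == EVENT_AE).mean()

        h1 = null_condition.hazard(EVENT_AE, GROUP_VERUM)
        h2 = null_condition.hazard(EVENT_DEATH, GROUP_VERUM)
        closed = h1 / (h1 + h2) * (1 - math.exp(-(h1 + h2) * 30.0))
        quad, _ = integrate.quad(lambda t: h1 * math.exp(-(h1 + h2) * t), 0, 30.0)
        assert closed == pytest.approx(quad, abs=1e-9)
        mc_se = math.sqrt(closed * (1 - closed) / n)
        assert abs(frac - closed) < 3 * mc_se

    def test_round_trip_through_frame(self, small_trial):
        ds2 = dataset_from_frame(small_trial.to_frame(), condition=small_trial.condition)
        assert np.array_equal(ds2.time, small_trial.time)
        assert np.array_equal(ds2.event, small_trial.event)
        assert np.array_equal(ds2.group, small_trial.group)


class TestTrueCif:
    def test_zero_at_time_zero(self, null_condition):
        assert true_cif(null_condition, GROUP_VERUM, EVENT_AE, 0.0) == 0.0

    def test_symmetric_causes_split_evenly_at_infinity(self):
        cond = Condition(10, 10, median_death_verum=10.0)
        assert true_cif(cond, GROUP_VERUM, EVENT_AE, 1e9) == pytest.approx(0.5)
        assert true_cif(cond, GROUP_VERUM, EVENT_DEATH, 1e9) == pytest.approx(0.5)

    def test_conservation(self, null_condition):
        t = np.linspace(0, 60, 7)
        h_all = null_condition.hazard(EVENT_AE, 0) + null_condition.hazard(EVENT_DEATH, 0)
        total = true_cif(null_condition, 0, EVENT_AE, t) + true_cif(
            null_condition, 0, EVENT_DEATH, t
        )
        np.testing.assert_allclose(total, 1 - np.exp(-h_all * t), atol=1e-12)

    def test_unknown_cause_rejected(self, null_condition):
        with pytest.raises(ValueError):
            true_cif(null_condition, GROUP_VERUM, 3, 1.0)


class TestSummarizeCondition:
    def test_mean_and_sd_of_replicate_medians(self):
        reps = [
            make_dataset([m, 30.0], [EVENT_AE, EVENT_CENSORED], [0, 0])
            for m in (4.0, 5.0, 6.0)
        ]
        out = summarize_condition(reps)
        row = out[(out.group == 0) & (out.cause == EVENT_AE)].iloc[0]
        assert row.mean_median == pytest.approx(5.0)
        assert row.sd_median == pytest.approx(1.0)
        assert row.n_used == 3

    def test_identical_replicates_have_zero_sd(self):
        reps = [make_dataset([4.0], [EVENT_AE], [1]) for _ in range(3)]
        out = summarize_condition(reps)
        row = out[(out.group == 1) & (out.cause == EVENT_AE)].iloc[0]
        assert row.sd_median == pytest.approx(0.0)

    def test_missing_cause_excluded(self):
        reps = [
            make_dataset([4.0], [EVENT_AE], [1]),
            make_dataset([9.0], [EVENT_DEATH], [1]),
        ]
        out = summarize_condition(reps)
        row = out[(out.group == 1) & (out.cause == EVENT_AE)].iloc[0]
        assert row.n_used == 1
        assert row.mean_median == pytest.approx(4.0)

    def test_large_sample_median_recovers_design_median(self):
        # no competing risk, effectively no censoring -> sample median ~ t_half
        cond = Condition(10, 10, median_death_verum=math.inf,
                         median_death_control=math.inf, censor_time=1e6)
        ds = simulate_trial(cond, 100_000, seed_info=SeedInfo(23, 0, 0))
        out = summarize_condition([ds])
        row = out[(out.group == 1) & (out.cause == EVENT_AE)].iloc[0]
        assert row.mean_median == pytest.approx(10.0, rel=0.02)
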