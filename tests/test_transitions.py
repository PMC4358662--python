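"""Transition curves: proportions, Gaussian fits, t50 extraction, outlier flagging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

import flydev as f
from flydev.simulate import CSV_COLUMNS
from flydev.transitions import TransitionCurve, rising_limb


def make_obs(rows):
    """rows: (replicate, temp, time, {stage: count}) tuples -> ObservationSet."""
    recs = []
    for rep, temp, time, counts in rows:
        rec = dict.fromkeys(CSV_COLUMNS, 0)
        rec.update(replicate_id=rep, temp_nominal_c=temp, temp_measured_c=temp,
                   sample_time_h=time)
        for stage, n in counts.items():
            rec[f"count_{stage}"] = n
        recs.append(rec)
    return f.ObservationSet(pd.DataFrame(recs))


def cumulative_series(mu=100.0, sigma=10.0, n=200, times=None, stage="L1", temp=20.0):
    t = np.asarray(times if times is not None else np.linspace(60, 140, 17), float)
    y = ndtr((t - mu) / sigma)
    return f.ProportionSeries(stage=stage, temperature=temp, times_h=t,
                              proportions=y, n_total=np.full(len(t), n))


class TestProportionEntered:
    def test_all_still_in_egg_gives_zeros(self):
        obs = make_obs([("R1", 20.0, t, {"E": 20}) for t in (1.0, 2.0, 3.0, 4.0)])
        series = f.proportion_entered(obs, "L1", 20.0)
        assert np.all(series.proportions == 0.0)

    def test_pooled_half_and_half(self):
        obs = make_obs([("R1", 20.0, 5.0, {"E": 40}), ("R2", 20.0, 5.0, {"L1": 40})])
        series = f.proportion_entered(obs, "L1", 20.0)
        assert series.proportions.tolist() == [0.5]
        assert series.n_total.tolist() == [80.0]

    def test_entered_is_cumulative_over_later_stages(self):
        obs = make_obs([("R1", 20.0, 5.0, {"E": 10, "L1": 5, "L2": 5})])
        series = f.proportion_entered(obs, "L1", 20.0)
        assert series.proportions.tolist() == [0.5]

    def test_dead_excluded_from_denominator(self):
        obs = make_obs([("R1", 20.0, 5.0, {"E": 10, "L1": 10, "dead": 20})])
        series = f.proportion_entered(obs, "L1", 20.0)
        assert series.proportions.tolist() == [0.5]

    def test_no_live_individuals_raises_with_temperature(self):
        obs = make_obs([("R1", 32.5, 5.0, {"dead": 20})])
        with pytest.raises(f.TransitionError, match="32.5"):
            f.proportion_entered(obs, "L1", 32.5)

    def test_noiseless_cohort_is_step_function(self, linear_truth):
        hatch = linear_truth.expected_event_times_h(20.0)["E-L1"]
        times = [hatch * k for k in (0.5, 0.8, 0.95, 1.001, 1.05)]
        design = f.DesignConfig(temperatures=[(20.0, 20.0)],
                                schedule={(20.0, "E-L1"): times},
                                temperature_jitter_c=0.0)
        obs = f.simulate_cohort(linear_truth, design)
        series = f.proportion_entered(obs, "L1", 20.0)
        assert series.proportions.tolist() == [0.0, 0.0, 0.0, 1.0, 1.0]


class TestFitTransition:
    def test_noiseless_self_fit_recovers_center(self):
        curve = f.fit_transition(cumulative_series(mu=100.0, sigma=10.0))
        assert curve.params["mu"] == pytest.approx(100.0, abs=1e-6)
        assert curve.params["sigma"] == pytest.approx(10.0, abs=1e-6)

    def test_time_reversal_symmetry(self):
        base = cumulative_series(mu=100.0, sigma=10.0)
        mirrored = f.ProportionSeries(
            stage=base.stage, temperature=base.temperature,
            times_h=(300.0 - base.times_h)[::-1],
            proportions=(1.0 - base.proportions)[::-1],
            n_total=base.n_total)
        curve = f.fit_transition(mirrored)
        assert curve.params["mu"] == pytest.approx(300.0 - 100.0, abs=1e-6)

    def test_self_consistency_refit_of_predicted_points(self):
        curve = f.fit_transition(cumulative_series(mu=80.0, sigma=7.0))
        t = curve.included_times_h
        series2 = f.ProportionSeries(stage="L1", temperature=20.0, times_h=t,
                                     proportions=curve(t), n_total=np.full(len(t), 100))
        curve2 = f.fit_transition(series2)
        for key in curve.params:
            assert curve2.params[key] == pytest.approx(curve.params[key], abs=1e-7)

    def test_degenerate_series_rejected(self):
        t = np.linspace(0, 10, 6)
        flat = f.ProportionSeries(stage="L1", temperature=20.0, times_h=t,
                                  proportions=np.zeros(6), n_total=np.full(6, 10))
        with pytest.raises(f.TransitionError, match="degenerate"):
            f.fit_transition(flat)

    def test_incomplete_transition_rejected(self):
        """A half-observed limb would extrapolate its midpoint: refuse to fit."""
        series = cumulative_series(mu=100.0, sigma=10.0,
                                   times=np.linspace(60, 100, 9))  # reaches only 0.5
        with pytest.raises(f.TransitionError, match="not completed"):
            f.fit_transition(series)

    def test_monte_carlo_center_recovery(self, default_truth):
        """Binomial sampling at n=80/time: mean recovered center within 3 SE of truth."""
        rng = np.random.default_rng(5)
        mu, cv = 200.0, 0.08
        sigma = cv * mu
        t = np.linspace(mu - 4 * sigma, mu + 4 * sigma, 9)
        truth_p = ndtr((t - mu) / sigma)
        estimates = []
        for _ in range(200):
            y = rng.binomial(80, truth_p) / 80.0
            series = f.ProportionSeries(stage="L1", temperature=20.0, times_h=t,
                                        proportions=y, n_total=np.full(len(t), 80))
            try:
                estimates.append(f.fit_transition(series).params["mu"])
            except f.TransitionError:
                continue
        estimates = np.array(estimates)
        assert len(estimates) > 180
        se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - mu) < 3 * se


class TestT50:
    def test_cumulative_midpoint_is_center(self):
        curve = f.fit_transition(cumulative_series(mu=100.0, sigma=10.0))
        point = f.t50(curve)
        assert point.t50_h == pytest.approx(100.0, abs=1e-6)

    def test_peak_family_narrow_width_limit(self):
        """As sigma -> 0 the rising-limb midpoint of a peak tends to its center."""
        for sigma in (5.0, 0.5, 0.01):
            curve = TransitionCurve(
                family="gaussian_peak", params={"a": 1.0, "mu": 50.0, "sigma": sigma},
                cov=np.zeros((3, 3)), fit_r2=1.0, aicc=0.0,
                included_times_h=np.array([0.0, 100.0]), stage="L1", temperature=20.0)
            assert f.t50(curve).t50_h == pytest.approx(50.0, abs=3 * sigma)

    def test_numeric_solution_matches_analytic_half_width(self):
        """Brute-force root of the fitted peak equals mu - sigma*sqrt(2 ln 2)."""
        a, mu, sigma, y0 = 0.9, 120.0, 15.0, 0.05
        curve = TransitionCurve(
            family="gaussian_peak_baseline",
            params={"a": a, "mu": mu, "sigma": sigma, "y0": y0},
            cov=np.zeros((4, 4)), fit_r2=1.0, aicc=0.0,
            included_times_h=np.array([0.0, 200.0]), stage="L1", temperature=20.0)
        analytic = mu - sigma * math.sqrt(2 * math.log(2))
        assert f.t50(curve).t50_h == pytest.approx(analytic, abs=1e-9)

    def test_t50_outside_sampled_window_rejected(self):
        curve = f.fit_transition(cumulative_series(mu=100.0, sigma=10.0))
        curve.included_times_h = np.array([150.0, 200.0])
        with pytest.raises(f.TransitionError, match="outside"):
            f.t50(curve)

    def test_probit_cross_check_agrees_with_gaussian(self):
        rng = np.random.default_rng(2)
        t = np.linspace(60, 140, 17)
        y = rng.binomial(80, ndtr((t - 100.0) / 10.0)) / 80.0
        series = f.ProportionSeries(stage="L1", temperature=20.0, times_h=t,
                                    proportions=y, n_total=np.full(len(t), 80))
        gaussian = f.t50(f.fit_transition(series)).t50_h
        probit = f.probit_t50(series)
        assert probit == pytest.approx(gaussian, rel=0.02)


class TestRisingLimb:
    def test_truncates_after_first_high_local_maximum(self):
        t = np.arange(8.0)
        y = np.array([0.0, 0.1, 0.5, 0.96, 0.94, 0.99, 0.97, 0.95])
        series = f.ProportionSeries(stage="L1", temperature=20.0, times_h=t,
                                    proportions=y, n_total=np.full(8, 10))
        limb = rising_limb(series)
        assert limb.times_h.tolist() == [0.0, 1.0, 2.0, 3.0]


class TestFlagOutliers:
    def test_homogeneous_cohort_has_empty_log(self, default_obs):
        _, log = f.flag_outliers(default_obs, k=3.0)
        assert log.empty

    def test_infinite_k_never_excludes(self, default_obs):
        filtered, log = f.flag_outliers(default_obs, k=math.inf)
        assert log.empty
        assert filtered.frame.equals(default_obs.frame)

    def test_extended_individual_flagged(self):
        # cohort hatches tightly around 10 h; one individual still an egg at 50 h
        rows = [("R1", 20.0, t, {"E": 20}) for t in (2.0, 6.0)]
        rows += [("R1", 20.0, t, {"E": 2, "L1": 18}) for t in (9.0, 10.0)]
        rows += [("R1", 20.0, t, {"L1": 20}) for t in (11.0, 14.0)]
        rows += [("R1", 20.0, 50.0, {"E": 1, "L1": 19})]
        obs = make_obs(rows)
        filtered, log = f.flag_outliers(obs, k=3.0)
        assert len(log) == 1
        assert log.iloc[0]["stage"] == "E"
        assert log.iloc[0]["n_excluded"] == 1
        late = filtered.frame[filtered.frame.sample_time_h == 50.0]
        assert (late.count_E == 0).all()


class TestInvariants:
    def test_monotone_staging_t50_nondecreasing_in_event_order(self, default_points):
        from flydev.reference import EVENTS
        for _, sub in default_points.groupby("temp_nominal_c"):
            t50s = sub.set_index("stage")["t50_h"]
            present = [e for e in EVENTS if e in t50s.index]
            vals = t50s[present].to_numpy()
            assert np.all(np.diff(vals) >= 0)

    def test_temperature_monotonicity_on_noiseless_linear_truth(self):
        """Measurement-noiseless cohort (large n, no mortality or chamber jitter):
        every event's t50 falls strictly with temperature on linear truth."""
        truth = f.SimulationTruth(cv_transition=0.05, curvature_low=1.0,
                                  curvature_high=1.0, mortality={}, seed=4)
        design = f.schedule_from_truth(truth, horizon_days=45.0,
                                       n_individuals=2000, n_replicates=1)
        design.temperature_jitter_c = 0.0
        obs = f.simulate_cohort(truth, design)
        points, _ = f.transition_points(obs)
        assert len(points)
        for _, sub in points.groupby("stage"):
            t50s = sub.sort_values("temp_nominal_c")["t50_h"].to_numpy()
            assert np.all(np.diff(t50s) < 0)
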