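"""Induction- and growth-lag estimators: examples, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trace
from lagkit import SimScenario, generate_cell_traces
from lagkit.single_cell import (LagEstimationError, analyze_traces,
                                build_growth_series, estimate_growth_lag,
                                estimate_induction_lag, fit_cell_cycle_growth,
                                profile_loglik_growth_lag, summarize_lags)
from lagkit.types import LagRecord, TraceSet

LN2 = np.log(2.0)


def single_cell_set(times, lengths, fluor):
    return TraceSet([make_trace(times, lengths, fluor)])


class TestInductionLag:
    def test_flat_trace_is_non_induced(self):
        t = np.arange(0, 240, 3.0)
        rng = np.random.default_rng(0)
        ts = single_cell_set(t, np.exp(0.01 * t), rng.normal(0, 5, len(t)))
        rec = estimate_induction_lag(ts, "c1", switch_time=0.0)
        assert rec.induction_status == "non_induced"
        assert rec.induction_lag is None

    def test_noiseless_ramp_reports_first_sampled_crossing(self):
        # flat at 0 until 75 min post-switch, then +30 molecules/min:
        # +200 is reached at 81.67 min, first sampled crossing at 84 min
        t = np.arange(0, 123, 3.0)
        fluor = 30.0 * np.clip(t - 75.0, 0, None)
        ts = single_cell_set(t, np.exp(0.01 * t), fluor)
        rec = estimate_induction_lag(ts, "c1", switch_time=0.0)
        assert rec.induction_status == "measured"
        assert rec.induction_lag == pytest.approx(84.0)

    def test_requires_four_post_switch_points(self):
        t = np.arange(0, 12, 3.0)
        ts = single_cell_set(t, np.ones(len(t)), np.zeros(len(t)))
        with pytest.raises(LagEstimationError):
            estimate_induction_lag(ts, "c1", switch_time=3.0)

    def test_daughter_sum_crosses_threshold_after_division(self):
        # mother divides at t=30; each daughter carries half the signal, so
        # only the summed pair crosses the threshold
        t_m = np.arange(0.0, 33.0, 3.0)
        mother = make_trace(t_m, np.exp(0.01 * t_m), np.zeros(len(t_m)),
                            cell_id="m", divides_at_end=True)
        t_d = np.arange(33.0, 90.0, 3.0)
        ramp = 15.0 * np.clip(t_d - 45.0, 0, None)   # each daughter: half rate
        d1 = make_trace(t_d, np.exp(0.01 * t_d) / 2, ramp, cell_id="d1",
                        parent="m")
        d2 = make_trace(t_d, np.exp(0.01 * t_d) / 2, ramp, cell_id="d2",
                        parent="m")
        ts = TraceSet([mother, d1, d2])
        rec = estimate_induction_lag(ts, "m", switch_time=0.0)
        assert rec.induction_status == "measured"
        # summed ramp 30/min from t=45: +200 at 51.67, sampled at 54
        assert rec.induction_lag == pytest.approx(54.0)

    def test_lost_daughter_censors_as_washed_out(self):
        t_m = np.arange(0.0, 33.0, 3.0)
        mother = make_trace(t_m, np.exp(0.01 * t_m), np.zeros(len(t_m)),
                            cell_id="m", divides_at_end=True)
        t_d = np.arange(33.0, 90.0, 3.0)
        d1 = make_trace(t_d, np.exp(0.01 * t_d) / 2, np.zeros(len(t_d)),
                        cell_id="d1", parent="m")
        t_short = np.arange(33.0, 48.0, 3.0)   # leaves the channel early
        d2 = make_trace(t_short, np.exp(0.01 * t_short) / 2,
                        np.zeros(len(t_short)), cell_id="d2", parent="m")
        ts = TraceSet([mother, d1, d2])
        rec = estimate_induction_lag(ts, "m", switch_time=0.0)
        assert rec.induction_status == "washed_out"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 240, 3.0)
        fluor = 25.0 * np.clip(t - 60.0, 0, None) + rng.normal(0, 20, len(t))
        ts = single_cell_set(t, np.exp(0.005 * t), fluor)
        lags = []
        for thr in (100.0, 200.0, 400.0, 800.0):
            rec = estimate_induction_lag(ts, "c1", 0.0, threshold=thr)
            lags.append(rec.induction_lag)
        assert all(a <= b for a, b in zip(lags, lags[1:]))

    def test_cohort_recovery_against_ground_truth(self, default_scenario,
                                                  cohort_lags):
        sc = default_scenario
        meas = cohort_lags[cohort_lags["induction_status"] == "measured"]
        assert len(meas) / len(cohort_lags) >= 0.9
        dt = sc.sampling_interval
        crossing = meas["true_lag"] + 200.0 / sc.induction_rate
        sampled_crossing = np.ceil(crossing / dt) * dt
        frac = (np.abs(meas["induction_lag"] - sampled_crossing)
                <= dt + 1e-9).mean()
        assert frac >= 0.95


class TestGrowthSeries:
    def test_single_cell_series_is_log_of_length(self):
        t = np.arange(0, 60, 3.0)
        lengths = np.exp(0.005 * t)
        ts = single_cell_set(t, lengths, np.zeros(len(t)))
        series, status = build_growth_series(ts, "c1", switch_time=0.0)
        np.testing.assert_allclose(series.length, lengths)
        assert status == "window_end"

    def test_series_truncates_at_tripling(self):
        t = np.arange(0, 300, 3.0)
        lengths = np.exp((LN2 / 50) * t)   # triples at t = 50*log2(3) = 79.2
        ts = single_cell_set(t, lengths, np.zeros(len(t)))
        series, status = build_growth_series(ts, "c1", switch_time=0.0)
        assert status == "tripled"
        assert series.length[-1] >= 3.0 > series.length[-2]

    def test_error_when_trace_ends_before_switch(self):
        t = np.arange(0, 30, 3.0)
        ts = single_cell_set(t, np.ones(len(t)), np.zeros(len(t)))
        with pytest.raises(LagEstimationError):
            build_growth_series(ts, "c1", switch_time=100.0)


def hinge_loglength(t, tau, lam, L0=0.0):
    return L0 + lam * np.clip(t - tau, 0.0, None)


class TestGrowthLagProfile:
    def test_noiseless_kink_recovered_exactly(self):
        t = np.arange(0, 120, 3.0)
        L = hinge_loglength(t, 60.0, LN2 / 58)
        grid = np.arange(0.0, 115.0, 1.0)
        grid, prof = profile_loglik_growth_lag(L, t, grid)
        assert grid[np.argmax(prof)] == pytest.approx(60.0)

    def test_pure_linear_growth_maximised_at_lower_boundary(self):
        t = np.arange(0, 120, 3.0)
        L = 0.5 + 0.01 * t
        grid = np.arange(0.0, 115.0, 1.0)
        grid, prof = profile_loglik_growth_lag(L, t, grid)
        assert grid[np.argmax(prof)] == 0.0

    def test_laplace_profile_matches_numerical_marginalisation(self):
        # exact p(D|tau): integrate Var[L - lam*Ramp]^((1-T)/2) over lam
        # numerically (uniform prior on the intercept and growth rate,
        # Jeffreys prior on the noise scale, as in the profile derivation)
        rng = np.random.default_rng(7)
        t = np.arange(0, 30, 3.0)            # T = 10
        for trial in range(12):
            tau0 = rng.uniform(3, 21)
            lam0 = rng.uniform(0.005, 0.02)
            L = hinge_loglength(t, tau0, lam0) + rng.normal(0, 0.01, len(t))
            grid = np.arange(0.0, t[-1] - 6.0 + 0.5, 1.0)
            T = len(t)

            def exact_log_marginal(tau):
                ramp = np.clip(t - tau, 0.0, None)
                lam_grid = np.linspace(-0.2, 0.2, 4001)
                resid = L[None, :] - lam_grid[:, None] * ramp[None, :]
                var = resid.var(axis=1)
                logf = (1.0 - T) / 2.0 * np.log(var)
                m = logf.max()
                return m + np.log(np.trapezoid(np.exp(logf - m), lam_grid))

            exact = np.array([exact_log_marginal(tau) for tau in grid])
            g2, prof = profile_loglik_growth_lag(L, t, grid)
            tau_exact = grid[np.argmax(exact)]
            tau_laplace = g2[np.argmax(prof)]
            assert abs(tau_exact - tau_laplace) <= 1.0

    @given(shift=st.floats(-2.0, 2.0), scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_profile_invariant_to_offset_and_length_rescaling(self, shift, scale):
        rng = np.random.default_rng(3)
        t = np.arange(0, 90, 3.0)
        L = hinge_loglength(t, 40.0, 0.012) + rng.normal(0, 0.01, len(t))
        grid = np.arange(0.0, 85.0, 1.0)
        _, p0 = profile_loglik_growth_lag(L, t, grid)
        _, p1 = profile_loglik_growth_lag(L + shift + np.log(scale), t, grid)
        assert np.argmax(p0) == np.argmax(p1)
        np.testing.assert_allclose(p0, p1, rtol=1e-8, atol=1e-8)


class TestGrowthLagFit:
    def test_noiseless_arrest_fit_is_exact(self):
        t = np.arange(0, 120, 3.0)           # 40 points at 3-min spacing
        lengths = np.exp(hinge_loglength(t, 60.0, LN2 / 58, L0=0.2))
        ts = single_cell_set(t, lengths, np.zeros(len(t)))
        fit, rec = estimate_growth_lag(ts, "c1", switch_time=0.0)
        assert fit.tau_star == pytest.approx(60.0)
        assert fit.lambda_star == pytest.approx(LN2 / 58, rel=1e-9)
        assert fit.sigma2_star == pytest.approx(0.0, abs=1e-18)
        assert fit.L0_star == pytest.approx(0.2, abs=1e-9)

    def test_cohort_recovery_median_error(self, cohort_lags):
        gm = cohort_lags[cohort_lags["growth_status"] == "measured"]
        assert len(gm) >= 150
        err = (gm["growth_lag"] - gm["true_lag"]).abs()
        assert err.median() <= 3.0

    def test_induction_growth_lags_tightly_correlated(self, cohort_lags):
        both = cohort_lags[(cohort_lags["induction_status"] == "measured")
                           & (cohort_lags["growth_status"] == "measured")]
        r2 = np.corrcoef(both["induction_lag"], both["growth_lag"])[0, 1] ** 2
        assert r2 >= 0.9


class TestCellCycleGrowth:
    def test_exact_exponential(self):
        t = np.arange(0, 60, 3.0)
        tr = make_trace(t, 1.3 * np.exp(0.012 * t), np.zeros(len(t)))
        slope, r, l0 = fit_cell_cycle_growth(tr)
        assert slope == pytest.approx(0.012, rel=1e-9)
        assert r == pytest.approx(1.0)
        assert l0 == pytest.approx(1.3, rel=1e-9)

    def test_ols_slope_unbiased_under_noise(self):
        rng = np.random.default_rng(12)
        t = np.arange(0, 60, 3.0)
        slopes = []
        for _ in range(1000):
            lengths = np.exp(0.012 * t + rng.normal(0, 0.02, len(t)))
            tr = make_trace(t, lengths, np.zeros(len(t)))
            slopes.append(fit_cell_cycle_growth(tr)[0])
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.012) <= 2 * se

    def test_constant_length_flagged_degenerate(self):
        t = np.arange(0, 30, 3.0)
        tr = make_trace(t, np.full(len(t), 2.0), np.zeros(len(t)))
        slope, r, _ = fit_cell_cycle_growth(tr)
        assert slope == 0.0
        assert np.isnan(r)

    def test_too_few_points_rejected(self):
        t = np.array([0.0, 3.0])
        tr = make_trace(t, np.ones(2), np.zeros(2))
        with pytest.raises(LagEstimationError):
            fit_cell_cycle_growth(tr)


class TestSummarise:
    def test_all_short_lags(self):
        recs = [LagRecord(cell_id=str(i), induction_lag=10.0) for i in range(5)]
        out = summarize_lags(recs, threshold=50.0)
        assert out["fraction_short"] == 1.0

    def test_fraction_short_is_cdf_below_threshold_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        lags = rng.uniform(0, 200, 101)
        recs = [LagRecord(cell_id=str(i), induction_lag=v)
                for i, v in enumerate(lags)]
        out = summarize_lags(recs, threshold=50.0)
        assert out["fraction_short"] == pytest.approx(np.mean(lags < 50.0))
        rng.shuffle(lags)
        recs2 = [LagRecord(cell_id=str(i), induction_lag=v)
                 for i, v in enumerate(lags)]
        assert summarize_lags(recs2, 50.0)["fraction_short"] \
            == out["fraction_short"]

    def test_synthetic_cohort_fraction_short(self):
        sc = SimScenario(fraction_nonzero_basal=0.4, seed=21)
        traces, truth = generate_cell_traces(sc, 300)
        table = analyze_traces(traces, sc.switch_time,
                               focal_ids=truth["focal_cell_id"].tolist())
        meas = table[table["induction_status"] == "measured"]
        frac = (meas["induction_lag"] < 50.0).mean()
        se = np.sqrt(0.4 * 0.6 / len(meas))
        assert abs(frac - 0.4) <= 2 * se + 0.02

    def test_no_measured_lags_is_an_error(self):
        recs = [LagRecord(cell_id="a", induction_lag=None,
                          induction_status="washed_out")]
        with pytest.raises(LagEstimationError):
            summarize_lags(recs)
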