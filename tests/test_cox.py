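import math

import numpy as np
import pandas as pd
import pytest

import dynamark as dm
from dynamark.cox import CoxError, informative_pair_counts

from conftest import make_paired_cohort

LOG3 = math.log(3.0)


def unstratified_cohort(times, events, treatment):
    frame = pd.DataFrame(
        {
            "id": np.arange(len(times)),
            "treatment": treatment,
            "time": times,
            "event": events,
        }
    )
    return dm.CohortTable(frame)


class TestMarginalCox:
    def test_symmetric_arms_give_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        cohort = unstratified_cohort(times, [1] * 6, [1, 1, 1, 0, 0, 0])
        fit = dm.fit_cox_marginal(cohort)
        assert fit.converged
        assert abs(fit.log_hr) < 1e-6

    def test_consistency_on_exponential_cohort(self):
        # control ~ Exp(1), treated ~ Exp(2): true log-HR = log 2
        gen = np.random.default_rng(31)
        n = 100_000
        z = np.repeat([1, 0], n // 2)
        t = np.where(z == 1, gen.exponential(0.5, n), gen.exponential(1.0, n))
        fit = dm.fit_cox_marginal(unstratified_cohort(t, np.ones(n, int), z))
        assert fit.log_hr == pytest.approx(math.log(2), abs=0.02)

    def test_complete_arm_separation_flagged(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        cohort = unstratified_cohort(times, [1] * 6, [1, 1, 1, 0, 0, 0])
        fit = dm.fit_cox_marginal(cohort)
        assert not fit.converged

    def test_no_events_rejected(self):
        cohort = unstratified_cohort([1.0, 2.0], [0, 0], [1, 0])
        with pytest.raises(CoxError):
            dm.fit_cox_marginal(cohort)

    def test_agrees_with_lifelines_oracle(self):
        from lifelines import CoxPHFitter

        config = dm.ScenarioConfig(n=800, seed=77, censor_rate=0.004)
        frame = dm.simulate_cohort(config, 0).data
        fit = dm.fit_cox_marginal(dm.CohortTable(
            frame[["id", "treatment", "time", "event"]]))
        fitter = CoxPHFitter()
        fitter.fit(frame[["time", "event", "treatment"]],
                   duration_col="time", event_col="event")
        assert fit.log_hr == pytest.approx(fitter.params_["treatment"], abs=1e-5)
        assert fit.se == pytest.approx(fitter.standard_errors_["treatment"], abs=1e-5)

    def test_time_origin_and_scale_invariance(self):
        gen = np.random.default_rng(13)
        t = gen.exponential(1.0, 400) + 5.0
        z = np.tile([1, 0], 200)
        e = gen.random(400) < 0.8
        base = dm.fit_cox_marginal(unstratified_cohort(t, e.astype(int), z))
        shifted = dm.fit_cox_marginal(unstratified_cohort(t - 4.5, e.astype(int), z))
        scaled = dm.fit_cox_marginal(unstratified_cohort(3.7 * t, e.astype(int), z))
        assert abs(base.log_hr - shifted.log_hr) < 1e-12
        assert abs(base.se - shifted.se) < 1e-12
        assert abs(base.log_hr - scaled.log_hr) < 1e-12


class TestPairStratifiedCox:
    def test_closed_form_six_three(self):
        # 6 pairs treated-fails-first, 3 control-fails-first: log(6/3), sqrt(9/18)
        tt = np.array([1, 1, 1, 1, 1, 1, 5, 5, 5], dtype=float)
        tc = np.array([2, 2, 2, 2, 2, 2, 1, 1, 1], dtype=float)
        cohort = make_paired_cohort(tt, np.ones(9), tc, np.ones(9))
        fit = dm.fit_cox_pair_stratified(cohort)
        assert fit.converged
        assert fit.log_hr == pytest.approx(math.log(2), abs=1e-8)
        assert fit.se == pytest.approx(math.sqrt(9 / 18), abs=1e-8)
        assert fit.informative_strata == 9

    def test_balanced_counts_give_zero(self):
        tt = np.array([1, 1, 1, 1, 1, 4, 4, 4, 4, 4], dtype=float)
        tc = np.array([2, 2, 2, 2, 2, 1, 1, 1, 1, 1], dtype=float)
        cohort = make_paired_cohort(tt, np.ones(10), tc, np.ones(10))
        fit = dm.fit_cox_pair_stratified(cohort)
        assert fit.log_hr == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_counts_flagged_divergent(self):
        tt = np.full(6, 1.0)
        tc = np.full(6, 2.0)
        cohort = make_paired_cohort(tt, np.ones(6), tc, np.zeros(6))
        fit = dm.fit_cox_pair_stratified(cohort)
        assert not fit.converged

    def test_no_informative_pairs_rejected(self):
        # every pair's earlier time is a censoring
        cohort = make_paired_cohort(
            np.array([1.0, 1.0]), np.zeros(2), np.array([2.0, 2.0]), np.ones(2)
        )
        with pytest.raises(CoxError):
            dm.fit_cox_pair_stratified(cohort)

    def test_newton_equals_closed_form_on_censored_pairs(self):
        gen = np.random.default_rng(3)
        k = 40
        tt = gen.exponential(0.7, k)
        tc = gen.exponential(1.0, k)
        et = gen.random(k) < 0.8
        ec = gen.random(k) < 0.8
        cohort = make_paired_cohort(tt, et, tc, ec)
        a, b = informative_pair_counts(cohort)
        fit = dm.fit_cox_pair_stratified(cohort)
        assert fit.log_hr == pytest.approx(math.log(a / b), abs=1e-8)
        assert fit.se == pytest.approx(math.sqrt((a + b) / (a * b)), abs=1e-8)

    def test_agrees_with_lifelines_strata_oracle(self):
        from lifelines import CoxPHFitter

        gen = np.random.default_rng(8)
        k = 60
        cohort = make_paired_cohort(
            gen.exponential(0.7, k), gen.random(k) < 0.9,
            gen.exponential(1.0, k), gen.random(k) < 0.9,
        )
        fit = dm.fit_cox_pair_stratified(cohort)
        frame = cohort.data[["time", "event", "treatment", "stratum"]]
        fitter = CoxPHFitter()
        fitter.fit(frame, duration_col="time", event_col="event", strata=["stratum"])
        assert fit.log_hr == pytest.approx(fitter.params_["treatment"], abs=1e-4)

    def test_time_origin_invariance(self):
        gen = np.random.default_rng(9)
        k = 30
        tt, tc = gen.exponential(1.0, k) + 2, gen.exponential(1.0, k) + 2
        cohort = make_paired_cohort(tt, np.ones(k), tc, np.ones(k))
        base = dm.fit_cox_pair_stratified(cohort)
        shifted_frame = cohort.data.copy()
        shifted_frame["time"] = shifted_frame["time"] - 1.9
        shifted = dm.fit_cox_pair_stratified(
            dm.CohortTable(shifted_frame, cohort.covariates))
        assert abs(base.log_hr - shifted.log_hr) < 1e-12
        assert abs(base.se - shifted.se) < 1e-12

    def test_singleton_strata_contribute_nothing(self):
        gen = np.random.default_rng(10)
        k = 10
        cohort = make_paired_cohort(
            gen.exponential(1.0, k), np.ones(k), gen.exponential(1.0, k), np.ones(k)
        )
        # delete one member of pair 3 -> singleton stratum
        frame = cohort.data[~((cohort.data["stratum"] == 3) & (cohort.data["treatment"] == 0))]
        with_singleton = dm.fit_cox_pair_stratified(dm.CohortTable(frame, cohort.covariates))
        # oracle: drop pair 3 entirely
        frame2 = cohort.data[cohort.data["stratum"] != 3]
        without_pair = dm.fit_cox_pair_stratified(dm.CohortTable(frame2, cohort.covariates))
        assert with_singleton.log_hr == pytest.approx(without_pair.log_hr, abs=1e-12)


class TestBuiltinSelectionAttenuation:
    def test_matched_stratified_estimate_attenuated_from_conditional(self):
        # omitted prognostic factor: the pair-stratified estimate on the
        # matched cohort lies strictly between 0 and the conditional beta_z
        config = dm.ScenarioConfig(seed=41, alpha_u=0.0, beta_u=LOG3, beta_z=LOG3)
        estimates = []
        for rep in range(20):
            cohort = dm.simulate_cohort(config, rep)
            fit = dm.fit_logistic_ps(cohort, ["X"])
            match = dm.greedy_caliper_match(
                fit.propensity, cohort.data["treatment"].to_numpy(),
                subject_ids=cohort.data["id"].to_numpy(), rng=rep,
            )
            matched = dm.matched_cohort(cohort, match)
            estimates.append(dm.fit_cox_pair_stratified(matched).log_hr)
        mean = np.mean(estimates)
        assert 0.0 < mean < LOG3
        assert np.mean(np.array(estimates) < LOG3) >= 0.95
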