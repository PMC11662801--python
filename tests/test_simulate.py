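import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import dynamark as dm

LOG3 = math.log(3.0)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSampleCovariates:
    def test_marginals_standard_normal(self):
        x, u = dm.sample_covariates(100_000, 0.6, rng(1))
        assert stats.kstest(x, "norm").pvalue > 0.001
        assert stats.kstest(u, "norm").pvalue > 0.001

    @pytest.mark.parametrize("rho", [0.0, 0.6])
    def test_empirical_correlation(self, rho):
        x, u = dm.sample_covariates(100_000, rho, rng(2))
        assert abs(np.corrcoef(x, u)[0, 1] - rho) < 0.02

    def test_perfect_correlation_degenerates(self):
        x, u = dm.sample_covariates(100, 1.0, rng(3))
        np.testing.assert_allclose(u, x, atol=1e-12)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            dm.sample_covariates(10, 1.5, rng(0))


class TestSampleTreatment:
    def test_null_model_gives_half(self):
        x, u = dm.sample_covariates(100_000, 0.0, rng(4))
        z = dm.sample_treatment(x, u, 0.0, 0.0, 0.0, rng(5))
        assert abs(z.mean() - 0.5) < 0.01

    def test_extreme_intercept_empties_treated_arm(self):
        x, u = dm.sample_covariates(50_000, 0.0, rng(6))
        z = dm.sample_treatment(x, u, -9.0, 0.0, 0.0, rng(7))
        assert z.mean() < 0.005

    def test_treated_prevalence_matches_quadrature_oracle(self):
        # independent oracle: Gauss-Hermite integration of
        # expit(alpha0 + alpha_x * z) against the standard normal
        nodes, weights = np.polynomial.hermite_e.hermegauss(80)
        expected = float(np.sum(expit(-1.21 + LOG3 * nodes) * weights) / np.sum(weights))
        x, u = dm.sample_covariates(400_000, 0.0, rng(8))
        z = dm.sample_treatment(x, u, -1.21, LOG3, 0.0, rng(9))
        assert abs(z.mean() - expected) < 0.003

    def test_prevalence_monotone_in_intercept(self):
        x, u = dm.sample_covariates(50_000, 0.0, rng(10))
        fracs = [
            dm.sample_treatment(x, u, a0, LOG3, 0.0, rng(11)).mean()
            for a0 in (-2.0, -1.0, 0.0, 1.0)
        ]
        assert all(np.diff(fracs) > 0)


class TestSampleEventTimes:
    def test_weibull_median_matches_closed_form(self):
        z = np.zeros(100_000)
        t = dm.sample_event_times(z, z, z, 0.0, 0.0, 0.0, 0.01, 1.5, rng(12))
        expected = (math.log(2) / 0.01) ** (1 / 1.5)  # 16.87
        assert abs(np.median(t) - expected) < 0.3

    def test_proportional_hazards_identity(self):
        # a +log 2 shift of the linear predictor squares the survival curve
        n = 200_000
        zeros = np.zeros(n)
        t1 = dm.sample_event_times(zeros, zeros, zeros, 0.0, 0.0, 0.0, 0.01, 1.5, rng(13))
        ones = np.ones(n)
        t2 = dm.sample_event_times(ones, zeros, zeros, math.log(2), 0.0, 0.0, 0.01, 1.5, rng(14))
        grid = np.quantile(t1, [0.2, 0.4, 0.6, 0.8])
        s1 = np.array([(t1 > g).mean() for g in grid])
        s2 = np.array([(t2 > g).mean() for g in grid])
        np.testing.assert_allclose(s2, s1 ** 2, atol=0.01)

    def test_gamma_one_reduces_to_exponential(self):
        z = np.zeros(100_000)
        t = dm.sample_event_times(z, z, z, 0.0, 0.0, 0.0, 0.25, 1.0, rng(15))
        assert stats.kstest(t, "expon", args=(0, 1 / 0.25)).statistic < 0.01

    def test_invalid_weibull_parameters_rejected(self):
        with pytest.raises(ValueError):
            dm.sample_event_times(np.zeros(5), np.zeros(5), np.zeros(5),
                                  0, 0, 0, -1.0, 1.5, rng(0))


class TestApplyCensoring:
    def test_zero_rate_keeps_all_events(self):
        t = rng(16).exponential(1.0, 1000)
        y, delta = dm.apply_censoring(t, 0.0, rng(17))
        np.testing.assert_array_equal(y, t)
        assert delta.all()

    def test_huge_rate_censors_almost_everything(self):
        t = rng(18).exponential(1.0, 10_000)
        _, delta = dm.apply_censoring(t, 1e6, rng(19))
        assert delta.mean() < 0.001

    def test_symmetric_exponentials_censor_half(self):
        t = rng(20).exponential(1.0, 100_000)
        _, delta = dm.apply_censoring(t, 1.0, rng(21))
        assert abs((1 - delta.mean()) - 0.5) < 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            dm.apply_censoring(np.ones(5), -0.1, rng(0))


class TestSimulateCohort:
    def test_shape_and_covariates(self):
        cohort = dm.simulate_cohort(dm.ScenarioConfig(seed=1), rep=0)
        assert cohort.n == 5000
        assert cohort.covariate_names == ("X", "U")

    def test_same_seed_is_deterministic(self):
        config = dm.ScenarioConfig(seed=7, censor_rate=0.01)
        a = dm.simulate_cohort(config, rep=3)
        b = dm.simulate_cohort(config, rep=3)
        assert a.data.equals(b.data)

    def test_replicates_differ(self):
        config = dm.ScenarioConfig(seed=7)
        a = dm.simulate_cohort(config, rep=0)
        b = dm.simulate_cohort(config, rep=1)
        assert not a.data["time"].equals(b.data["time"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            dm.ScenarioConfig(n=5)
        with pytest.raises(ValueError):
            dm.ScenarioConfig(rho_xu=1.2)
        with pytest.raises(ValueError):
            dm.ScenarioConfig(weibull_gamma=0.0)

    @pytest.mark.parametrize(
        "alpha_u,beta_u,role",
        [
            (0.0, 0.0, "independent"),
            (0.0, LOG3, "prognostic"),
            (LOG3, 0.0, "instrument"),
            (LOG3, LOG3, "confounder"),
        ],
    )
    def test_u_role_classification(self, alpha_u, beta_u, role):
        assert dm.ScenarioConfig(alpha_u=alpha_u, beta_u=beta_u).u_role == role


class TestCalibrateCensorRate:
    def test_recovers_symmetric_exponential_rate(self):
        # T ~ Exp(1) when gamma=1, lambda=1, all betas 0: target 50% -> rate 1
        config = dm.ScenarioConfig(
            seed=2, alpha_x=0.0, beta_z=0.0, beta_x=0.0, beta_u=0.0, alpha_u=0.0,
            weibull_lambda=1.0, weibull_gamma=1.0,
        )
        rate = dm.calibrate_censor_rate(config, 0.5)
        assert abs(rate - 1.0) < 0.05

    def test_default_scenario_hits_ten_percent(self):
        config = dm.ScenarioConfig(seed=3)
        rate = dm.calibrate_censor_rate(config, 0.10)
        cohort = dm.simulate_cohort(config.replace(n=50_000, censor_rate=rate), rep=0)
        achieved = 1 - cohort.data["event"].mean()
        assert 0.08 <= achieved <= 0.12

    def test_rate_monotone_in_target(self):
        config = dm.ScenarioConfig(seed=3)
        r10 = dm.calibrate_censor_rate(config, 0.10)
        r80 = dm.calibrate_censor_rate(config, 0.80)
        assert r80 > r10 > 0

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            dm.calibrate_censor_rate(dm.ScenarioConfig(), 1.5)


class TestModelRecovery:
    def test_adjusted_cox_recovers_conditional_effect(self):
        # with no omitted structure, a Cox model in Z and X on the raw
        # cohort is unbiased for beta_z (independent fit via lifelines)
        from lifelines import CoxPHFitter

        config = dm.ScenarioConfig(
            seed=21, alpha_u=0.0, beta_u=0.0, beta_z=LOG3, censor_rate=0.004
        )
        estimates = []
        for rep in range(100):
            frame = dm.simulate_cohort(config, rep).data[
                ["time", "event", "treatment", "X"]
            ]
            fitter = CoxPHFitter()
            fitter.fit(frame, duration_col="time", event_col="event")
            estimates.append(fitter.params_["treatment"])
        mean = np.mean(estimates)
        mc_se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - LOG3) < 3 * mc_se

    def test_no_proportional_hazards_violation_by_construction(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        config = dm.ScenarioConfig(seed=22, alpha_u=0.0, beta_u=0.0, censor_rate=0.004)
        frame = dm.simulate_cohort(config, 0).data[["time", "event", "treatment", "X"]]
        fitter = CoxPHFitter()
        fitter.fit(frame, duration_col="time", event_col="event")
        result = proportional_hazard_test(fitter, frame, time_transform="rank")
        assert (result.summary["p"] > 0.001).all()
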