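import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dynamark as dm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_cohort() -> dm.CohortTable:
    """Six subjects, one continuous and one binary covariate, no strata."""
    frame = pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6],
            "treatment": [1, 1, 1, 0, 0, 0],
            "time": [2.0, 5.0, 7.0, 3.0, 6.0, 9.0],
            "event": [1, 0, 1, 1, 1, 0],
            "age": [60.0, 72.0, 55.0, 64.0, 70.0, 58.0],
            "smoker": [1, 0, 1, 0, 1, 0],
        }
    )
    specs = (
        dm.CovariateSpec("age", "continuous"),
        dm.CovariateSpec("smoker", "binary"),
    )
    return dm.CohortTable(frame, specs)


def make_paired_cohort(times_treated, events_treated, times_control, events_control,
                       u_treated=None, u_control=None) -> dm.CohortTable:
    """1:1 matched cohort from per-pair member outcomes."""
    k = len(times_treated)
    u_treated = u_treated if u_treated is not None else np.zeros(k)
    u_control = u_control if u_control is not None else np.zeros(k)
    frame = pd.DataFrame(
        {
            "id": np.arange(1, 2 * k + 1),
            "treatment": np.tile([1, 0], k),
            "time": np.column_stack([times_treated, times_control]).ravel(),
            "event": np.column_stack([events_treated, events_control]).ravel().astype(int),
            "U": np.column_stack([u_treated, u_control]).ravel(),
            "stratum": np.repeat(np.arange(1, k + 1), 2),
        }
    )
    return dm.CohortTable(frame, (dm.CovariateSpec("U", "continuous"),))


@pytest.fixture(scope="session")
def matched_sim_cohort() -> dm.CohortTable:
    """PS-matched analysis set from one replicate of the default scenario."""
    config = dm.ScenarioConfig(seed=314, censor_rate=0.004)
    cohort = dm.simulate_cohort(config, 0)
    fit = dm.fit_logistic_ps(cohort, ["X"])
    match = dm.greedy_caliper_match(
        fit.propensity,
        cohort.data["treatment"].to_numpy(),
        subject_ids=cohort.data["id"].to_numpy(),
        rng=99,
    )
    return dm.matched_cohort(cohort, match, propensity=fit.propensity)
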