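"""Scenario-level simulation experiments and trajectory summaries.

One scenario = one parameterization of the data-generating process,
analysed replicate by replicate with the full pipeline the method
prescribes: simulate a cohort, estimate the propensity score on the
measured confounder X only (U stays omitted), match 1:1 with the 0.2-SD
caliper, run Dynamic Landmarking on the matched set with the
pair-stratified estimator and U as the omitted covariate, and classify
the resulting trajectories.

Replicate trajectories stop at different sample sizes, so they are
aggregated on a common percent-remaining grid (1% spacing) with linear
interpolation between observed steps and NaN outside each replicate's
observed range.  The default replicate count mirrors the ambient
scenario definition; tests and quick looks scale it down via ``reps``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxError
from .diagnostics import DiagnosisThresholds, classify
from .landmark import LandmarkError, StopRule, run_dynamic_landmarking
from .matching import (
    EstimationError,
    MatchingError,
    fit_logistic_ps,
    greedy_caliper_match,
    matched_cohort,
)
from .simulate import ScenarioConfig, replicate_rng, simulate_cohort

__all__ = [
    "LandmarkSettings",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "grid_frame",
    "plot_trajectories",
    "canonical_scenarios",
    "expected_diagnosis",
]

PCT_GRID = np.arange(100.0, 3.0, -1.0)  # percent of individuals remaining


@dataclass(frozen=True)
class LandmarkSettings:
    """How each matched replicate is landmarked and judged."""

    deletion: float = 0.01
    estimator: str = "pair_stratified"
    stop_rule: StopRule = field(default_factory=StopRule)
    thresholds: DiagnosisThresholds = field(default_factory=DiagnosisThresholds)
    classify: bool = True
    ps_covariates: tuple[str, ...] = ("X",)
    omitted_covariates: tuple[str, ...] = ("U",)


@dataclass(frozen=True)
class ScenarioResult:
    """Replicate-level records plus grid-aggregated trajectory summaries."""

    config: ScenarioConfig
    settings: LandmarkSettings
    replicates: pd.DataFrame
    pct_grid: np.ndarray
    log_hr_mean: np.ndarray
    log_hr_lo: np.ndarray
    log_hr_hi: np.ndarray
    ssq_mean: np.ndarray
    ssq_lo: np.ndarray
    ssq_hi: np.ndarray
    label_tally: dict[str, int]
    n_failed: int

    @property
    def mean_matched_size(self) -> float:
        return float(self.replicates["matched_n"].mean())

    @property
    def majority_label(self) -> str | None:
        if not self.label_tally:
            return None
        return max(self.label_tally.items(), key=lambda kv: kv[1])[0]


def run_replicate(config: ScenarioConfig, settings: LandmarkSettings, rep: int):
    """(matched cohort's trajectory, matched_n) for one replicate dataset."""
    cohort = simulate_cohort(config, rep)
    ps_fit = fit_logistic_ps(cohort, settings.ps_covariates)
    match = greedy_caliper_match(
        ps_fit.propensity,
        cohort.data["treatment"].to_numpy(),
        subject_ids=cohort.data["id"].to_numpy(),
        rng=replicate_rng(config.seed, rep).integers(2 ** 31),
    )
    matched = matched_cohort(cohort, match, propensity=ps_fit.propensity)
    trajectory = run_dynamic_landmarking(
        matched,
        settings.omitted_covariates,
        estimator=settings.estimator,
        deletion=settings.deletion,
        stop_rule=settings.stop_rule,
    )
    return trajectory, matched.n


def _interp_to_grid(trajectory, pct_grid: np.ndarray):
    pct = 100.0 * (1.0 - trajectory.fraction_deleted)  # decreasing
    x = pct[::-1]
    loghr = np.interp(pct_grid, x, trajectory.log_hr[::-1], left=np.nan, right=np.nan)
    ssq = np.interp(pct_grid, x, trajectory.ssq[::-1], left=np.nan, right=np.nan)
    outside = (pct_grid > pct[0]) | (pct_grid < pct[-1])
    loghr[outside] = np.nan
    ssq[outside] = np.nan
    return loghr, ssq


def run_scenario(config: ScenarioConfig,
                 settings: LandmarkSettings | None = None,
                 reps: int | None = None) -> ScenarioResult:
    """Run ``reps`` replicates of the full pipeline and aggregate.

    Replicates whose matching or fitting fails are excluded from the
    aggregates and counted in ``n_failed``.
    """
    settings = settings or LandmarkSettings()
    n_reps = reps if reps is not None else config.reps
    rows = []
    loghr_grid = []
    ssq_grid = []
    tally: Counter = Counter()
    failed = 0
    for rep in range(n_reps):
        try:
            trajectory, matched_n = run_replicate(config, settings, rep)
        except (EstimationError, MatchingError, CoxError, LandmarkError):
            failed += 1
            continue
        step0 = trajectory.steps[0]
        label = None
        if settings.classify and len(trajectory) >= 10:
            label = classify(trajectory, settings.thresholds).label
            tally[label] += 1
        rows.append(
            {
                "rep": rep,
                "matched_n": matched_n,
                "step0_log_hr": step0.fit.log_hr,
                "step0_se": step0.fit.se,
                "step0_ssq": step0.ssq_omitted.ssq,
                "n_steps": len(trajectory),
                "termination": trajectory.termination_reason,
                "label": label,
            }
        )
        lg, sq = _interp_to_grid(trajectory, PCT_GRID)
        loghr_grid.append(lg)
        ssq_grid.append(sq)
    if not rows:
        raise RuntimeError("all replicates failed; nothing to aggregate")
    loghr_grid = np.vstack(loghr_grid)
    ssq_grid = np.vstack(ssq_grid)
    import warnings

    with warnings.catch_warnings():
        # grid points outside every replicate's observed range are all-NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return ScenarioResult(
            config=config,
            settings=settings,
            replicates=pd.DataFrame(rows),
            pct_grid=PCT_GRID.copy(),
            log_hr_mean=np.nanmean(loghr_grid, axis=0),
            log_hr_lo=np.nanquantile(loghr_grid, 0.025, axis=0),
            log_hr_hi=np.nanquantile(loghr_grid, 0.975, axis=0),
            ssq_mean=np.nanmean(ssq_grid, axis=0),
            ssq_lo=np.nanquantile(ssq_grid, 0.025, axis=0),
            ssq_hi=np.nanquantile(ssq_grid, 0.975, axis=0),
            label_tally=dict(tally),
            n_failed=failed,
        )


def run_grid(configs, settings: LandmarkSettings | None = None,
             reps: int | None = None) -> list[ScenarioResult | None]:
    """One ScenarioResult per config; a failing scenario yields None, not an abort."""
    configs = list(configs)
    if not configs:
        raise ValueError("scenario grid must be nonempty")
    results: list[ScenarioResult | None] = []
    for config in configs:
        try:
            results.append(run_scenario(config, settings, reps))
        except RuntimeError:
            results.append(None)
    return results


def grid_frame(results) -> pd.DataFrame:
    """Long-format table of grid-aggregated trajectories, one row per grid point."""
    blocks = []
    for i, res in enumerate(results):
        if res is None:
            continue
        cfg = res.config
        blocks.append(
            pd.DataFrame(
                {
                    "scenario": i,
                    "alpha_u": cfg.alpha_u,
                    "beta_u": cfg.beta_u,
                    "beta_z": cfg.beta_z,
                    "rho_xu": cfg.rho_xu,
                    "censor_rate": cfg.censor_rate,
                    "u_role": cfg.u_role,
                    "pct_remaining": res.pct_grid,
                    "log_hr_mean": res.log_hr_mean,
                    "ssq_mean": res.ssq_mean,
                    "mean_matched_n": res.mean_matched_size,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def plot_trajectories(obj, path, true_log_hr: float | None = None) -> None:
    """Dual-axis trajectory plot: log-HR (left, red) and SSQ (right, blue).

    The x-axis shows the percentage of individuals remaining,
    decreasing from left to right.  ``obj`` may be a single
    LandmarkTrajectory or a ScenarioResult (mean curve with a 95%
    band).
    """
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax2 = ax.twinx()
    if isinstance(obj, ScenarioResult):
        x = obj.pct_grid
        ax.plot(x, obj.log_hr_mean, color="crimson", lw=1.8, label="log(HR)")
        ax.fill_between(x, obj.log_hr_lo, obj.log_hr_hi, color="crimson", alpha=0.15)
        ax2.plot(x, obj.ssq_mean, color="steelblue", lw=1.8, label="SSQ")
        ax2.fill_between(x, obj.ssq_lo, obj.ssq_hi, color="steelblue", alpha=0.15)
    else:
        x = 100.0 * (1.0 - obj.fraction_deleted)
        ax.plot(x, obj.log_hr, color="crimson", lw=1.8, label="log(HR)")
        ax2.plot(x, obj.ssq, color="steelblue", lw=1.8, label="SSQ")
    if true_log_hr is not None:
        ax.axhline(true_log_hr, color="black", ls="--", lw=1.0)
    ax.set_xlabel("% of individuals remaining")
    ax.set_ylabel("log hazard ratio", color="crimson")
    ax2.set_ylabel("sum of squared z-differences", color="steelblue")
    ax.set_xlim(max(x), min(x))  # decreasing left to right
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


STRONG = math.log(3.0)


def canonical_scenarios(seed: int = 20240, n: int = 5000,
                        target_censoring: float | None = 0.10,
                        calibrate: bool = True) -> dict[str, ScenarioConfig]:
    """The four canonical omitted-covariate roles at strong effect sizes.

    U is, in turn: an independent covariate (alpha_u = beta_u = 0), a
    prognostic factor (beta_u = log 3 only), an instrument (alpha_u =
    log 3 only), and a confounder (both log 3); always rho = 0 and
    beta_z = log 3.  When ``calibrate`` is set, each scenario's
    exponential censoring rate is calibrated to the target fraction.
    """
    from .simulate import calibrate_censor_rate

    roles = {
        "independent": dict(alpha_u=0.0, beta_u=0.0),
        "prognostic": dict(alpha_u=0.0, beta_u=STRONG),
        "instrument": dict(alpha_u=STRONG, beta_u=0.0),
        "confounder": dict(alpha_u=STRONG, beta_u=STRONG),
    }
    out = {}
    for name, kw in roles.items():
        cfg = ScenarioConfig(n=n, seed=seed, beta_z=STRONG, rho_xu=0.0,
                             censor_rate=0.0, **kw)
        if calibrate and target_censoring:
            cfg = cfg.replace(
                censor_rate=calibrate_censor_rate(cfg, target_censoring)
            )
        out[name] = cfg
    return out


EXPECTED_LABEL = {
    "independent": "no_bias_indicated",
    "prognostic": "builtin_selection_suspected",
    "instrument": "instrument_omitted",
    "confounder": "confounding_suspected",
}


def expected_diagnosis(u_role: str) -> str:
    """The diagnosis label a correctly working screen should assign to each U role."""
    return EXPECTED_LABEL[u_role]
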