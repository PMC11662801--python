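"""Dynamic Landmarking: sequential deletion, refitting, and balance tracking.

The procedure sorts the analysis set by observation time, fits the
treatment-only Cox model and measures the balance of the omitted
covariates, then repeatedly deletes the earliest M observations
(regardless of event status), moves time zero forward to the follow-up
time of the latest deleted subject, refits, and re-measures balance.
Because high-risk subjects (with respect to omitted prognostic
factors) tend to fail early, the surviving population becomes
progressively lower-risk, and any dependence of the hazard-ratio
estimate on that selection shows up as a systematic drift of the
trajectory — built-in selection bias made visible.

Deleted subjects' matched partners are retained: their strata become
singletons that contribute nothing to the stratified partial
likelihood but still count in balance measurement (``drop_orphans``
removes them instead, as a sensitivity analysis).  Balance at every
step uses the plain two-group z-difference formulas over all remaining
subjects, orphans included.

The time-zero reset is bookkeeping: partial-likelihood estimates
depend on follow-up times only through their ordering, so shifting
changes nothing numerically, but the recorded landmark time carries
the "conditional on survival up to t" interpretation of each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import BalanceError, BalanceReport, balance_between, report_from_records
from .cox import CoxError, CoxFit, _fit_from_pair_counts, _newton_marginal
from .io import CohortTable

__all__ = [
    "LandmarkError",
    "StopRule",
    "LandmarkStep",
    "LandmarkTrajectory",
    "sort_by_followup",
    "delete_earliest",
    "run_dynamic_landmarking",
]


class LandmarkError(ValueError):
    """The landmark procedure's preconditions are violated."""


@dataclass(frozen=True)
class StopRule:
    """When to stop deleting.

    The procedure continues "until the data no longer support a
    converging fit"; these thresholds operationalize that: stop once
    fewer than ``min_subjects`` remain, either arm has fewer than
    ``min_events_per_arm`` events, or (stratified estimator) fewer
    than ``min_informative_strata`` informative pairs remain.
    """

    min_subjects: int = 100
    min_events_per_arm: int = 5
    min_informative_strata: int = 10


@dataclass(frozen=True)
class LandmarkStep:
    """One point of the trajectory: fit plus balance on the remaining set."""

    step_index: int
    landmark_time: float
    n_remaining: int
    events_remaining: int
    fit: CoxFit
    ssq_omitted: BalanceReport
    ssq_included: BalanceReport | None = None

    @property
    def per_covariate_z(self) -> dict[str, float]:
        return {r.name: r.z for r in self.ssq_omitted.records}


@dataclass(frozen=True)
class LandmarkTrajectory:
    """Ordered landmark steps plus the settings that produced them."""

    steps: tuple[LandmarkStep, ...]
    n_initial: int
    deletion_m: int
    estimator: str
    stop_rule: StopRule
    termination_reason: str  # min_size_reached | non_convergence | exhausted

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def fraction_deleted(self) -> np.ndarray:
        return 1.0 - np.array([s.n_remaining for s in self.steps]) / self.n_initial

    @property
    def log_hr(self) -> np.ndarray:
        return np.array([s.fit.log_hr for s in self.steps])

    @property
    def se(self) -> np.ndarray:
        return np.array([s.fit.se for s in self.steps])

    @property
    def ssq(self) -> np.ndarray:
        return np.array([s.ssq_omitted.ssq for s in self.steps])

    def step_nearest_fraction(self, fraction: float) -> int:
        """Index of the step whose deleted fraction is closest to ``fraction``."""
        return int(np.argmin(np.abs(self.fraction_deleted - fraction)))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def sort_by_followup(cohort: CohortTable) -> CohortTable:
    """Ascending follow-up time; ties: events before censorings, then id."""
    frame = cohort.data.sort_values(
        by=["time", "event", "id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return cohort.replace_data(frame)


def delete_earliest(cohort: CohortTable, m: int) -> tuple[CohortTable, float]:
    """Drop the first ``m`` rows of a time-sorted cohort, regardless of status.

    Returns the remaining cohort and the landmark time (the follow-up
    time of the latest deleted subject).  Matched partners of deleted
    subjects are retained; their strata become singletons.
    """
    if m < 1:
        raise LandmarkError("deletion count M must be >= 1")
    if m >= cohort.n:
        raise LandmarkError(f"cannot delete M={m} from a cohort of {cohort.n} subjects")
    landmark_time = float(cohort.data["time"].iloc[m - 1])
    remaining = cohort.replace_data(cohort.data.iloc[m:].copy())
    return remaining, landmark_time


def _resolve_m(deletion, n0: int) -> int:
    if isinstance(deletion, float) and not deletion.is_integer():
        if not 0 < deletion < 1:
            raise LandmarkError("fractional deletion step must lie in (0, 1)")
        return max(1, round(deletion * n0))
    m = int(deletion)
    if isinstance(deletion, float) and deletion == 1.0:
        return n0
    if m < 1:
        raise LandmarkError("absolute deletion step must be >= 1")
    return m


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def run_dynamic_landmarking(
    cohort: CohortTable,
    omitted_covariates,
    *,
    estimator: str = "pair_stratified",
    deletion=0.01,
    stop_rule: StopRule | None = None,
    ci_level: float = 0.95,
    include_balance_for=None,
    drop_orphans: bool = False,
) -> LandmarkTrajectory:
    """Full landmark run: step 0 on the input set, then delete-and-refit.

    ``deletion`` is either an absolute per-step count (int >= 1) or a
    fraction of the initial analysis-set size (float in (0, 1]); the
    default 1% yields roughly a hundred steps.  ``omitted_covariates``
    must name at least one covariate — measuring the balance of an
    omitted covariate is the point of the method.
    """
    omitted = tuple(omitted_covariates)
    if not omitted:
        raise LandmarkError(
            "at least one covariate must be omitted (and named) for balance measurement"
        )
    for name in omitted:
        cohort.spec(name)  # raises KeyError for unknown covariates
    if estimator not in ("marginal", "pair_stratified"):
        raise LandmarkError(f"unknown estimator {estimator!r}")
    if estimator == "pair_stratified" and not cohort.has_strata:
        raise LandmarkError("pair_stratified estimator requires stratum labels")
    rule = stop_rule or StopRule()
    included = tuple(include_balance_for) if include_balance_for else None

    ordered = sort_by_followup(cohort)
    n0 = ordered.n
    m = _resolve_m(deletion, n0)

    df = ordered.data
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=np.int64)
    treat = df["treatment"].to_numpy(dtype=np.int64)
    cov_values = {
        name: df[name].to_numpy() for name in set(omitted) | set(included or ())
    }
    specs = {name: cohort.spec(name) for name in cov_values}

    # complete 1:1 pairs as row positions (treated, control)
    pair_t = pair_c = None
    partner = np.full(n0, -1)
    if cohort.has_strata:
        strat = df["stratum"]
        pos = np.arange(n0)
        pt, pc = [], []
        grouped = pd.Series(pos, index=strat.to_numpy()).groupby(level=0, sort=False, dropna=True)
        for _, members in grouped:
            if len(members) != 2:
                continue
            i, j = members.to_numpy()
            if treat[i] == treat[j]:
                continue  # concordant pairs cannot occur in validated tables
            ti, ci_ = (i, j) if treat[i] == 1 else (j, i)
            pt.append(ti)
            pc.append(ci_)
            partner[i], partner[j] = j, i
        pair_t = np.asarray(pt, dtype=np.int64)
        pair_c = np.asarray(pc, dtype=np.int64)

    alive = np.ones(n0, dtype=bool)
    scan = 0  # all rows before `scan` are deleted
    landmark_time = 0.0
    steps: list[LandmarkStep] = []
    termination = None

    def stratified_fit() -> CoxFit:
        both = alive[pair_t] & alive[pair_c]
        tt, tc = time[pair_t[both]], time[pair_c[both]]
        et = event[pair_t[both]].astype(bool)
        ec = event[pair_c[both]].astype(bool)
        ca = et & (tt <= tc)
        cb = ec & (tc <= tt)
        a, b = int(ca.sum()), int(cb.sum())
        return _fit_from_pair_counts(
            a, b, int((ca | cb).sum()),
            n_used=int(alive.sum()), events_used=int(event[alive].sum()),
            ci_level=ci_level,
        )

    def informative_count() -> int:
        both = alive[pair_t] & alive[pair_c]
        tt, tc = time[pair_t[both]], time[pair_c[both]]
        et = event[pair_t[both]].astype(bool)
        ec = event[pair_c[both]].astype(bool)
        return int(((et & (tt <= tc)) | (ec & (tc <= tt))).sum())

    def balance_of(names) -> BalanceReport:
        t_mask = alive & (treat == 1)
        c_mask = alive & (treat == 0)
        records = [
            balance_between(specs[nm], cov_values[nm][t_mask], cov_values[nm][c_mask])
            for nm in names
        ]
        return report_from_records(records, int(t_mask.sum()), int(c_mask.sum()))

    def compute_step(index: int) -> LandmarkStep:
        if estimator == "pair_stratified":
            fit = stratified_fit()
        else:
            fit = _newton_marginal(
                time[alive] - landmark_time, event[alive], treat[alive],
                ci_level=ci_level,
            )
        return LandmarkStep(
            step_index=index,
            landmark_time=landmark_time,
            n_remaining=int(alive.sum()),
            events_remaining=int(event[alive].sum()),
            fit=fit,
            ssq_omitted=balance_of(omitted),
            ssq_included=balance_of(included) if included else None,
        )

    step0 = compute_step(0)
    steps.append(step0)
    if not step0.fit.converged:
        termination = "non_convergence"

    index = 0
    while termination is None:
        index += 1
        remaining = int(alive.sum())
        if remaining - m < 1:
            termination = "exhausted"
            break
        # delete the earliest m still-present subjects
        deleted = 0
        while deleted < m:
            if alive[scan]:
                alive[scan] = False
                landmark_time = max(landmark_time, time[scan])
                deleted += 1
            scan += 1
        if drop_orphans:
            orphans = np.flatnonzero(~alive[: scan])
            for i in orphans:
                p = partner[i]
                if p >= 0 and alive[p]:
                    alive[p] = False

        # stop-rule checks on the new remaining set
        n_rem = int(alive.sum())
        ev_t = int(event[alive & (treat == 1)].sum())
        ev_c = int(event[alive & (treat == 0)].sum())
        if (
            n_rem < rule.min_subjects
            or ev_t < rule.min_events_per_arm
            or ev_c < rule.min_events_per_arm
            or (estimator == "pair_stratified"
                and informative_count() < rule.min_informative_strata)
        ):
            termination = "min_size_reached"
            break
        try:
            step = compute_step(index)
        except (CoxError, BalanceError):
            termination = "non_convergence"
            break
        steps.append(step)
        if not step.fit.converged:
            termination = "non_convergence"

    return LandmarkTrajectory(
        steps=tuple(steps),
        n_initial=n0,
        deletion_m=m,
        estimator=estimator,
        stop_rule=rule,
        termination_reason=termination,
    )
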