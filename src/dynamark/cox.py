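"""Treatment-only Cox models: marginal and matched-pair-stratified.

Two partial-likelihood fits cover everything the landmark loop needs:

* :func:`fit_cox_marginal` — the univariable Cox model with treatment
  as the single covariate, maximized by Newton iteration on the Breslow
  partial likelihood.  With a binary covariate the likelihood depends
  on the data only through per-event-time risk counts by arm, so the
  solver is a scalar Newton that costs O(n log n) per fit.

* :func:`fit_cox_pair_stratified` — the Cox model stratified on the
  matching stratum, h_j(t|Z) = h_{0j}(t) exp(beta Z), with each 1:1
  pair its own stratum.  For treatment-discordant pairs the stratified
  partial likelihood collapses to a conditional-logistic form

      loglik(beta) = a*beta - (a + b) * log(1 + exp(beta)),

  where ``a`` counts informative pairs whose treated member fails first
  and ``b`` those whose control fails first ("informative": the
  earlier observed time is an event while the partner is still at
  risk).  The Newton solution therefore equals log(a/b) with standard
  error sqrt((a+b)/(a*b)) whenever both counts are positive; ties
  within a pair (probability zero under a continuous event-time model)
  are handled Breslow-style and add one count to each side.

Estimates depend on follow-up times only through their ordering, so
they are invariant to shifting or positively rescaling the time axis —
the property that lets the landmark procedure reset time zero after
each deletion without touching the estimates.

Divergence policy: |beta| > 15 is treated as monotone-likelihood
non-convergence and flagged rather than raised; the landmark loop
consumes the flag as a stopping signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CohortTable

__all__ = [
    "CoxError",
    "CoxFit",
    "fit_cox_marginal",
    "fit_cox_pair_stratified",
    "informative_pair_counts",
]

DIVERGENCE_BOUND = 15.0
NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 100


class CoxError(ValueError):
    """The partial likelihood is undefined for the supplied data."""


@dataclass(frozen=True)
class CoxFit:
    """Result of a treatment-only Cox fit.

    ``log_hr`` is the log hazard ratio for treatment; ``exp(log_hr)``
    is the reported hazard ratio.  ``informative_strata`` is populated
    by the stratified fit only.
    """

    log_hr: float
    se: float
    ci: tuple[float, float]
    n_used: int
    events_used: int
    converged: bool
    iterations: int
    informative_strata: int | None = None

    @property
    def hazard_ratio(self) -> float:
        return math.exp(self.log_hr)


def _wald_ci(beta: float, se: float, level: float) -> tuple[float, float]:
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return (beta - zq * se, beta + zq * se)


# ---------------------------------------------------------------------------
# marginal model
# ---------------------------------------------------------------------------

def _marginal_sufficient_stats(time: np.ndarray, event: np.ndarray, z: np.ndarray):
    """Per-event-time risk counts for the binary-covariate Breslow likelihood.

    Returns (d, d1, n0, n1, D1): event counts per distinct event time,
    treated event counts, at-risk counts by arm, and the total treated
    event count.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    zz = z[order]
    n = t.size
    # suffix sums give at-risk counts at each position
    suffix_z = np.concatenate((np.cumsum(zz[::-1])[::-1], [0.0]))
    distinct, start = np.unique(t, return_index=True)
    # events per distinct time
    csum_e = np.concatenate(([0.0], np.cumsum(e)))
    csum_ez = np.concatenate(([0.0], np.cumsum(e * zz)))
    stop = np.concatenate((start[1:], [n]))
    d = csum_e[stop] - csum_e[start]
    d1 = csum_ez[stop] - csum_ez[start]
    keep = d > 0
    n_at = (n - start)[keep].astype(float)
    n1 = suffix_z[start][keep]
    n0 = n_at - n1
    return d[keep], d1[keep], n0, n1, float((e * zz).sum())


def _newton_marginal(time, event, z, ci_level=0.95) -> CoxFit:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    z = np.asarray(z, dtype=float)
    events_total = int(event.sum())
    if events_total < 1:
        raise CoxError("no events: the partial likelihood is empty")
    if z.min() == z.max():
        raise CoxError("both treatment arms must be present")
    d, d1, n0, n1, D1 = _marginal_sufficient_stats(time, event, z)

    beta = 0.0
    converged = False
    info = np.nan
    it = 0
    for it in range(1, NEWTON_MAX_ITER + 1):
        eb = math.exp(beta)
        denom = n0 + eb * n1
        pi = eb * n1 / denom
        grad = D1 - float(np.dot(d, pi))
        info = float(np.dot(d, pi * (1 - pi)))
        if info <= 0:
            break
        step = grad / info
        beta += step
        if abs(beta) > DIVERGENCE_BOUND:
            break
        if abs(step) <= NEWTON_TOL * (1.0 + abs(beta)):
            converged = True
            break
    se = 1.0 / math.sqrt(info) if (converged and info > 0) else math.nan
    ci = _wald_ci(beta, se, ci_level) if converged else (math.nan, math.nan)
    return CoxFit(
        log_hr=beta,
        se=se,
        ci=ci,
        n_used=int(time.size),
        events_used=events_total,
        converged=converged,
        iterations=it,
    )


def fit_cox_marginal(cohort: CohortTable, ci_level: float = 0.95) -> CoxFit:
    """Univariable Cox model with treatment as the only covariate."""
    df = cohort.data
    return _newton_marginal(
        df["time"].to_numpy(), df["event"].to_numpy(), df["treatment"].to_numpy(),
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# pair-stratified model
# ---------------------------------------------------------------------------

def _pair_arrays(cohort: CohortTable):
    """(t_treated, e_treated, t_control, e_control) over complete strata."""
    df = cohort.data
    if "stratum" not in df.columns:
        raise CoxError("pair-stratified fit requires stratum labels")
    sub = df.loc[df["stratum"].notna()]
    grouped = sub.groupby("stratum", sort=False)
    tt, et, tc, ec = [], [], [], []
    for _, g in grouped:
        if len(g) != 2:
            continue  # singleton stratum: contributes factor 1
        rows = g.sort_values("treatment", ascending=False)
        tt.append(rows["time"].iloc[0])
        et.append(rows["event"].iloc[0])
        tc.append(rows["time"].iloc[1])
        ec.append(rows["event"].iloc[1])
    return (np.asarray(tt, float), np.asarray(et, bool),
            np.asarray(tc, float), np.asarray(ec, bool))


def _pair_counts(tt, et, tc, ec) -> tuple[int, int, int]:
    """(a, b, informative_strata) from per-pair times and event flags.

    An event is informative when the partner is still at risk at that
    time (partner time >= event time); a within-pair tie of two events
    contributes one count to each side (Breslow).
    """
    contrib_a = et & (tt <= tc)
    contrib_b = ec & (tc <= tt)
    a = int(contrib_a.sum())
    b = int(contrib_b.sum())
    return a, b, int((contrib_a | contrib_b).sum())


def _fit_from_pair_counts(a: int, b: int, informative: int,
                          n_used: int, events_used: int,
                          ci_level: float = 0.95) -> CoxFit:
    if a + b == 0:
        raise CoxError("no informative pairs: the stratified partial likelihood is empty")
    beta = 0.0
    converged = False
    it = 0
    info = np.nan
    for it in range(1, NEWTON_MAX_ITER + 1):
        p = 1.0 / (1.0 + math.exp(-beta))
        grad = a - (a + b) * p
        info = (a + b) * p * (1 - p)
        if info <= 0:
            break
        step = grad / info
        beta += step
        if abs(beta) > DIVERGENCE_BOUND:
            break
        if abs(step) <= NEWTON_TOL * (1.0 + abs(beta)):
            converged = True
            break
    se = math.sqrt((a + b) / (a * b)) if (a > 0 and b > 0) else math.nan
    ci = _wald_ci(beta, se, ci_level) if converged else (math.nan, math.nan)
    return CoxFit(
        log_hr=beta,
        se=se,
        ci=ci,
        n_used=n_used,
        events_used=events_used,
        converged=converged,
        iterations=it,
        informative_strata=informative,
    )


def informative_pair_counts(cohort: CohortTable) -> tuple[int, int]:
    """(a, b): informative pairs with the treated / control member failing first."""
    tt, et, tc, ec = _pair_arrays(cohort)
    a, b, _ = _pair_counts(tt, et, tc, ec)
    return a, b


def fit_cox_pair_stratified(cohort: CohortTable, ci_level: float = 0.95) -> CoxFit:
    """Cox model stratified on 1:1 matching strata, treatment-only.

    Singleton strata (matched partners removed by landmark deletion)
    contribute a factor of one and are silently skipped; uninformative
    complete pairs likewise.
    """
    tt, et, tc, ec = _pair_arrays(cohort)
    if tt.size == 0:
        raise CoxError("no complete 1:1 strata present")
    a, b, informative = _pair_counts(tt, et, tc, ec)
    df = cohort.data
    return _fit_from_pair_counts(
        a, b, informative,
        n_used=int(len(df)), events_used=int(df["event"].sum()),
        ci_level=ci_level,
    )
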