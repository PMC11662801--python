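"""Propensity-score estimation and 1:1 greedy caliper matching.

The propensity score is fitted by maximum-likelihood logistic
regression (Newton/IRLS via statsmodels, relative tolerance 1e-8, at
most 50 iterations).  Matching pairs each treated subject with the
nearest not-yet-used control on the logit-PS scale, discarding matches
farther than ``caliper_multiplier`` (default 0.2) times the pooled
standard deviation of the logit PS over *all* subjects.

Treated subjects are processed in a seeded-random order: the greedy
result depends on processing order, the underlying study design does
not prescribe one, and a random order avoids the artefacts of PS-sorted
processing while staying exactly reproducible.  Distance ties break to
the smaller control id.  Matching is without replacement and roles are
never swapped, even when treated outnumber controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit as _logit

from .io import CohortTable, CovariateSpec

__all__ = [
    "EstimationError",
    "MatchingError",
    "PropensityFit",
    "MatchResult",
    "design_matrix",
    "fit_logistic_ps",
    "greedy_caliper_match",
    "matched_cohort",
]

SEPARATION_BOUND = 15.0


class EstimationError(RuntimeError):
    """The PS logistic model could not be estimated reliably."""


class MatchingError(ValueError):
    """Greedy caliper matching is undefined for the supplied scores."""


@dataclass(frozen=True)
class PropensityFit:
    """Fitted PS model: coefficients (named, intercept first) and per-subject scores."""

    coefficients: pd.Series
    propensity: np.ndarray
    converged: bool
    iterations: int


@dataclass(frozen=True)
class MatchResult:
    """1:1 treated-control pair assignments with caliper bookkeeping.

    ``pairs`` holds (treated_id, control_id, logit_distance) in the
    order the treated subjects were matched; stratum labels 1..#pairs
    follow that order.  ``sd_logit_ps`` is the pooled (all-subject) SD
    of the logit PS from which the caliper width was derived.
    """

    pairs: tuple[tuple[object, object, float], ...]
    caliper_width: float
    sd_logit_ps: float
    caliper_multiplier: float
    unmatched_treated: tuple

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"treated_id": t, "control_id": c, "distance": d, "stratum": i + 1}
                for i, (t, c, d) in enumerate(self.pairs)
            ]
        )


def design_matrix(cohort: CohortTable, covariate_names) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix (no intercept) for the named covariates.

    Continuous and binary columns enter as-is, ordinal columns as their
    declared level codes, nominal columns as one-hot indicators with
    the first declared level as reference.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariate_names:
        spec = cohort.spec(name)
        col = cohort.data[name]
        if spec.kind in ("continuous", "binary"):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        elif spec.kind == "ordinal":
            codes = pd.Categorical(col, categories=spec.levels, ordered=True).codes
            cols.append(codes.astype(float))
            names.append(name)
        else:  # nominal
            for level in spec.levels[1:]:
                cols.append((col == level).to_numpy(dtype=float))
                names.append(f"{name}[{level}]")
    return np.column_stack(cols), names


def fit_logistic_ps(cohort: CohortTable, covariate_names) -> PropensityFit:
    """Maximum-likelihood logistic PS model for treatment on the named covariates.

    Raises :class:`EstimationError` on a collinear design and on
    complete or quasi-separation (non-convergence or any coefficient
    exceeding 15 in absolute value), advising the caller to revise the
    covariate set.
    """
    if not covariate_names:
        raise EstimationError("at least one covariate is required for the PS model")
    z = cohort.data["treatment"].to_numpy(dtype=float)
    if z.sum() == 0 or z.sum() == z.size:
        raise EstimationError("both treatment arms must be nonempty")
    xmat, names = design_matrix(cohort, covariate_names)
    exog = sm.add_constant(xmat, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise EstimationError(
            "collinear design matrix: drop redundant or constant covariates"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(z, exog).fit(method="newton", tol=1e-8, maxiter=50, disp=0)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as err:
        raise EstimationError(f"PS model estimation failed: {err}") from err
    params = np.asarray(res.params, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged or np.max(np.abs(params)) > SEPARATION_BOUND:
        raise EstimationError(
            "separation suspected in the PS model (non-convergence or |coefficient| > 15); "
            "revise the covariate set"
        )
    ps = np.asarray(res.predict(exog), dtype=float)
    coef = pd.Series(params, index=["intercept"] + names)
    return PropensityFit(
        coefficients=coef,
        propensity=ps,
        converged=converged,
        iterations=int(res.mle_retvals.get("iterations", -1)),
    )


def greedy_caliper_match(propensity, treatment, subject_ids=None,
                         caliper_multiplier: float = 0.2,
                         rng=None) -> MatchResult:
    """Greedy nearest-available-neighbour 1:1 matching on the logit-PS scale."""
    ps = np.asarray(propensity, dtype=float)
    z = np.asarray(treatment)
    if ps.shape != z.shape:
        raise MatchingError("propensity and treatment must have the same length")
    if ((ps <= 0) | (ps >= 1)).any():
        raise MatchingError("propensity scores must lie strictly in (0, 1)")
    if subject_ids is None:
        subject_ids = np.arange(ps.size)
    ids = np.asarray(subject_ids)
    if rng is None:
        rng = np.random.default_rng(0)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    lp = _logit(ps)
    sd = float(np.std(lp, ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise MatchingError("degenerate propensity scores: caliper width undefined (SD of logit PS is 0)")
    caliper = caliper_multiplier * sd

    treated_idx = np.flatnonzero(z == 1)
    control_idx = np.flatnonzero(z == 0)
    if treated_idx.size == 0 or control_idx.size == 0:
        raise MatchingError("both treatment arms must be nonempty")
    # sort controls by id so argmin ties resolve to the smaller control id
    control_idx = control_idx[np.argsort(ids[control_idx], kind="stable")]
    control_lp = lp[control_idx]
    used = np.zeros(control_idx.size, dtype=bool)

    order = rng.permutation(treated_idx.size)
    pairs = []
    unmatched = []
    for ti in treated_idx[order]:
        dist = np.abs(control_lp - lp[ti])
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= caliper:
            used[j] = True
            pairs.append((ids[ti], ids[control_idx[j]], float(dist[j])))
        else:
            unmatched.append(ids[ti])
    return MatchResult(
        pairs=tuple(pairs),
        caliper_width=caliper,
        sd_logit_ps=sd,
        caliper_multiplier=caliper_multiplier,
        unmatched_treated=tuple(unmatched),
    )


def matched_cohort(cohort: CohortTable, match: MatchResult,
                   propensity=None) -> CohortTable:
    """Analysis set of matched subjects with stratum labels 1..#pairs.

    Rows appear pair by pair (treated, control).  When ``propensity``
    is given it is stored in the ``propensity`` column.
    """
    if match.n_pairs == 0:
        raise MatchingError("no pairs were matched within the caliper")
    df = cohort.data.set_index("id", drop=False)
    ids_in_order = [sid for (tid, cid, _d) in match.pairs for sid in (tid, cid)]
    out = df.loc[ids_in_order].reset_index(drop=True)
    out["stratum"] = np.repeat(np.arange(1, match.n_pairs + 1), 2)
    if propensity is not None:
        ps = pd.Series(np.asarray(propensity, float), index=cohort.data["id"].to_numpy())
        out["propensity"] = ps.loc[out["id"]].to_numpy()
    return CohortTable(out, cohort.covariates)
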