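"""Interpretation of landmark trajectories: which bias, if any?

The diagnostic reads the two trajectories in sequence.  First the
treatment-effect trajectory: is there a systematic shift of the
log-hazard-ratio over the first half of the deletion path, measured in
units of the step-0 standard error?  Only if a shift is present does
the SSQ trajectory come into play: a large SSQ already at step 0
(before any deletion) points at an omitted *confounder* — its
association with treatment allocation survives matching — whereas a
low initial SSQ that *rises* during deletion points at an omitted
*prognostic factor* whose balance erodes as high-risk subjects are
selectively removed, i.e. built-in selection bias.  A stable
trajectory with high initial SSQ is the signature of an omitted
instrument (imbalanced but harmless); a shifting trajectory with no
SSQ signal at all suggests an unmeasured source that the observed
omitted covariates cannot explain.

Decision table (shift flag, initial-imbalance flag, SSQ trend):

    no shift, balanced    -> no_bias_indicated
    no shift, imbalanced  -> instrument_omitted
    shift,    imbalanced  -> confounding_suspected
    shift,    balanced, rising SSQ -> builtin_selection_suspected
    shift,    balanced, flat SSQ   -> unmeasured_source_suspected

All cutoffs are explicit configuration: the shift threshold (2.0
standard errors), the imbalance level (upper 1% of the chi^2_k
reference), and the trend rule (positive least-squares slope of SSQ
versus deleted fraction over the first half).  The underlying scheme
is qualitative; these defaults make it a reproducible screening rule,
not a calibrated hypothesis test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .balance import BalanceReport
from .io import CohortTable
from .landmark import LandmarkTrajectory, run_dynamic_landmarking

__all__ = [
    "DiagnosisThresholds",
    "DiagnosisResult",
    "ShiftTest",
    "detect_shift",
    "assess_initial_imbalance",
    "classify",
    "per_covariate_diagnosis",
    "recommendation",
    "LABELS",
]

LABELS = (
    "no_bias_indicated",
    "confounding_suspected",
    "builtin_selection_suspected",
    "instrument_omitted",
    "unmeasured_source_suspected",
)

MIN_STEPS = 10


@dataclass(frozen=True)
class DiagnosisThresholds:
    """Cutoffs of the screening rule, all configurable."""

    shift_se_multiple: float = 2.0
    imbalance_alpha: float = 0.01
    evaluation_fraction: float = 0.5


class ShiftTest(NamedTuple):
    flag: bool
    magnitude: float
    slope: float


@dataclass(frozen=True)
class DiagnosisResult:
    label: str
    shift_detected: bool
    shift_magnitude: float
    initial_ssq: float
    initial_ssq_df: int
    initial_ssq_pvalue: float
    ssq_trend: float
    thresholds: DiagnosisThresholds


def detect_shift(trajectory: LandmarkTrajectory,
                 se_multiple: float = 2.0,
                 evaluation_fraction: float = 0.5) -> ShiftTest:
    """Systematic shift of the log-HR over the first half of deletion.

    The magnitude is |log-HR at the step nearest the evaluation
    fraction minus log-HR at step 0| divided by the step-0 standard
    error; the least-squares slope of log-HR versus deleted fraction
    over the evaluated stretch is returned as supporting evidence.
    """
    if len(trajectory) < MIN_STEPS:
        raise ValueError(
            f"shift detection needs >= {MIN_STEPS} landmark steps, got {len(trajectory)}"
        )
    frac = trajectory.fraction_deleted
    loghr = trajectory.log_hr
    se0 = trajectory.steps[0].fit.se
    target = trajectory.step_nearest_fraction(evaluation_fraction)
    magnitude = abs(loghr[target] - loghr[0]) / se0
    window = frac <= max(evaluation_fraction, frac[target])
    slope = _ls_slope(frac[window], loghr[window])
    return ShiftTest(bool(magnitude > se_multiple), float(magnitude), slope)


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope via the covariance formula (exactly 0 for constant y)."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.dot(xc, xc))


def assess_initial_imbalance(step0_balance: BalanceReport,
                             alpha: float = 0.01) -> bool:
    """True when the step-0 SSQ exceeds the upper-alpha chi^2_k quantile."""
    if step0_balance.k < 1:
        raise ValueError("balance report must carry at least one df")
    return bool(step0_balance.ssq > stats.chi2.ppf(1 - alpha, step0_balance.k))


def _classify_evidence(shift: ShiftTest, imbalanced: bool,
                       ssq_slope: float, initial: tuple[float, int, float],
                       thresholds: DiagnosisThresholds) -> DiagnosisResult:
    ssq0, k0, p0 = initial
    if not shift.flag:
        label = "instrument_omitted" if imbalanced else "no_bias_indicated"
    elif imbalanced:
        label = "confounding_suspected"
    elif ssq_slope > 0:
        label = "builtin_selection_suspected"
    else:
        label = "unmeasured_source_suspected"
    return DiagnosisResult(
        label=label,
        shift_detected=shift.flag,
        shift_magnitude=shift.magnitude,
        initial_ssq=ssq0,
        initial_ssq_df=k0,
        initial_ssq_pvalue=p0,
        ssq_trend=ssq_slope,
        thresholds=thresholds,
    )


def _ssq_slope(frac: np.ndarray, ssq: np.ndarray, evaluation_fraction: float) -> float:
    window = frac <= evaluation_fraction
    if window.sum() < 2:
        window = np.ones_like(frac, dtype=bool)
    return _ls_slope(frac[window], ssq[window])


def classify(trajectory: LandmarkTrajectory,
             thresholds: DiagnosisThresholds | None = None) -> DiagnosisResult:
    """Apply the two-step decision scheme to a full landmark trajectory."""
    th = thresholds or DiagnosisThresholds()
    shift = detect_shift(trajectory, th.shift_se_multiple, th.evaluation_fraction)
    report0 = trajectory.steps[0].ssq_omitted
    imbalanced = assess_initial_imbalance(report0, th.imbalance_alpha)
    slope = _ssq_slope(trajectory.fraction_deleted, trajectory.ssq, th.evaluation_fraction)
    return _classify_evidence(
        shift, imbalanced, slope, (report0.ssq, report0.k, report0.pvalue), th
    )


def per_covariate_diagnosis(cohort: CohortTable, omitted_covariates,
                            thresholds: DiagnosisThresholds | None = None,
                            **landmark_kwargs) -> dict[str, DiagnosisResult]:
    """One diagnosis per omitted covariate, each judged on its own balance.

    A single landmark run supplies the shared treatment-effect
    trajectory (which does not depend on the balance set); each
    covariate is then classified against its own z-difference series,
    with the chi^2 reference df of its declared kind.
    """
    omitted = tuple(omitted_covariates)
    if not omitted:
        raise ValueError("at least one omitted covariate is required")
    th = thresholds or DiagnosisThresholds()
    trajectory = run_dynamic_landmarking(cohort, omitted, **landmark_kwargs)
    shift = detect_shift(trajectory, th.shift_se_multiple, th.evaluation_fraction)
    frac = trajectory.fraction_deleted

    out: dict[str, DiagnosisResult] = {}
    for name in omitted:
        records = [s.ssq_omitted.record(name) for s in trajectory.steps]
        ssq_series = np.array([r.ssq for r in records])
        k = records[0].df
        ssq0 = float(ssq_series[0])
        imbalanced = bool(ssq0 > stats.chi2.ppf(1 - th.imbalance_alpha, k))
        slope = _ssq_slope(frac, ssq_series, th.evaluation_fraction)
        out[name] = _classify_evidence(
            shift, imbalanced, slope,
            (ssq0, k, float(stats.chi2.sf(ssq0, k))), th,
        )
    return out


_RECOMMENDATION = {
    "no_bias_indicated": (
        "No systematic shift and balanced omitted covariates: the hazard ratio "
        "shows no sign of confounding or built-in selection bias."
    ),
    "confounding_suspected": (
        "Systematic shift with imbalanced omitted covariates at step 0: "
        "re-estimate the propensity score including the flagged covariates "
        "and re-run the diagnostic."
    ),
    "builtin_selection_suspected": (
        "Systematic shift with initially balanced omitted covariates whose "
        "imbalance grows during deletion: an omitted prognostic factor is "
        "inducing built-in selection bias; condition the outcome model on it "
        "for a subject-specific effect."
    ),
    "instrument_omitted": (
        "Imbalanced omitted covariate but a stable effect trajectory: the "
        "covariate behaves like an instrument (treatment-associated only) "
        "and need not enter the outcome model."
    ),
    "unmeasured_source_suspected": (
        "Systematic shift without any signal in the measured omitted "
        "covariates: an unmeasured confounder or prognostic factor (or a "
        "time-dependent effect) may be present; consider more flexible "
        "modelling."
    ),
}


def recommendation(result: DiagnosisResult) -> str:
    """Human-readable recommendation for a diagnosis."""
    return _RECOMMENDATION[result.label]
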