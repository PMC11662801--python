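"""Covariate balance between treatment arms: z-differences and SSQ.

The z-difference standardizes a between-group difference by the
standard error of that difference, so — unlike the standardized mean
difference — it grows with sqrt(n).  Summing the squared z-differences
of a covariate set gives the global balance statistic SSQ, which under
balance (two arms drawn from the same distribution) is approximately
chi-squared with k degrees of freedom, k being the number of
independent components: 1 per continuous, binary or ordinal covariate
and (#levels - 1) per nominal covariate.

Sign convention: every z is oriented treated minus control.

Per-kind statistics
-------------------
continuous
    Welch-type: difference of means over sqrt(var_T/n_T + var_C/n_C),
    with unbiased (n-1) sample variances.
binary
    Difference of proportions over the unpooled binomial standard error.
ordinal
    Mid-rank (tie-corrected Mann-Whitney) standardization of the
    two-sample rank sum on the declared level order: mean 0 and unit
    variance under exchangeability, positive when the treated arm sits
    higher.  Contributes 1 df.
nominal
    One indicator z_binary per non-reference level (reference = first
    declared level), contributing (#levels - 1) df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import CohortTable, CovariateSpec

__all__ = [
    "BalanceError",
    "BalanceRecord",
    "BalanceReport",
    "z_continuous",
    "z_binary",
    "z_ordinal",
    "z_nominal",
    "balance_between",
    "balance_report",
    "report_from_records",
]


class BalanceError(ValueError):
    """A z-difference is undefined for the supplied groups."""


# ---------------------------------------------------------------------------
# per-kind kernels
# ---------------------------------------------------------------------------

def z_continuous(mean_a: float, var_a: float, n_a: int,
                 mean_b: float, var_b: float, n_b: int) -> float:
    """Welch-type z-difference for a continuous covariate (group a - group b)."""
    if n_a < 2 or n_b < 2:
        raise BalanceError("z_continuous needs at least 2 subjects per group")
    if var_a < 0 or var_b < 0:
        raise BalanceError("variances must be non-negative")
    denom = var_a / n_a + var_b / n_b
    if denom <= 0:
        raise BalanceError("zero denominator: both group variances vanish")
    return (mean_a - mean_b) / math.sqrt(denom)


def z_binary(p_a: float, n_a: int, p_b: float, n_b: int) -> float:
    """Two-proportion z-difference with unpooled variance (group a - group b)."""
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise BalanceError("proportions must lie in [0, 1]")
    if n_a < 1 or n_b < 1:
        raise BalanceError("groups must be nonempty")
    denom = p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b
    if denom <= 0:
        raise BalanceError("zero denominator: both proportions are degenerate (0 or 1)")
    return (p_a - p_b) / math.sqrt(denom)


def z_ordinal(level_counts_a: Sequence[float], level_counts_b: Sequence[float]) -> float:
    """Standardized two-sample mid-rank statistic on ordered level counts.

    Positive when group a is concentrated on higher levels than group b.
    """
    ca = np.asarray(level_counts_a, dtype=float)
    cb = np.asarray(level_counts_b, dtype=float)
    if ca.shape != cb.shape or ca.size < 2:
        raise BalanceError("ordinal counts need >=2 levels and matching shapes")
    n_a, n_b = ca.sum(), cb.sum()
    if n_a < 1 or n_b < 1:
        raise BalanceError("both groups must be nonempty")
    total = ca + cb
    if (total > 0).sum() < 2:
        raise BalanceError("only one occupied level overall: rank statistic undefined")
    n = n_a + n_b
    # mid-rank of each level = (# strictly below) + (t + 1) / 2
    below = np.concatenate(([0.0], np.cumsum(total)[:-1]))
    midrank = below + (total + 1) / 2.0
    rank_sum_a = float(np.dot(ca, midrank))
    expected = n_a * (n + 1) / 2.0
    tie_term = float(np.sum(total ** 3 - total)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise BalanceError("zero rank variance")
    return (rank_sum_a - expected) / math.sqrt(var)


def z_nominal(level_counts_a: Sequence[float], level_counts_b: Sequence[float]) -> list[float]:
    """Per-level indicator z-differences against the first (reference) level.

    Returns one z per non-reference level; a level empty in both groups
    yields NaN for that component (degenerate indicator).
    """
    ca = np.asarray(level_counts_a, dtype=float)
    cb = np.asarray(level_counts_b, dtype=float)
    if ca.shape != cb.shape or ca.size < 2:
        raise BalanceError("nominal counts need >=2 levels and matching shapes")
    n_a, n_b = ca.sum(), cb.sum()
    if n_a < 1 or n_b < 1:
        raise BalanceError("both groups must be nonempty")
    zs = []
    for level in range(1, ca.size):
        p_a, p_b = ca[level] / n_a, cb[level] / n_b
        denom = p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b
        if denom <= 0:
            if p_a == p_b:
                zs.append(math.nan)
                continue
            raise BalanceError(f"degenerate indicator for level index {level} with unequal proportions")
        zs.append((p_a - p_b) / math.sqrt(denom))
    return zs


# ---------------------------------------------------------------------------
# records and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalanceRecord:
    """Balance evidence for one covariate.

    ``z_components`` holds the individual z-differences (a single value
    except for nominal covariates, which carry one per non-reference
    level).  ``z`` collapses them: the signed component for df-1 kinds,
    the root-sum-of-squares magnitude for nominal.  ``smd`` is the
    standardized mean difference, emitted as a convenience for
    continuous and binary covariates only.
    """

    name: str
    kind: str
    z_components: tuple[float, ...]
    df: int
    smd: float | None = None

    @property
    def z(self) -> float:
        if self.df == 1 and len(self.z_components) == 1:
            return self.z_components[0]
        return math.sqrt(float(np.nansum(np.square(self.z_components))))

    @property
    def ssq(self) -> float:
        return float(np.nansum(np.square(self.z_components)))


@dataclass(frozen=True)
class BalanceReport:
    """Per-covariate z-differences plus the global SSQ statistic."""

    records: tuple[BalanceRecord, ...]
    n_treated: int
    n_control: int

    @property
    def ssq(self) -> float:
        return float(sum(r.ssq for r in self.records))

    @property
    def k(self) -> int:
        return int(sum(r.df for r in self.records))

    @property
    def pvalue(self) -> float:
        """Upper-tail chi^2_k probability of the observed SSQ."""
        return float(stats.chi2.sf(self.ssq, self.k))

    @property
    def chi2_reference_quantiles(self) -> dict[float, float]:
        qs = (0.5, 0.9, 0.95, 0.99, 0.999)
        return {q: float(stats.chi2.ppf(q, self.k)) for q in qs}

    def record(self, name: str) -> BalanceRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(f"no balance record for covariate {name!r}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"name": r.name, "kind": r.kind, "z": r.z, "df": r.df,
                 "ssq": r.ssq, "smd": r.smd}
                for r in self.records
            ]
        )


def report_from_records(records: Sequence[BalanceRecord],
                        n_treated: int, n_control: int) -> BalanceReport:
    return BalanceReport(tuple(records), n_treated, n_control)


def _level_counts(values: np.ndarray, levels: Sequence) -> np.ndarray:
    idx = {lv: i for i, lv in enumerate(levels)}
    counts = np.zeros(len(levels))
    for v in values:
        counts[idx[v]] += 1
    return counts


def balance_between(spec: CovariateSpec, treated_values, control_values) -> BalanceRecord:
    """Balance record for one covariate from raw per-arm values.

    A covariate degenerate in *both* arms (zero-variance denominator
    with identical location) is recorded with NaN components and its df
    still counted; degenerate in one arm only raises
    :class:`BalanceError`.
    """
    a = np.asarray(treated_values)
    c = np.asarray(control_values)
    if a.size == 0 or c.size == 0:
        raise BalanceError(f"covariate {spec.name!r}: both arms must be nonempty")

    if spec.kind == "continuous":
        a = a.astype(float)
        c = c.astype(float)
        ma, mc = a.mean(), c.mean()
        va = a.var(ddof=1) if a.size > 1 else 0.0
        vc = c.var(ddof=1) if c.size > 1 else 0.0
        pooled = (va + vc) / 2.0
        smd = (ma - mc) / math.sqrt(pooled) if pooled > 0 else math.nan
        try:
            z = z_continuous(ma, va, a.size, mc, vc, c.size)
        except BalanceError:
            if va == vc == 0 and ma == mc:
                return BalanceRecord(spec.name, spec.kind, (math.nan,), 1, math.nan)
            raise
        return BalanceRecord(spec.name, spec.kind, (z,), 1, smd)

    if spec.kind == "binary":
        p_a, p_c = float(np.mean(a)), float(np.mean(c))
        pooled = (p_a * (1 - p_a) + p_c * (1 - p_c)) / 2.0
        smd = (p_a - p_c) / math.sqrt(pooled) if pooled > 0 else math.nan
        try:
            z = z_binary(p_a, a.size, p_c, c.size)
        except BalanceError:
            if p_a == p_c:
                return BalanceRecord(spec.name, spec.kind, (math.nan,), 1, math.nan)
            raise
        return BalanceRecord(spec.name, spec.kind, (z,), 1, smd)

    counts_a = _level_counts(a, spec.levels)
    counts_c = _level_counts(c, spec.levels)
    if spec.kind == "ordinal":
        try:
            z = z_ordinal(counts_a, counts_c)
        except BalanceError:
            occupied = counts_a + counts_c
            if (occupied > 0).sum() < 2:
                return BalanceRecord(spec.name, spec.kind, (math.nan,), 1)
            raise
        return BalanceRecord(spec.name, spec.kind, (z,), 1)

    # nominal
    zs = z_nominal(counts_a, counts_c)
    return BalanceRecord(spec.name, spec.kind, tuple(zs), len(spec.levels) - 1)


def balance_report(cohort: CohortTable, covariate_names: Sequence[str]) -> BalanceReport:
    """Per-covariate z-differences and SSQ between the treatment arms."""
    if not covariate_names:
        raise BalanceError("at least one covariate is required for a balance report")
    z = cohort.data["treatment"].to_numpy()
    treated = z == 1
    if treated.sum() == 0 or (~treated).sum() == 0:
        raise BalanceError("both treatment arms must be nonempty")
    records = []
    for name in covariate_names:
        spec = cohort.spec(name)
        col = cohort.data[name].to_numpy()
        records.append(balance_between(spec, col[treated], col[~treated]))
    return report_from_records(records, int(treated.sum()), int((~treated).sum()))
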