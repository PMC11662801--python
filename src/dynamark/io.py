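"""Cohort tables, covariate schemas, and result files.

A cohort is a subject-level table with columns ``id``, ``treatment``
(0/1), ``time`` (strictly positive follow-up), ``event`` (1 = event
observed, 0 = censored), one column per declared covariate, and the
optional analysis columns ``propensity`` and ``stratum``.  Covariate
types are *declared*, never inferred: the sum-of-squared-z-differences
balance statistic decomposes differently for continuous, binary,
ordinal and nominal covariates, so a silent misclassification would
change its degrees of freedom.  The declaration lives in a JSON sidecar
(see :func:`read_covariate_specs`).

Event coding is fixed as 1 = event, 0 = censored; no other dialect is
accepted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSpec",
    "CohortTable",
    "RunConfig",
    "CohortValidationError",
    "read_covariate_specs",
    "write_covariate_specs",
    "read_cohort",
    "write_cohort",
    "write_results",
    "read_run_config",
]

COVARIATE_KINDS = ("continuous", "binary", "ordinal", "nominal")
RESERVED_COLUMNS = ("id", "treatment", "time", "event", "propensity", "stratum")


class CohortValidationError(ValueError):
    """A cohort table or covariate schema violates its contract."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declared type of a single covariate.

    Parameters
    ----------
    name
        Column name in the cohort table.
    kind
        One of ``continuous``, ``binary``, ``ordinal``, ``nominal``.
    levels
        Ordered category labels; required for ordinal/nominal covariates
        and forbidden otherwise.  The declared order defines the rank
        order (ordinal) and the reference level (nominal: first level).
    """

    name: str
    kind: str
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in COVARIATE_KINDS:
            raise CohortValidationError(
                f"covariate {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {COVARIATE_KINDS}"
            )
        if self.kind in ("ordinal", "nominal"):
            if self.levels is None or len(self.levels) < 2:
                raise CohortValidationError(
                    f"covariate {self.name!r}: {self.kind} covariates need >=2 declared levels"
                )
            object.__setattr__(self, "levels", tuple(self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise CohortValidationError(
                    f"covariate {self.name!r}: duplicate levels in declaration"
                )
        elif self.levels is not None:
            raise CohortValidationError(
                f"covariate {self.name!r}: levels are only allowed for ordinal/nominal kinds"
            )

    @property
    def df(self) -> int:
        """Degrees of freedom this covariate contributes to the SSQ reference."""
        if self.kind == "nominal":
            return len(self.levels) - 1
        return 1


@dataclass
class CohortTable:
    """Validated subject-level survival table with typed covariates.

    ``data`` holds one row per subject.  Strata, when present, label 1:1
    treated-control matches; a stratum may hold a single subject after
    landmark deletion has removed its partner (the orphan is retained on
    purpose), but never more than two subjects and never a concordant
    pair.
    """

    data: pd.DataFrame
    covariates: tuple[CovariateSpec, ...] = ()

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        self.data = self.data.reset_index(drop=True)
        _validate(self.data, self.covariates)

    # -- conveniences -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.covariates)

    def spec(self, name: str) -> CovariateSpec:
        for s in self.covariates:
            if s.name == name:
                return s
        raise KeyError(f"no declared covariate named {name!r}")

    @property
    def has_strata(self) -> bool:
        return "stratum" in self.data.columns

    def subset(self, mask_or_index) -> "CohortTable":
        """New cohort restricted to the given boolean mask or positional index."""
        if np.asarray(mask_or_index).dtype == bool:
            frame = self.data.loc[np.asarray(mask_or_index)]
        else:
            frame = self.data.iloc[np.asarray(mask_or_index)]
        return CohortTable(frame.copy(), self.covariates)

    def replace_data(self, frame: pd.DataFrame) -> "CohortTable":
        return CohortTable(frame, self.covariates)


def _validate(df: pd.DataFrame, specs: Sequence[CovariateSpec]) -> None:
    for col in ("id", "treatment", "time", "event"):
        if col not in df.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise CohortValidationError(f"duplicate subject id {dup!r}")
    for col in ("treatment", "time", "event"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise CohortValidationError(f"missing value in column {col!r} at row {row}")
    for col in ("treatment", "event"):
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"column {col!r} must be coded 0/1; offending value "
                f"{vals[bad][0]!r} at row {row}"
            )
    t = pd.to_numeric(df["time"], errors="coerce")
    bad = ~(t > 0) | t.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError(f"column 'time' must be strictly positive; row {row}")

    declared = {s.name for s in specs}
    for s in specs:
        if s.name in RESERVED_COLUMNS:
            raise CohortValidationError(f"covariate name {s.name!r} clashes with a reserved column")
        if s.name not in df.columns:
            raise CohortValidationError(f"declared covariate {s.name!r} missing from table")
        col = df[s.name]
        if s.kind == "binary":
            vals = col.dropna().to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise CohortValidationError(
                    f"binary covariate {s.name!r} must be coded 0/1"
                )
        elif s.kind in ("ordinal", "nominal"):
            extra = set(col.dropna().unique()) - set(s.levels)
            if extra:
                raise CohortValidationError(
                    f"covariate {s.name!r}: undeclared level(s) {sorted(map(str, extra))!r}"
                )
    undeclared = [
        c for c in df.columns if c not in RESERVED_COLUMNS and c not in declared
    ]
    if undeclared:
        raise CohortValidationError(
            f"column(s) {undeclared!r} present in table but not declared in the covariate schema"
        )

    if "propensity" in df.columns:
        p = df["propensity"].dropna().to_numpy(dtype=float)
        if ((p <= 0) | (p >= 1)).any():
            raise CohortValidationError("propensity scores must lie strictly in (0, 1)")
    if "stratum" in df.columns:
        grouped = df.loc[df["stratum"].notna()].groupby("stratum", sort=False)
        sizes = grouped.size()
        if (sizes > 2).any():
            label = sizes.index[sizes > 2][0]
            raise CohortValidationError(
                f"stratum {label!r} has {int(sizes[label])} members; 1:1 matching allows at most 2"
            )
        arm_sum = grouped["treatment"].sum()
        full = sizes == 2
        bad = full & (arm_sum != 1)
        if bad.any():
            label = arm_sum.index[bad][0]
            raise CohortValidationError(
                f"stratum {label!r} is not treatment-discordant (1:1 pairs need one treated, one control)"
            )


# ---------------------------------------------------------------------------
# covariate schema sidecar
# ---------------------------------------------------------------------------

def read_covariate_specs(path) -> tuple[CovariateSpec, ...]:
    """Read the JSON covariate schema: a list of {name, kind[, levels]}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise CohortValidationError("covariate schema must be a JSON list")
    specs = []
    for entry in raw:
        levels = entry.get("levels")
        specs.append(
            CovariateSpec(
                name=entry["name"],
                kind=entry["kind"],
                levels=tuple(levels) if levels is not None else None,
            )
        )
    return tuple(specs)


def write_covariate_specs(specs: Iterable[CovariateSpec], path) -> None:
    payload = []
    for s in specs:
        entry: dict = {"name": s.name, "kind": s.kind}
        if s.levels is not None:
            entry["levels"] = list(s.levels)
        payload.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def read_cohort(path, spec_path) -> CohortTable:
    """Read a cohort CSV plus its covariate schema sidecar.

    The CSV must carry a header with at least ``id, treatment, time,
    event``; every non-reserved column must be declared in the sidecar.
    """
    specs = read_covariate_specs(spec_path)
    df = pd.read_csv(path)
    return CohortTable(df, specs)


def write_cohort(cohort: CohortTable, path, spec_path=None) -> None:
    cohort.data.to_csv(path, index=False)
    if spec_path is not None:
        write_covariate_specs(cohort.covariates, spec_path)


# ---------------------------------------------------------------------------
# trajectory results CSV
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "step",
    "landmark_time",
    "n_remaining",
    "events_remaining",
    "log_hr",
    "se",
    "ci_low",
    "ci_high",
    "ssq_omitted",
    "converged",
)


def write_results(trajectory, path) -> None:
    """Write a landmark trajectory as a long-format CSV, one row per step.

    Floats are written with 12 significant digits so that a re-read
    reproduces estimates to well below 1e-9.
    """
    steps = getattr(trajectory, "steps", None)
    if not steps:
        raise ValueError("cannot write an empty trajectory")
    rows = []
    for s in steps:
        rows.append(
            {
                "step": s.step_index,
                "landmark_time": s.landmark_time,
                "n_remaining": s.n_remaining,
                "events_remaining": s.events_remaining,
                "log_hr": s.fit.log_hr,
                "se": s.fit.se,
                "ci_low": s.fit.ci[0],
                "ci_high": s.fit.ci[1],
                "ssq_omitted": s.ssq_omitted.ssq,
                "converged": s.fit.converged,
            }
        )
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """End-to-end analysis configuration for the CLI pipeline."""

    cohort_path: str = ""
    schema_path: str = ""
    output_path: str = ""
    ps_covariates: tuple[str, ...] = ()
    omitted_covariates: tuple[str, ...] = ()
    estimator: str = "pair_stratified"
    deletion: float = 0.01
    caliper_multiplier: float = 0.2
    min_subjects: int = 100
    min_events_per_arm: int = 5
    min_informative_strata: int = 10
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ps_covariates", tuple(self.ps_covariates))
        object.__setattr__(self, "omitted_covariates", tuple(self.omitted_covariates))
        overlap = set(self.ps_covariates) & set(self.omitted_covariates)
        if overlap:
            raise CohortValidationError(
                f"covariates {sorted(overlap)!r} cannot be both in the PS model and omitted"
            )
        if self.estimator not in ("marginal", "pair_stratified"):
            raise CohortValidationError(f"unknown estimator {self.estimator!r}")
        if isinstance(self.deletion, float) and not self.deletion.is_integer():
            if not 0 < self.deletion < 1:
                raise CohortValidationError("fractional deletion step must lie in (0, 1)")
        elif int(self.deletion) < 1:
            raise CohortValidationError("absolute deletion step must be >= 1")
        if not 0 < self.ci_level < 1:
            raise CohortValidationError("ci_level must lie in (0, 1)")


def read_run_config(path) -> RunConfig:
    """Read a RunConfig from YAML or JSON (chosen by extension, YAML parses both)."""
    text = Path(path).read_text(encoding="utf-8")
    raw: Mapping = yaml.safe_load(text)
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise CohortValidationError(f"unknown config key(s): {sorted(unknown)!r}")
    return RunConfig(**raw)
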