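"""Cohort container, covariate derivation, and the exclusion cascade.

A cohort is a participant-by-variable table: one column per questionnaire
variable (ordinal labels) plus covariate columns (anthropometrics, blood
pressure, blood chemistry, lifestyle) and outcome flags.  The exclusion
cascade filters the enrolled roster down to the analysis sample, keeping
per-step removal counts with first-step attribution so the printed
flowchart arithmetic is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .schema import QuestionnaireSchema, SchemaError, load_schema

#: Covariate / outcome columns understood by the pipeline.  All are optional
#: at load time; individual operations check for what they need.
COVARIATE_COLUMNS = [
    "age", "height", "weight", "bmi", "sbp", "dbp", "fbg", "ldl", "hdl",
    "triglycerides", "salt_intake", "sds", "sleep_hours", "smoking",
    "education", "pa_category",
    "hypertension_history_or_medication", "diabetes_history_or_medication",
    "dyslipidemia_medication",
    "dyslipidemia", "diabetes", "depressive", "typical_sleep",
    "baseline_hypertension", "incident_hypertension",
    "followed_up", "heart_disease", "female", "consented",
]

SMOKING_LEVELS = ("never", "former", "current")
EDUCATION_LEVELS = ("below_college", "college_plus")
PA_LEVELS = ("0", "0.1-22.9", ">=23")


class CohortValidationError(ValueError):
    """A record violates the questionnaire schema."""


@dataclass(frozen=True)
class CovariateRules:
    """Diagnostic threshold rules.

    Comparison operators follow the clinical definitions exactly:
    blood pressure, LDL and triglycerides use >=, fasting blood glucose
    uses strict >, HDL uses strict <.
    """

    sbp_hypertension: float = 140.0   # mmHg, >=
    dbp_hypertension: float = 90.0    # mmHg, >=
    fbg_diabetes: float = 126.0       # mg/dL, strict >
    ldl_dyslipidemia: float = 140.0   # mg/dL, >=
    hdl_dyslipidemia: float = 40.0    # mg/dL, strict <
    tg_dyslipidemia: float = 150.0    # mg/dL, >=
    sds_depressive: float = 40.0      # score, >=
    typical_sleep_range: tuple[float, float] = (6.0, 8.0)  # hours, inclusive


@dataclass
class ExclusionStep:
    name: str
    description: str
    n_removed: int = 0


@dataclass
class ExclusionCascade:
    """Provenance of an exclusion run: ordered steps with removal counts."""

    n_in: int
    n_out: int
    steps: list[ExclusionStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = sum(s.n_removed for s in self.steps)
        if self.n_out != self.n_in - removed:
            raise ValueError(
                f"cascade does not conserve counts: {self.n_in} - {removed} "
                f"!= {self.n_out}"
            )

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "steps": [
                {"name": s.name, "description": s.description,
                 "n_removed": s.n_removed}
                for s in self.steps
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def report(self) -> str:
        lines = [f"enrolled: n = {self.n_in}"]
        running = self.n_in
        for s in self.steps:
            running -= s.n_removed
            lines.append(f"  - {s.description}: removed {s.n_removed} "
                         f"(remaining {running})")
        lines.append(f"analysis sample: n = {self.n_out}")
        return "\n".join(lines)


@dataclass
class Cohort:
    """Participant records validated against a questionnaire schema.

    ``data`` is indexed by participant id; questionnaire columns hold
    ordered categoricals whose categories are the variable's scale labels.
    """

    schema: QuestionnaireSchema
    data: pd.DataFrame
    provenance: ExclusionCascade | None = None

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise CohortValidationError(f"duplicate participant ids: {dupes[:5]}")
        for var in self.schema:
            if var.id not in self.data.columns:
                raise SchemaError(f"missing questionnaire column {var.id!r}")
            col = self.data[var.id]
            if not isinstance(col.dtype, pd.CategoricalDtype):
                col = col.astype(
                    pd.CategoricalDtype(categories=var.scale_labels, ordered=True)
                )
            bad = col.isna() & self.data[var.id].notna()
            if bad.any():
                pid = self.data.index[bad][0]
                val = self.data.loc[pid, var.id]
                raise CohortValidationError(
                    f"participant {pid!r}: response {val!r} is not on the "
                    f"scale of variable {var.id!r}"
                )
            if tuple(col.cat.categories) != var.scale_labels:
                col = col.cat.set_categories(var.scale_labels, ordered=True)
            self.data[var.id] = col

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    def subset(self, mask_or_ids) -> "Cohort":
        """A new cohort restricted to the given boolean mask or id list."""
        sub = self.data.loc[mask_or_ids].copy()
        return Cohort(self.schema, sub, provenance=self.provenance)

    def responses(self) -> pd.DataFrame:
        """Questionnaire columns only, in schema order."""
        return self.data[self.schema.variable_ids]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="id")


def load_cohort(path: str | Path,
                schema_path: str | Path | QuestionnaireSchema) -> Cohort:
    """Read a cohort from delimited text (one row per participant).

    ``schema_path`` may be a YAML schema file or an already-loaded
    :class:`QuestionnaireSchema`.  Column order is free; row order is
    preserved.  Missing questionnaire columns raise :class:`SchemaError`;
    off-scale responses raise :class:`CohortValidationError` naming the
    participant and variable.
    """
    schema = (schema_path if isinstance(schema_path, QuestionnaireSchema)
              else load_schema(schema_path))
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "id" in df.columns:
        df = df.set_index("id")
    else:
        df.index = pd.Index([str(i) for i in range(len(df))], name="id")
    # restore numeric / boolean covariate dtypes
    for col in df.columns:
        if col in schema:
            continue
        ser = df[col]
        if col in ("smoking", "education", "pa_category"):
            continue
        lowered = ser.dropna().str.lower()
        if len(lowered) and lowered.isin(["true", "false"]).all():
            df[col] = ser.str.lower().map({"true": True, "false": False})
        else:
            converted = pd.to_numeric(ser, errors="coerce")
            if converted.notna().sum() == ser.notna().sum():
                df[col] = converted
    return Cohort(schema, df)


# ---------------------------------------------------------------------------
# Covariate derivation
# ---------------------------------------------------------------------------

def _missing_aware_or(*conditions: pd.Series) -> pd.Series:
    """Elementwise OR over nullable-boolean conditions.

    True if any condition is True; False only if all are False; <NA> if no
    condition is True and at least one is missing (a missing measurement is
    flagged, never silently treated as negative).
    """
    out = conditions[0].astype("boolean")
    for cond in conditions[1:]:
        out = out | cond.astype("boolean")
    return out


def derive_covariates(cohort_or_df: "Cohort | pd.DataFrame",
                      rules: CovariateRules | None = None,
                      ) -> "Cohort | pd.DataFrame":
    """Populate derived covariates on a cohort (idempotent).

    Derives BMI (weight/height^2, only where absent), baseline
    hypertension, diabetes, dyslipidemia, depressive symptoms, and typical
    sleep duration.  Flags whose inputs are missing are left as <NA>.
    """
    rules = rules or CovariateRules()
    if isinstance(cohort_or_df, Cohort):
        df = cohort_or_df.data.copy()
    else:
        df = cohort_or_df.copy()

    def col(name: str) -> pd.Series:
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce")
        return pd.Series(np.nan, index=df.index, dtype=float)

    def flag(name: str) -> pd.Series:
        if name in df.columns:
            return df[name].astype("boolean")
        return pd.Series(pd.NA, index=df.index, dtype="boolean")

    height, weight = col("height"), col("weight")
    bmi = weight / height**2
    if "bmi" in df.columns:
        df["bmi"] = col("bmi").fillna(bmi)
    else:
        df["bmi"] = bmi

    def ge(series: pd.Series, threshold: float) -> pd.Series:
        return pd.Series(series >= threshold, dtype="boolean").mask(series.isna())

    def gt(series: pd.Series, threshold: float) -> pd.Series:
        return pd.Series(series > threshold, dtype="boolean").mask(series.isna())

    def lt(series: pd.Series, threshold: float) -> pd.Series:
        return pd.Series(series < threshold, dtype="boolean").mask(series.isna())

    df["baseline_hypertension"] = _missing_aware_or(
        ge(col("sbp"), rules.sbp_hypertension),
        ge(col("dbp"), rules.dbp_hypertension),
        flag("hypertension_history_or_medication"),
    )
    df["diabetes"] = _missing_aware_or(
        gt(col("fbg"), rules.fbg_diabetes),
        flag("diabetes_history_or_medication"),
    )
    df["dyslipidemia"] = _missing_aware_or(
        ge(col("ldl"), rules.ldl_dyslipidemia),
        lt(col("hdl"), rules.hdl_dyslipidemia),
        ge(col("triglycerides"), rules.tg_dyslipidemia),
        flag("dyslipidemia_medication"),
    )
    sds = col("sds")
    df["depressive"] = ge(sds, rules.sds_depressive)
    sleep = col("sleep_hours")
    lo, hi = rules.typical_sleep_range
    df["typical_sleep"] = pd.Series(
        (sleep >= lo) & (sleep <= hi), dtype="boolean"
    ).mask(sleep.isna())

    if isinstance(cohort_or_df, Cohort):
        return Cohort(cohort_or_df.schema, df,
                      provenance=cohort_or_df.provenance)
    return df


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

Predicate = Callable[[pd.DataFrame], pd.Series]


def apply_exclusion_cascade(
    cohort: Cohort,
    steps: Sequence[tuple[str, str, Predicate]],
) -> tuple[Cohort, ExclusionCascade]:
    """Filter a cohort through ordered exclusion predicates.

    Each step is ``(name, description, predicate)`` where the predicate
    returns a boolean Series (True = exclude) over a DataFrame.  A record
    is attributed to the FIRST step that removes it, so per-step counts are
    disjoint and sum with ``n_out`` to ``n_in``.
    """
    df = cohort.data
    keep = pd.Series(True, index=df.index)
    cascade_steps: list[ExclusionStep] = []
    for name, description, predicate in steps:
        excl = predicate(df).fillna(False).astype(bool) & keep
        cascade_steps.append(ExclusionStep(name, description, int(excl.sum())))
        keep &= ~excl
    filtered = df.loc[keep].copy()
    cascade = ExclusionCascade(n_in=len(df), n_out=len(filtered),
                               steps=cascade_steps)
    out = Cohort(cohort.schema, filtered, provenance=cascade)
    return out, cascade


def _missing_response(df: pd.DataFrame, variable_ids: Sequence[str]) -> pd.Series:
    return df[list(variable_ids)].isna().any(axis=1)


def standard_exclusion_steps(
    schema: QuestionnaireSchema,
    exam_columns: Sequence[str] = ("sbp", "dbp", "fbg", "ldl", "hdl",
                                   "triglycerides", "bmi"),
) -> list[tuple[str, str, Predicate]]:
    """The study's enrolment-to-analysis cascade.

    Order: no consent, female, missing dietary data, incomplete health
    examination, heart disease, elevated SBP, elevated DBP, hypertension
    history or medication, no follow-up examination.
    """
    variable_ids = schema.variable_ids

    def not_consented(df):
        return ~df["consented"].astype("boolean").fillna(False)

    def female(df):
        return df["female"].astype("boolean").fillna(False)

    def missing_diet(df):
        return _missing_response(df, variable_ids)

    def missing_exam(df):
        cols = [c for c in exam_columns if c in df.columns]
        return df[cols].isna().any(axis=1)

    def heart_disease(df):
        return df["heart_disease"].astype("boolean").fillna(False)

    def high_sbp(df):
        return pd.to_numeric(df["sbp"], errors="coerce") >= 140

    def high_dbp(df):
        return pd.to_numeric(df["dbp"], errors="coerce") >= 90

    def ht_history(df):
        return df["hypertension_history_or_medication"].astype(
            "boolean").fillna(False)

    def not_followed(df):
        return ~df["followed_up"].astype("boolean").fillna(False)

    return [
        ("no_consent", "did not provide informed consent", not_consented),
        ("female", "female participants", female),
        ("missing_diet", "missing dietary information", missing_diet),
        ("missing_exam", "incomplete health examination records", missing_exam),
        ("heart_disease", "presence of heart disease", heart_disease),
        ("high_sbp", "systolic blood pressure >= 140 mmHg", high_sbp),
        ("high_dbp", "diastolic blood pressure >= 90 mmHg", high_dbp),
        ("ht_history", "history of or medication for hypertension", ht_history),
        ("not_followed", "no follow-up examination", not_followed),
    ]
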