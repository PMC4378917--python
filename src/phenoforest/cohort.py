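"""Cohort data model: variable schema, delimited I/O, derived clinical
variables, and aggregation of raw sputum-culture records into presence flags.

A cohort is a complete-case table of adult cystic-fibrosis subjects, one row
per subject, mixing continuous (spirometry, anthropometry), binary
(pancreatic sufficiency, per-organism airway-culture presence) and
categorical (gender, CFTR mutation class group) variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variable",
    "CohortSchema",
    "Cohort",
    "SchemaError",
    "VocabularyError",
    "ORGANISMS",
    "GENDER_LEVELS",
    "CFTR_LEVELS",
    "EVENT_LEVELS",
    "default_schema",
    "load_cohort",
    "write_cohort",
    "derive_features",
    "severity_band",
    "aggregate_microbiology",
    "combo_trait",
    "validate_cohort",
]


class SchemaError(ValueError):
    """The file header or a variable definition does not match the schema."""


class VocabularyError(ValueError):
    """A value is outside its controlled vocabulary."""


# Sputum-culture organisms tracked as presence/absence flags.
ORGANISMS = (
    "pa",               # Pseudomonas spp.
    "mrsa",             # methicillin-resistant S. aureus
    "mssa",             # methicillin-sensitive S. aureus
    "achromobacter",
    "burkholderia",
    "stenotrophomonas",
    "candida",
    "aspergillus",
    "scedosporium",
    "mycobacteria",
)

GENDER_LEVELS = ("male", "female")
# Two class I/II/III mutations vs. at least one residual-function (IV/V/VI)
# mutation vs. compound heterozygotes with only one known mutation.
CFTR_LEVELS = ("two_class_I_II_III", "any_class_IV_V_VI", "unknown")
EVENT_LEVELS = ("none", "death", "transplant")


@dataclass(frozen=True)
class Variable:
    """One column of the cohort table."""

    name: str
    role: str  # 'continuous' | 'binary' | 'categorical'
    levels: tuple[str, ...] | None = None
    units: str = ""

    def __post_init__(self):
        if self.role not in ("continuous", "binary", "categorical"):
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.role == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(
                    f"categorical variable {self.name!r} needs >=2 levels"
                )


class CohortSchema:
    """Ordered collection of :class:`Variable` with unique names."""

    def __init__(self, variables: Iterable[Variable]):
        self.variables: tuple[Variable, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        self._by_name = {v.name: v for v in self.variables}

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.variables)

    def __len__(self):
        return len(self.variables)

    def subset(self, names: Sequence[str]) -> "CohortSchema":
        return CohortSchema(self._by_name[n] for n in names)


def default_schema(organisms: Sequence[str] = ORGANISMS) -> CohortSchema:
    """The common clinical variables used for phenotyping an adult CF clinic
    population: demographics, CFTR group, spirometry, anthropometry, chest
    radiograph score, pancreatic sufficiency, and airway microbiology flags.
    """
    variables = [
        Variable("age", "continuous", units="years"),
        Variable("gender", "categorical", GENDER_LEVELS),
        Variable("cftr_group", "categorical", CFTR_LEVELS),
        Variable("fev1_pct", "continuous", units="% predicted"),
        Variable("fvc_pct", "continuous", units="% predicted"),
        Variable("height", "continuous", units="m"),
        Variable("weight", "continuous", units="kg"),
        Variable("bmi", "continuous", units="kg/m^2"),
        Variable("brasfield", "continuous", units="score (0-25)"),
        Variable("age_fev1_product", "continuous", units="years·%"),
        Variable("pancreatic_sufficient", "binary"),
    ]
    variables += [Variable(org, "binary") for org in organisms]
    return CohortSchema(variables)


@dataclass
class Cohort:
    """A complete-case subject table plus its variable schema.

    ``data`` is indexed by unique subject id and holds one column per schema
    variable; an optional non-schema column ``event`` records death or
    transplant.
    """

    data: pd.DataFrame
    schema: CohortSchema
    label: str = ""

    def __post_init__(self):
        if not self.data.index.is_unique:
            raise SchemaError("subject ids are not unique")
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"columns missing from cohort table: {missing}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.schema, self.label)


def validate_cohort(cohort: Cohort, rtol_bmi: float = 1e-6) -> list[str]:
    """Return a list of invariant violations (empty when the cohort is valid).

    Checks positivity of anthropometric and spirometric values, the Brasfield
    score range, internal consistency of BMI with height/weight and of the
    age x FEV1% product with its factors, and controlled vocabularies.
    """
    df = cohort.data
    problems: list[str] = []

    def _bad(mask, msg):
        if np.asarray(mask).any():
            ids = list(df.index[np.asarray(mask)][:5])
            problems.append(f"{msg} (e.g. {ids})")

    for col in ("age", "fev1_pct", "fvc_pct", "height", "weight"):
        _bad(~(df[col] > 0) | ~np.isfinite(df[col]), f"{col} must be finite and > 0")
    _bad((df["brasfield"] < 0) | (df["brasfield"] > 25), "brasfield outside [0, 25]")
    bmi = df["weight"] / df["height"] ** 2
    _bad(~np.isclose(df["bmi"], bmi, rtol=rtol_bmi), "bmi != weight/height^2")
    prod = df["age"] * df["fev1_pct"]
    _bad(
        ~np.isclose(df["age_fev1_product"], prod, rtol=1e-9),
        "age_fev1_product != age * fev1_pct",
    )
    _bad(~df["gender"].isin(GENDER_LEVELS), "gender outside vocabulary")
    _bad(~df["cftr_group"].isin(CFTR_LEVELS), "cftr_group outside vocabulary")
    for var in cohort.schema:
        if var.role == "binary":
            _bad(~df[var.name].isin([0, 1, True, False]), f"{var.name} not 0/1")
    if "event" in df.columns:
        _bad(~df["event"].isin(EVENT_LEVELS), "event outside vocabulary")
    return problems


# ---------------------------------------------------------------------------
# Delimited I/O (complete-case policy: rows with missing values are rejected
# and reported, mirroring exclusion of incomplete records from the analysis).
# ---------------------------------------------------------------------------

def load_cohort(
    path,
    schema: CohortSchema | None = None,
    label: str = "",
    sep: str = ",",
    height_in_cm: bool = False,
) -> tuple[Cohort, pd.DataFrame]:
    """Read a cohort table, returning ``(cohort, rejections)``.

    The file must have a header with an ``id`` column and every schema
    variable. Rows with any missing or unparseable required value are
    rejected; the rejection report has columns ``line`` (1-based file line)
    and ``reason``.
    """
    if schema is None:
        schema = default_schema()
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "id" not in raw.columns:
        raise SchemaError("cohort table must have an 'id' column")
    missing_cols = [n for n in schema.names if n not in raw.columns]
    if missing_cols:
        raise SchemaError(f"cohort table is missing columns: {missing_cols}")

    rows: list[dict] = []
    rejected: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(raw.iterrows()):
        line = pos + 2  # 1-based, after the header line
        parsed: dict = {"id": row["id"].strip()}
        reason = None
        for var in schema:
            cell = row[var.name].strip()
            if cell == "":
                reason = f"missing value for {var.name}"
                break
            try:
                if var.role == "continuous":
                    parsed[var.name] = float(cell)
                elif var.role == "binary":
                    if cell not in ("0", "1"):
                        raise ValueError(cell)
                    parsed[var.name] = int(cell)
                else:
                    if cell not in var.levels:
                        raise ValueError(cell)
                    parsed[var.name] = cell
            except ValueError:
                reason = f"unparseable value {cell!r} for {var.name}"
                break
        if reason is None and "event" in raw.columns:
            ev = row["event"].strip() or "none"
            if ev not in EVENT_LEVELS:
                reason = f"unparseable value {ev!r} for event"
            else:
                parsed["event"] = ev
        if reason is None and not parsed["id"]:
            reason = "missing subject id"
        if reason is not None:
            rejected.append((line, reason))
        else:
            rows.append(parsed)

    data = pd.DataFrame(rows)
    if data.empty:
        data = pd.DataFrame(columns=["id"] + schema.names)
    if height_in_cm:
        data["height"] = data["height"] / 100.0
    data = data.set_index("id")
    rejections = pd.DataFrame(rejected, columns=["line", "reason"])
    return Cohort(data, schema, label), rejections


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write the cohort so that ``load_cohort`` round-trips it exactly.

    Booleans are encoded 0/1; floats use Python repr, which round-trips
    bit-identically.
    """
    df = cohort.data.copy()
    for var in cohort.schema:
        if var.role == "binary":
            df[var.name] = df[var.name].astype(int)
    df.index.name = "id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Derived clinical variables
# ---------------------------------------------------------------------------

def derive_features(cohort: Cohort, mismatch_warn: float = 0.01) -> Cohort:
    """Populate BMI (kg/m^2) and the age x FEV1% product.

    The product of age and best FEV1% predicted serves as an accrued
    lung-health score. Stored values disagreeing with recomputation by more
    than ``mismatch_warn`` (relative) trigger a warning; recomputed values
    always win, making the operation idempotent.
    """
    df = cohort.data.copy()
    if (df["height"] <= 0).any():
        raise ValueError("height must be positive to compute BMI")
    bmi = df["weight"] / df["height"] ** 2
    prod = df["age"] * df["fev1_pct"]
    for name, new in (("bmi", bmi), ("age_fev1_product", prod)):
        if name in df.columns:
            old = pd.to_numeric(df[name], errors="coerce")
            stored = old.notna()
            off = stored & ~np.isclose(old, new, rtol=mismatch_warn)
            if off.any():
                warnings.warn(
                    f"stored {name} disagrees with recomputation for "
                    f"{int(off.sum())} subject(s); overwriting",
                    stacklevel=2,
                )
        df[name] = new
    return Cohort(df, cohort.schema, cohort.label)


def severity_band(
    product: float, cutoffs: tuple[float, float] = (1000.0, 1600.0)
) -> str:
    """Band an age x FEV1% product into severe / moderate / mild.

    Populations divide at products of approximately 1000 and 1600; the
    boundary convention here is severe < 1000 <= moderate <= 1600 < mild.
    """
    lo, hi = cutoffs
    if product < 0:
        raise ValueError("age*FEV1% product cannot be negative")
    if product < lo:
        return "severe"
    if product <= hi:
        return "moderate"
    return "mild"


# ---------------------------------------------------------------------------
# Microbiology aggregation
# ---------------------------------------------------------------------------

def aggregate_microbiology(
    records: pd.DataFrame,
    reference_date: "date | Mapping[str, date] | pd.Series",
    organisms: Sequence[str] = ORGANISMS,
    min_positive: int = 2,
) -> pd.DataFrame:
    """Aggregate raw culture records into per-subject presence flags.

    An organism is called present iff it was identified in at least
    ``min_positive`` positive sputum cultures in the 365 days up to and
    including the subject's reference date. ``records`` needs columns
    ``subject_id``, ``date`` (ISO-8601), ``organism``, ``positive``.
    """
    rec = records.copy()
    unknown = set(rec["organism"]) - set(organisms)
    if unknown:
        raise VocabularyError(f"unknown organism(s): {sorted(unknown)}")
    rec["date"] = pd.to_datetime(rec["date"])
    subjects = sorted(rec["subject_id"].unique())

    def _ref(sid) -> pd.Timestamp:
        if isinstance(reference_date, (pd.Series, Mapping)):
            return pd.Timestamp(reference_date[sid])
        return pd.Timestamp(reference_date)

    flags = pd.DataFrame(0, index=pd.Index(subjects, name="subject_id"),
                         columns=list(organisms), dtype=int)
    for sid, grp in rec.groupby("subject_id"):
        ref = _ref(sid)
        window = grp[
            (grp["date"] > ref - timedelta(days=365)) & (grp["date"] <= ref)
        ]
        pos = window[window["positive"].astype(bool)]
        counts = pos.groupby("organism").size()
        for org, cnt in counts.items():
            if cnt >= min_positive:
                flags.loc[sid, org] = 1
    return flags


def combo_trait(flag_a, flag_b):
    """Combination trait: logical AND of two presence flags (e.g. PA with
    Candida spp., or MSSA with Aspergillus spp.)."""
    a = np.asarray(flag_a).astype(bool)
    b = np.asarray(flag_b).astype(bool)
    out = (a & b).astype(int)
    if isinstance(flag_a, pd.Series):
        return pd.Series(out, index=flag_a.index)
    return out
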