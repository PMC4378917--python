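"""Synthetic adult-CF-like cohort generator with known latent classes.

Real clinic cohorts of this kind are not publicly deposited, so every
pipeline stage is exercised against simulated cohorts with ground truth:
subjects are drawn from a mixture of latent classes, each class specifying
truncated-normal parameters for the continuous clinical variables
(physiologic bounds keep values plausible), a male probability, pancreatic
sufficiency and CFTR-group probabilities, and per-organism culture-presence
prevalences. BMI and the age x FEV1% product are computed, never drawn, so
the cohort invariants hold by construction. A paired follow-up generator
emulates a re-assessment a few years later: subjects persist in class with
a per-class probability, occasionally move class, die or are transplanted
with a per-class hazard, and new subjects are accrued.

All preset parameter values are synthetic choices for qualitative realism;
none is a measurement from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import (
    CFTR_LEVELS,
    ORGANISMS,
    Cohort,
    CohortSchema,
    Variable,
    default_schema,
)

__all__ = [
    "ClassSpec",
    "FollowupConfig",
    "SimConfig",
    "ConfigError",
    "TRUNCATION_BOUNDS",
    "simulate_cohort",
    "simulate_followup",
    "preset",
    "PRESETS",
]


class ConfigError(ValueError):
    """A simulation configuration is infeasible."""


# Plausible adult-CF physiologic ranges used to truncate the class-conditional
# normal draws (synthetic design choices, not measurements).
TRUNCATION_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 80.0),
    "fev1_pct": (15.0, 140.0),
    "fvc_pct": (20.0, 150.0),
    "height": (1.40, 2.00),
    "weight": (35.0, 120.0),
    "brasfield": (3.0, 25.0),
}

_CONTINUOUS = ("age", "fev1_pct", "fvc_pct", "height", "weight", "brasfield")


@dataclass(frozen=True)
class ClassSpec:
    """One latent class: truncated-normal (mean, sd) per continuous variable,
    plus gender/trait probabilities."""

    name: str
    mixing_weight: float
    means: Mapping[str, float]
    sds: Mapping[str, float]
    male_probability: float = 0.5
    ps_probability: float = 0.15
    cftr_probs: tuple[float, float, float] = (0.80, 0.10, 0.10)
    organism_prevalence: Mapping[str, float] = field(default_factory=dict)

    def prevalence(self, organism: str) -> float:
        return float(self.organism_prevalence.get(organism, 0.10))

    def validate(self) -> None:
        if not 0 < self.mixing_weight <= 1:
            raise ConfigError(f"{self.name}: mixing weight outside (0, 1]")
        for v in _CONTINUOUS:
            if v not in self.means or v not in self.sds:
                raise ConfigError(f"{self.name}: missing mean/sd for {v}")
            if self.sds[v] <= 0:
                raise ConfigError(f"{self.name}: sd for {v} must be positive")
            lo, hi = TRUNCATION_BOUNDS[v]
            if not lo <= self.means[v] <= hi:
                raise ConfigError(
                    f"{self.name}: mean for {v} outside bounds [{lo}, {hi}]"
                )
        probs = [self.male_probability, self.ps_probability, *self.cftr_probs]
        probs += [self.prevalence(o) for o in ORGANISMS]
        if any(not 0 <= q <= 1 for q in probs):
            raise ConfigError(f"{self.name}: probability outside [0, 1]")
        if abs(sum(self.cftr_probs) - 1) > 1e-9:
            raise ConfigError(f"{self.name}: cftr_probs must sum to 1")


@dataclass(frozen=True)
class FollowupConfig:
    """Paired re-assessment: per-class persistence probability, continuous
    drift (in units of the class sd), per-class death/transplant hazard over
    the gap, and a target size reached by accruing new subjects."""

    persistence: float | Mapping[str, float] = 0.8
    drift_sd: float = 0.3
    event_hazard: float | Mapping[str, float] = 0.0
    years_gap: float = 3.0
    target_n: int | None = None

    def persist_p(self, cls: str) -> float:
        p = self.persistence
        return float(p[cls]) if isinstance(p, Mapping) else float(p)

    def hazard(self, cls: str) -> float:
        h = self.event_hazard
        return float(h[cls]) if isinstance(h, Mapping) else float(h)


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int
    class_specs: tuple[ClassSpec, ...]
    n_noise_variables: int = 0
    n_noise_traits: int = 0
    noise_trait_prevalence: float = 0.3
    seed: int = 0
    followup: FollowupConfig | None = None

    def validate(self) -> None:
        k = len(self.class_specs)
        if self.n_subjects < k:
            raise ConfigError("need at least one subject per class")
        for spec in self.class_specs:
            spec.validate()
        total = sum(s.mixing_weight for s in self.class_specs)
        if abs(total - 1) > 1e-9:
            raise ConfigError("mixing weights must sum to 1")

    def schema(self) -> CohortSchema:
        variables = list(default_schema())
        variables += [
            Variable(f"noise_{j + 1:02d}", "continuous")
            for j in range(self.n_noise_variables)
        ]
        variables += [
            Variable(f"noise_trait_{j + 1:02d}", "binary")
            for j in range(self.n_noise_traits)
        ]
        return CohortSchema(variables)


def _draw_truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_subject_block(rng, spec: ClassSpec, size: int) -> dict[str, np.ndarray]:
    """Class-conditional draws for ``size`` subjects of one class."""
    out: dict[str, np.ndarray] = {}
    for v in _CONTINUOUS:
        lo, hi = TRUNCATION_BOUNDS[v]
        out[v] = _draw_truncnorm(rng, spec.means[v], spec.sds[v], lo, hi, size)
    # keep the spirometric relation plausible: FVC% at least 0.9 x FEV1%
    out["fvc_pct"] = np.clip(
        np.maximum(out["fvc_pct"], 0.9 * out["fev1_pct"]),
        *TRUNCATION_BOUNDS["fvc_pct"],
    )
    out["brasfield"] = np.round(out["brasfield"]).clip(3, 25)
    out["gender"] = np.where(
        rng.random(size) < spec.male_probability, "male", "female"
    )
    out["pancreatic_sufficient"] = (
        rng.random(size) < spec.ps_probability
    ).astype(int)
    out["cftr_group"] = rng.choice(CFTR_LEVELS, size=size, p=spec.cftr_probs)
    for org in ORGANISMS:
        out[org] = (rng.random(size) < spec.prevalence(org)).astype(int)
    return out


def _finalise(df: pd.DataFrame) -> pd.DataFrame:
    df["bmi"] = df["weight"] / df["height"] ** 2
    df["age_fev1_product"] = df["age"] * df["fev1_pct"]
    return df


def simulate_cohort(config: SimConfig) -> tuple[Cohort, np.ndarray]:
    """Draw a cohort from the latent-class mixture; returns the cohort and
    the true class labels (class-spec names), fully reproducible from
    ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    k = len(config.class_specs)
    weights = np.array([s.mixing_weight for s in config.class_specs])
    assignment = rng.choice(k, size=config.n_subjects, p=weights)

    columns: dict[str, np.ndarray] = {}
    n = config.n_subjects
    for name in _CONTINUOUS:
        columns[name] = np.empty(n)
    columns["gender"] = np.empty(n, dtype=object)
    columns["cftr_group"] = np.empty(n, dtype=object)
    columns["pancreatic_sufficient"] = np.empty(n, dtype=int)
    for org in ORGANISMS:
        columns[org] = np.empty(n, dtype=int)
    for ci, spec in enumerate(config.class_specs):
        idx = np.nonzero(assignment == ci)[0]
        if idx.size == 0:
            continue
        block = _draw_subject_block(rng, spec, idx.size)
        for name, vals in block.items():
            columns[name][idx] = vals
    for j in range(config.n_noise_variables):
        columns[f"noise_{j + 1:02d}"] = rng.standard_normal(n)
    for j in range(config.n_noise_traits):
        columns[f"noise_trait_{j + 1:02d}"] = (
            rng.random(n) < config.noise_trait_prevalence
        ).astype(int)

    ids = [f"S{i + 1:04d}" for i in range(n)]
    df = _finalise(pd.DataFrame(columns, index=pd.Index(ids, name="id")))
    df["event"] = "none"
    labels = np.array([config.class_specs[c].name for c in assignment])
    return Cohort(df, config.schema(), label="baseline"), labels


def simulate_followup(
    cohort: Cohort, labels: np.ndarray, config: SimConfig
) -> tuple[Cohort, np.ndarray, pd.DataFrame]:
    """Generate the paired follow-up cohort.

    Each baseline subject either suffers an event (death/transplant, removed
    from follow-up and reported), persists in class (continuous variables
    drift), or moves to another class (class-conditional variables redrawn).
    Ages always advance by the configured gap. New subjects are accrued up
    to ``target_n``. Returns ``(followup_cohort, labels, events)``.
    """
    fu = config.followup or FollowupConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    spec_by_name = {s.name: s for s in config.class_specs}
    names = [s.name for s in config.class_specs]

    rows: list[pd.Series] = []
    out_labels: list[str] = []
    events: list[tuple[str, str]] = []
    for sid, cls in zip(cohort.ids, labels):
        spec = spec_by_name[cls]
        if rng.random() < fu.hazard(cls):
            kind = "death" if rng.random() < 0.5 else "transplant"
            events.append((sid, kind))
            continue
        row = cohort.data.loc[sid].copy()
        if rng.random() < fu.persist_p(cls):
            new_cls = cls
            for v in ("fev1_pct", "fvc_pct", "weight", "brasfield"):
                lo, hi = TRUNCATION_BOUNDS[v]
                drift = rng.normal(0.0, fu.drift_sd * spec.sds[v])
                row[v] = float(np.clip(row[v] + drift, lo, hi))
        else:
            others = [m for m in names if m != cls] or [cls]
            new_cls = others[rng.integers(len(others))]
            block = _draw_subject_block(rng, spec_by_name[new_cls], 1)
            for key, vals in block.items():
                if key == "gender":
                    continue  # identity is retained
                row[key] = vals[0]
        row["age"] = float(
            np.clip(cohort.data.loc[sid, "age"] + fu.years_gap,
                    *TRUNCATION_BOUNDS["age"])
        )
        row["brasfield"] = float(np.round(row["brasfield"]))
        rows.append(row.rename(sid))
        out_labels.append(new_cls)

    target = fu.target_n if fu.target_n is not None else len(rows)
    n_new = max(0, target - len(rows))
    if n_new:
        weights = np.array([s.mixing_weight for s in config.class_specs])
        new_assign = rng.choice(len(names), size=n_new, p=weights)
        for i, ci in enumerate(new_assign):
            block = _draw_subject_block(rng, config.class_specs[ci], 1)
            row = pd.Series({key: vals[0] for key, vals in block.items()})
            for j in range(config.n_noise_variables):
                row[f"noise_{j + 1:02d}"] = rng.standard_normal()
            for j in range(config.n_noise_traits):
                row[f"noise_trait_{j + 1:02d}"] = int(
                    rng.random() < config.noise_trait_prevalence
                )
            rows.append(row.rename(f"N{i + 1:04d}"))
            out_labels.append(names[ci])

    df = pd.DataFrame(rows)
    df.index.name = "id"
    df = _finalise(df)
    df["event"] = "none"
    for var in cohort.schema:
        if var.role == "binary":
            df[var.name] = df[var.name].astype(int)
    events_df = pd.DataFrame(events, columns=["subject_id", "event"])
    return (
        Cohort(df, cohort.schema, label="followup"),
        np.asarray(out_labels),
        events_df,
    )


# ---------------------------------------------------------------------------
# Presets (all values synthetic; qualitative correspondence only)
# ---------------------------------------------------------------------------

def _spec(name, w, age, fev1, fvc, height, weight, brasfield, male, ps,
          cftr, organisms):
    means = {"age": age[0], "fev1_pct": fev1[0], "fvc_pct": fvc[0],
             "height": height[0], "weight": weight[0], "brasfield": brasfield[0]}
    sds = {"age": age[1], "fev1_pct": fev1[1], "fvc_pct": fvc[1],
           "height": height[1], "weight": weight[1], "brasfield": brasfield[1]}
    return ClassSpec(name, w, means, sds, male, ps, cftr, organisms)


def _fig4_like_k5() -> SimConfig:
    """Five classes qualitatively echoing the published phenotype structure:
    a low lung-health, poorly nourished class; an older male class with low
    lung health; a median, female-dominated class; a well-nourished,
    high lung-health, male-dominated, pancreatic-sufficiency-enriched class;
    and a young female class with low accrued lung health. Synthetic values."""
    specs = (
        _spec("low_health", 0.22, (29, 5), (32, 7), (48, 9), (1.65, 0.07),
              (50, 6), (9, 2), 0.50, 0.03, (0.90, 0.02, 0.08),
              {"pa": 0.80, "candida": 0.65, "mssa": 0.20, "aspergillus": 0.20}),
        _spec("older_male", 0.18, (42, 5), (36, 7), (52, 9), (1.76, 0.06),
              (70, 8), (13, 2), 0.85, 0.05, (0.85, 0.05, 0.10),
              {"pa": 0.75, "candida": 0.45, "mssa": 0.20, "aspergillus": 0.15}),
        _spec("median_female", 0.22, (30, 5), (62, 8), (78, 9), (1.62, 0.06),
              (58, 7), (18, 2), 0.15, 0.10, (0.80, 0.10, 0.10),
              {"pa": 0.25, "candida": 0.30, "mssa": 0.60, "aspergillus": 0.50}),
        _spec("mild_male", 0.20, (36, 5), (88, 9), (98, 9), (1.79, 0.06),
              (79, 8), (22, 1.5), 0.85, 0.50, (0.45, 0.45, 0.10),
              {"pa": 0.20, "candida": 0.08, "mssa": 0.25, "aspergillus": 0.10}),
        _spec("young_female", 0.18, (24, 4), (52, 8), (68, 9), (1.63, 0.06),
              (57, 6), (16, 2), 0.15, 0.10, (0.80, 0.10, 0.10),
              {"pa": 0.45, "candida": 0.35, "mssa": 0.30, "aspergillus": 0.20}),
    )
    followup = FollowupConfig(
        persistence={"low_health": 0.78, "older_male": 0.94,
                     "median_female": 0.78, "mild_male": 0.95,
                     "young_female": 0.85},
        drift_sd=0.3,
        event_hazard={"low_health": 0.12, "older_male": 0.08,
                      "median_female": 0.01, "mild_male": 0.01,
                      "young_female": 0.03},
        years_gap=3.0,
        target_n=211,
    )
    return SimConfig(211, specs, followup=followup)


def _separable_k3() -> SimConfig:
    """Three classes separated by >= 3 sd on several variables, with a
    strong PA enrichment (0.8 vs 0.1) in the sickest class."""
    base_org = {"pa": 0.10, "candida": 0.20, "mssa": 0.30, "aspergillus": 0.15}
    specs = (
        _spec("sick", 1 / 3, (25, 3), (30, 6), (45, 7), (1.60, 0.05),
              (48, 5), (7, 1.5), 0.5, 0.10, (0.85, 0.05, 0.10),
              dict(base_org, pa=0.80)),
        _spec("middle", 1 / 3, (35, 3), (70, 6), (82, 7), (1.70, 0.05),
              (63, 5), (15, 1.5), 0.5, 0.15, (0.80, 0.10, 0.10), base_org),
        _spec("mild", 1 / 3, (50, 3), (110, 6), (118, 7), (1.80, 0.05),
              (80, 5), (23, 1.5), 0.5, 0.30, (0.60, 0.30, 0.10), base_org),
    )
    return SimConfig(150, specs,
                     followup=FollowupConfig(persistence=0.8, event_hazard=0.0))


def _noise_heavy() -> SimConfig:
    """Four classes that differ only in the eight lung-health / nutrition
    variables (age, FEV1%, FVC%, height, weight, BMI, age x FEV1% product,
    Brasfield); gender, CFTR group and all traits are identically
    distributed across classes, and ten pure-noise continuous variables are
    appended. Informative-variable selection should recover exactly the
    eight."""
    flat_org = {org: 0.25 for org in ORGANISMS}
    cftr = (0.80, 0.10, 0.10)
    specs = (
        _spec("c1", 0.25, (25, 3), (35, 6), (50, 7), (1.55, 0.04),
              (45, 4), (6, 1.5), 0.5, 0.2, cftr, flat_org),
        _spec("c2", 0.25, (35, 3), (65, 6), (78, 7), (1.65, 0.04),
              (60, 4), (12, 1.5), 0.5, 0.2, cftr, flat_org),
        _spec("c3", 0.25, (45, 3), (95, 6), (105, 7), (1.75, 0.04),
              (75, 4), (18, 1.5), 0.5, 0.2, cftr, flat_org),
        _spec("c4", 0.25, (55, 3), (125, 6), (132, 7), (1.85, 0.04),
              (90, 4), (24, 1.5), 0.5, 0.2, cftr, flat_org),
    )
    return SimConfig(200, specs, n_noise_variables=10,
                     followup=FollowupConfig(persistence=0.8))


def _null_one_class() -> SimConfig:
    """A single homogeneous class: any partition of it is arbitrary."""
    specs = (
        _spec("only", 1.0, (33, 8), (70, 15), (84, 15), (1.70, 0.08),
              (65, 10), (15, 4), 0.5, 0.15, (0.80, 0.10, 0.10),
              {"pa": 0.45, "candida": 0.30}),
    )
    return SimConfig(150, specs)


PRESETS = {
    "fig4_like_k5": _fig4_like_k5,
    "separable_k3": _separable_k3,
    "noise_heavy": _noise_heavy,
    "null_one_class": _null_one_class,
}


def preset(name: str, n: int | None = None, seed: int | None = None) -> SimConfig:
    """A documented, shipped simulation configuration by name."""
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    config = PRESETS[name]()
    if n is not None:
        config = replace(config, n_subjects=n)
    if seed is not None:
        config = replace(config, seed=seed)
    return config
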