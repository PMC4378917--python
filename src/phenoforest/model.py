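"""Two-stage unsupervised random-forest phenotyping.

``PhenotypeModel`` is built from a :class:`~phenoforest.cohort.Cohort` and a
:class:`PipelineConfig`; ``fit()`` executes the six-step procedure and
returns a :class:`PhenotypeResults` carrying the class assignments and all
stage-wise diagnostics:

1. unsupervised random forest on all clinical variables -> proximity P1;
2. PAM on 1 - P1 at the chosen k -> initial classes;
3. supervised random forest on the initial classes -> OOB error and
   permutation variable importance;
4. unsupervised forest repeated on the top-m most important variables
   (dimension reduction) -> proximity P2;
5. PAM on 1 - P2 -> final classes;
6. supervised forest on the final classes -> OOB error and confusion
   matrix, plus classical MDS of 1 - P2 for visual separation.

Class letters A, B, C, ... are assigned by ascending class mean of the
age x FEV1% product, so the letter A always denotes the lowest accrued
lung-health class.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ORGANISMS
from .forest import (
    Forest,
    ForestConfig,
    ImportanceReport,
    OOBResult,
    ProximityMatrix,
    compute_proximity,
    encode_features,
    fit_supervised_forest,
    fit_unsupervised_forest,
    oob_evaluate,
    permutation_importance,
)
from .mds import Embedding, classical_mds
from .pam import Clustering, pam

__all__ = [
    "PipelineConfig",
    "StageDiagnostics",
    "PhenotypeModel",
    "PhenotypeResults",
    "run_two_stage",
    "select_top_variables",
    "profile_classes",
]

_PROFILE_MEANS = ("fev1_pct", "fvc_pct", "brasfield", "age",
                  "age_fev1_product", "bmi")


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline settings: number of classes ``k``, number of variables kept
    after dimension reduction (default 8), forest hyper-parameters, and
    optional include/exclude variable lists."""

    k: int
    n_top_variables: int = 8
    forest: ForestConfig = field(default_factory=ForestConfig)
    include: tuple[str, ...] | None = None
    exclude: tuple[str, ...] = ()
    consensus_k: tuple[int, ...] | None = None
    oob_proximity: bool = False
    mds_dims: int = 2

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class StageDiagnostics:
    proximity: ProximityMatrix
    clustering: Clustering
    oob: OOBResult
    importance: ImportanceReport | None = None


def select_top_variables(report: ImportanceReport, m: int) -> list[str]:
    """Top ``m`` variables by mean decrease in OOB accuracy (ties break to
    the lower variable index, already encoded in the report's rank)."""
    if m > len(report.table):
        raise ValueError(f"cannot select {m} of {len(report.table)} variables")
    return report.top(m)


def profile_classes(cohort: Cohort, labels: pd.Series,
                    traits: Sequence[str] = ORGANISMS) -> pd.DataFrame:
    """Per-class profile: size, means of the six profile variables
    (FEV1%, FVC%, Brasfield, age, age x FEV1% product, BMI), fraction male,
    and trait prevalences (pancreatic sufficiency plus organism flags)."""
    df = cohort.data
    lab = labels.loc[cohort.ids]
    rows = []
    for cls in sorted(lab.unique()):
        sub = df[(lab == cls).to_numpy()]
        if len(sub) == 0:
            raise ValueError(f"class {cls!r} is empty")
        row = {"class": cls, "n": len(sub)}
        for v in _PROFILE_MEANS:
            row[f"mean_{v}"] = float(sub[v].mean())
        row["fraction_male"] = float((sub["gender"] == "male").mean())
        row["prev_pancreatic_sufficient"] = float(
            sub["pancreatic_sufficient"].astype(float).mean()
        )
        for t in traits:
            if t in sub.columns:
                row[f"prev_{t}"] = float(sub[t].astype(float).mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    assert int(out["n"].sum()) == cohort.n
    return out


def _letters(k: int) -> list[str]:
    return list(string.ascii_uppercase[:k])


class PhenotypeModel:
    """Unsupervised phenotyping model for a clinical cohort.

    Parameters
    ----------
    cohort : Cohort
        Complete-case subject table with schema.
    config : PipelineConfig
        k, dimension-reduction size, and forest settings.
    """

    def __init__(self, cohort: Cohort, config: PipelineConfig):
        self.cohort = cohort
        self.config = config
        names = list(config.include) if config.include is not None \
            else cohort.schema.names
        self.variables = [n for n in names if n not in config.exclude]
        if config.n_top_variables > len(self.variables):
            raise ValueError("n_top_variables exceeds the number of variables")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema, config: PipelineConfig,
                       label: str = "") -> "PhenotypeModel":
        return cls(Cohort(df, schema, label), config)

    # -- internal ----------------------------------------------------------
    def _stage(self, variables: Sequence[str], seed: int, want_importance: bool):
        """One unsupervised-forest -> PAM -> supervised-forest pass."""
        cfg = replace(self.config.forest, seed=int(seed))
        X, col_kind, names = encode_features(self.cohort, variables)
        unsup = fit_unsupervised_forest(X, cfg, col_kind, names)
        prox = compute_proximity(unsup, X, ids=self.cohort.ids,
                                 oob_only=self.config.oob_proximity)
        clust = pam(prox.dissimilarity(), self.config.k)
        sup = fit_supervised_forest(X, clust.assignment, cfg, col_kind, names)
        oob = oob_evaluate(sup, X, clust.assignment)
        imp = permutation_importance(sup, X, clust.assignment) \
            if want_importance else None
        return X, StageDiagnostics(prox, clust, oob, imp), unsup, sup

    def _consensus_importance(self, X, col_kind, names, seed) -> ImportanceReport:
        """Average importance ranks over several k (used with consensus_k)."""
        cfg = replace(self.config.forest, seed=int(seed))
        unsup = fit_unsupervised_forest(X, cfg, col_kind, names)
        prox = compute_proximity(unsup, X, oob_only=self.config.oob_proximity)
        ranks = []
        table = None
        for kk in self.config.consensus_k:
            clust = pam(prox.dissimilarity(), kk)
            sup = fit_supervised_forest(X, clust.assignment, cfg, col_kind, names)
            rep = permutation_importance(sup, X, clust.assignment)
            ranks.append(rep.table["rank"].to_numpy())
            table = rep.table
        mean_rank = np.mean(ranks, axis=0)
        order = np.lexsort((np.arange(len(mean_rank)), mean_rank))
        rank = np.empty(len(mean_rank), dtype=int)
        rank[order] = np.arange(1, len(mean_rank) + 1)
        out = table.copy()
        out["rank"] = rank
        return ImportanceReport(out)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "PhenotypeResults":
        """Run the full two-stage procedure; deterministic given the forest
        seed."""
        seeds = np.random.SeedSequence(self.config.forest.seed).generate_state(4)
        X1, stage1, _, _ = self._stage(self.variables, seeds[0],
                                       want_importance=True)
        if self.config.consensus_k:
            _, col_kind, names = encode_features(self.cohort, self.variables)
            importance = self._consensus_importance(X1, col_kind, names, seeds[0])
        else:
            importance = stage1.importance
        selected = select_top_variables(importance,
                                        self.config.n_top_variables)
        X2, stage2, _, _ = self._stage(selected, seeds[1],
                                       want_importance=False)
        embedding = classical_mds(stage2.proximity.dissimilarity(),
                                  dims=self.config.mds_dims,
                                  ids=self.cohort.ids)
        return PhenotypeResults(self, stage1, stage2, selected, embedding)


class PhenotypeResults:
    """Fitted phenotyping result: final class letters per subject, stage-wise
    OOB diagnostics, selected variables, MDS coordinates, and class
    profiles."""

    def __init__(self, model: PhenotypeModel, stage1: StageDiagnostics,
                 stage2: StageDiagnostics, selected_variables: list[str],
                 embedding: Embedding):
        self.model = model
        self.stage1 = stage1
        self.stage2 = stage2
        self.selected_variables = selected_variables
        self.embedding = embedding
        self.labels = self._letter_labels()
        self.profiles = profile_classes(model.cohort, self.labels)

    def _letter_labels(self) -> pd.Series:
        """Letter classes ordered by ascending mean age x FEV1% product."""
        cohort = self.model.cohort
        assign = self.stage2.clustering.assignment
        prod = cohort.data["age_fev1_product"].to_numpy()
        k = self.stage2.clustering.k
        means = [prod[assign == c].mean() if (assign == c).any() else np.inf
                 for c in range(k)]
        order = np.argsort(np.asarray(means), kind="stable")
        letter_of = {int(c): L for L, c in zip(_letters(k), order)}
        return pd.Series([letter_of[int(a)] for a in assign],
                         index=cohort.data.index, name="class")

    @property
    def importance(self) -> ImportanceReport:
        return self.stage1.importance

    @property
    def oob_error_stage1(self) -> float:
        return self.stage1.oob.error_rate

    @property
    def oob_error_stage2(self) -> float:
        return self.stage2.oob.error_rate

    def class_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        lines = [
            "Multidimensional clinical phenotyping",
            "=" * 54,
            f"Cohort: {m.cohort.label or '(unlabelled)'}  n={m.cohort.n}  "
            f"k={m.config.k}",
            f"Forest: {m.config.forest.n_trees} trees, seed "
            f"{m.config.forest.seed}",
            f"Stage 1 (all {len(m.variables)} variables): "
            f"OOB error {self.oob_error_stage1:.1%}",
            f"Selected variables ({len(self.selected_variables)}): "
            + ", ".join(self.selected_variables),
            f"Stage 2 (reduced): OOB error {self.oob_error_stage2:.1%}",
            f"MDS negative-eigenvalue mass: "
            f"{self.embedding.negative_eigenvalue_mass:.3f}",
            "",
            "Class profiles:",
            self.profiles.set_index("class").round(2).to_string(),
        ]
        return "\n".join(lines)

    def plot_embedding(self, ax=None):
        """Class-coloured scatter of the first two MDS axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        coords = self.embedding.coordinates
        for cls in sorted(self.labels.unique()):
            mask = (self.labels == cls).to_numpy()
            ax.scatter(coords[mask, 0], coords[mask, 1], s=18, label=cls)
        ax.set_xlabel("MDS 1")
        ax.set_ylabel("MDS 2")
        ax.legend(title="class")
        ax.set_title("Phenotype separation (classical MDS of 1 - proximity)")
        return ax

    def save(self, outdir) -> None:
        """Write clustering, importance, confusion, proximity, embedding and
        profile CSVs under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.labels.rename("class").to_frame().assign(
            medoid_position=self.stage2.clustering.assignment
        ).to_csv(out / "clustering.csv", index_label="subject_id")
        self.stage1.importance.to_csv(out / "importance.csv")
        self.stage2.oob.confusion.to_csv(out / "confusion.csv")
        self.stage2.proximity.to_csv(out / "proximity.csv")
        self.embedding.to_csv(out / "embedding.csv")
        self.profiles.to_csv(out / "profiles.csv", index=False)


def run_two_stage(cohort: Cohort, config: PipelineConfig) -> PhenotypeResults:
    """Functional wrapper: ``PhenotypeModel(cohort, config).fit()``."""
    return PhenotypeModel(cohort, config).fit()
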