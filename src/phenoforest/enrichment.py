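"""Class-vs-nonclass trait enrichment.

For every (phenotype class, trait) pair, a 2x2 table of in-class vs
out-of-class by trait-present vs trait-absent is tested with the two-sided
Fisher exact test; p-values are corrected across the whole run with the
Benjamini-Hochberg step-up procedure (FDR). The reported odds ratio is the
conditional maximum-likelihood estimate, which is 0 or +inf for tables with
an empty cell — a class in which a prevalent trait never occurs reports
OR = 0. Combination traits (e.g. PA with Candida, MSSA with Aspergillus)
are logical ANDs of two presence flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, combo_trait

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "bh_adjust",
    "class_trait_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable:
    """a = in-class & trait present, b = in-class & absent,
    c = out-of-class & present, d = out-of-class & absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else np.nan
        return (self.a * self.d) / (self.b * self.c)


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact p and the conditional-MLE odds ratio.

    The p-value sums the hypergeometric probabilities (margins fixed) of all
    outcomes no more probable than the observed one. Degenerate tables:
    OR = 0 when a = 0, +inf when b = 0 or c = 0 while a and d are positive;
    a table with a zero margin (constant trait) has p = 1 and OR reported
    as 1.
    """
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0, 1.0
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    if table.a == 0:
        return p, 0.0
    if table.b == 0 or table.c == 0:
        return p, np.inf
    orr = float(_cmle_odds_ratio(arr, kind="conditional").statistic)
    return p, orr


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order:
    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def class_trait_enrichment(
    cohort: Cohort,
    class_labels: pd.Series,
    traits: Sequence[str],
    combos: Sequence[tuple[str, str]] = (),
    alpha: float = 0.05,
    bh_family: str = "per-run",
) -> pd.DataFrame:
    """Class-vs-nonclass Fisher tests for every trait and combination trait.

    ``class_labels`` maps subject id to class letter. Returns one row per
    (class, trait) with the 2x2 counts, conditional-MLE and sample odds
    ratios, raw and BH-adjusted p, and a significance flag at ``alpha``.
    ``bh_family`` is ``per-run`` (one family across all class x trait tests,
    the default) or ``per-trait``.
    """
    if bh_family not in ("per-run", "per-trait"):
        raise ValueError("bh_family must be 'per-run' or 'per-trait'")
    labels = class_labels.loc[cohort.ids]
    classes = sorted(labels.unique())
    flag_cols: dict[str, np.ndarray] = {}
    for t in traits:
        flag_cols[t] = cohort.data[t].to_numpy().astype(bool)
    for a_name, b_name in combos:
        name = f"{a_name}/{b_name}"
        flag_cols[name] = combo_trait(
            cohort.data[a_name], cohort.data[b_name]
        ).to_numpy().astype(bool)

    rows = []
    for cls in classes:
        in_cls = (labels == cls).to_numpy()
        for trait, flag in flag_cols.items():
            tab = ContingencyTable(
                a=int((in_cls & flag).sum()),
                b=int((in_cls & ~flag).sum()),
                c=int((~in_cls & flag).sum()),
                d=int((~in_cls & ~flag).sum()),
            )
            note = ""
            if flag.all() or not flag.any():
                p_raw, orr = 1.0, 1.0
                note = "trait constant across cohort"
            else:
                p_raw, orr = fisher_exact(tab)
            rows.append({
                "class": cls, "trait": trait,
                "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                "or_cmle": orr, "or_sample": tab.sample_odds_ratio,
                "p_raw": p_raw, "note": note,
            })
    out = pd.DataFrame(rows)
    if bh_family == "per-run":
        out["p_bh"] = bh_adjust(out["p_raw"].to_numpy())
    else:
        out["p_bh"] = np.nan
        for trait in out["trait"].unique():
            mask = out["trait"] == trait
            out.loc[mask, "p_bh"] = bh_adjust(out.loc[mask, "p_raw"].to_numpy())
    out["significant"] = out["p_bh"] < alpha
    return out
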