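"""Cross-cohort phenotype stability.

Two clusterings of cohorts a few years apart are compared on their shared
subjects: class labels are matched by maximum overlap (exact assignment),
transitions are counted under the matched labels, and two per-class
statistics are reported — the proportion of subjects leaving a phenotype
(p Transitions) and the fraction of all transitions arriving into a
phenotype (f Transitions) — together with per-class death/transplant
tallies. Subjects who died or were transplanted between the time points are
excluded from transition counts and appear only in the event tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["ClassMatching", "TransitionReport", "match_classes", "transition_report"]


@dataclass
class ClassMatching:
    """Injective mapping from time-0 class letters to time-1 class letters,
    chosen to maximise total overlap on the shared subjects."""

    mapping: dict
    overlap: pd.DataFrame  # rows = time-0 classes, columns = time-1 classes

    def inverse(self) -> dict:
        return {v: k for k, v in self.mapping.items()}


def match_classes(
    labels0: pd.Series, labels1: pd.Series, shared_ids: Sequence
) -> ClassMatching:
    """Optimal one-to-one label matching between two clusterings.

    Solved exactly with the Hungarian assignment on the negated overlap
    matrix (k <= 6 in practice, where exhaustive search over k! permutations
    gives the same optimum). Requires equal numbers of classes.
    """
    shared = list(shared_ids)
    l0 = labels0.loc[shared]
    l1 = labels1.loc[shared]
    c0 = sorted(labels0.unique())
    c1 = sorted(labels1.unique())
    if len(c0) != len(c1):
        raise ValueError(
            f"cannot match {len(c0)} classes to {len(c1)}; "
            "re-run both clusterings at the same k"
        )
    overlap = pd.DataFrame(0, index=c0, columns=c1, dtype=int)
    for a, b in zip(l0, l1):
        overlap.loc[a, b] += 1
    row, col = linear_sum_assignment(-overlap.to_numpy())
    mapping = {c0[r]: c1[c] for r, c in zip(row, col)}
    return ClassMatching(mapping, overlap)


@dataclass
class TransitionReport:
    shared_ids: list
    counts: pd.DataFrame          # origin class x destination class (matched labels)
    p_transitions: pd.Series      # per origin class: fraction of subjects leaving
    f_transitions: pd.Series      # per destination class: share of all transitions arriving
    events: pd.DataFrame          # per time-0 class: death and transplant counts
    n_transitions: int

    @property
    def overall_transition_fraction(self) -> float:
        total = self.counts.to_numpy().sum()
        return self.n_transitions / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "p_transitions": self.p_transitions,
            "f_transitions": self.f_transitions,
        })
        return out.join(self.events)


def transition_report(
    labels0: pd.Series,
    labels1: pd.Series,
    matching: ClassMatching,
    events: Mapping | pd.Series | None = None,
    shared_ids: Sequence | None = None,
) -> TransitionReport:
    """Count class transitions of shared subjects under matched labels.

    ``events`` maps subject id to 'death' or 'transplant' for subjects lost
    between the time points; they are tallied by their time-0 class and
    excluded from the transition counts.
    """
    ev = pd.Series(events, dtype=object) if events is not None else pd.Series(dtype=object)
    ev = ev[ev.isin(["death", "transplant"])]
    if shared_ids is None:
        shared_ids = [i for i in labels0.index if i in labels1.index]
    moved_ids = [i for i in shared_ids if i not in ev.index]

    classes = sorted(labels0.unique())
    inv = matching.inverse()
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for sid in moved_ids:
        origin = labels0.loc[sid]
        dest = inv[labels1.loc[sid]]  # destination in time-0 letter space
        counts.loc[origin, dest] += 1

    arr = counts.to_numpy()
    row_tot = arr.sum(axis=1)
    diag = np.diag(arr)
    leaving = row_tot - diag
    with np.errstate(invalid="ignore", divide="ignore"):
        p_trans = np.where(row_tot > 0, leaving / np.maximum(row_tot, 1), 0.0)
    n_trans = int(leaving.sum())
    arriving = arr.sum(axis=0) - diag
    f_trans = arriving / n_trans if n_trans > 0 else np.zeros(len(classes))

    event_counts = pd.DataFrame(0, index=classes, columns=["death", "transplant"], dtype=int)
    for sid, kind in ev.items():
        if sid in labels0.index:
            event_counts.loc[labels0.loc[sid], kind] += 1

    return TransitionReport(
        shared_ids=list(shared_ids),
        counts=counts,
        p_transitions=pd.Series(p_trans, index=classes),
        f_transitions=pd.Series(f_trans, index=classes),
        events=event_counts,
        n_transitions=n_trans,
    )
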