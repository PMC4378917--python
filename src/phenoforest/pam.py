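"""Partitioning Around Medoids (PAM) on a precomputed dissimilarity matrix.

Classical BUILD (greedy seeding) followed by steepest-descent SWAP: at each
iteration the single (medoid, non-medoid) exchange with the greatest total
cost reduction is applied, until no exchange reduces the cost. All ties
break to the lowest row index, so the algorithm is deterministic without a
seed. Works on any symmetric non-negative dissimilarity, in particular
D = 1 - proximity from a random forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Clustering", "pam_build", "pam_swap", "pam", "validate_dissimilarity"]

_EPS = 1e-12


def validate_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("dissimilarity diagonal must be zero")
    if D.min() < -1e-12:
        raise ValueError("dissimilarities must be non-negative")
    return D


@dataclass
class Clustering:
    """k-medoid partition: ``medoids`` are row indices in ascending order;
    ``assignment[i]`` is the position (0..k-1) of row i's medoid; each row is
    assigned to its nearest medoid (ties to the lowest medoid row index) and
    each medoid to itself."""

    k: int
    medoids: np.ndarray
    assignment: np.ndarray
    total_cost: float

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def to_frame(self, ids=None) -> pd.DataFrame:
        n = len(self.assignment)
        idx = ids if ids is not None else list(range(n))
        med_ids = [idx[m] for m in self.medoids]
        return pd.DataFrame({
            "subject_id": idx,
            "cluster": self.assignment,
            "medoid_id": [med_ids[a] for a in self.assignment],
        })


def _make_clustering(D: np.ndarray, medoids: np.ndarray) -> Clustering:
    medoids = np.sort(np.asarray(medoids, dtype=np.int64))
    sub = D[:, medoids]
    assignment = np.argmin(sub, axis=1)  # first min -> lowest medoid index
    assignment[medoids] = np.arange(len(medoids))  # medoids own themselves
    total_cost = float(sub[np.arange(len(D)), assignment].sum())
    return Clustering(len(medoids), medoids, assignment, total_cost)


def pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD phase: the first medoid minimises total dissimilarity to
    all rows; each further medoid maximises the decrease in total cost."""
    D = validate_dissimilarity(D)
    n = len(D)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    for _ in range(k - 1):
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))  # first max -> lowest index
        medoids.append(c)
        nearest = np.minimum(nearest, D[:, c])
    return np.sort(np.asarray(medoids, dtype=np.int64))


def pam_swap(D: np.ndarray, medoids: np.ndarray) -> Clustering:
    """Steepest-descent SWAP phase from the given medoids to a local optimum
    (no single medoid/non-medoid exchange reduces the total cost)."""
    D = validate_dissimilarity(D)
    n = len(D)
    medoids = np.sort(np.asarray(medoids, dtype=np.int64))
    k = len(medoids)
    if k == n:
        return _make_clustering(D, medoids)
    while True:
        sub = D[:, medoids]  # (n, k)
        order = np.argsort(sub, axis=1, kind="stable")
        d1 = sub[np.arange(n), order[:, 0]]
        nearest_pos = order[:, 0]
        d2 = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        cost = float(d1.sum())
        A = np.minimum(d1[:, None], D)  # cost term if i keeps a medoid != m
        B = np.minimum(d2[:, None], D) if k > 1 else D
        base = A.sum(axis=0)
        best = None  # (new_cost, medoid_pos, candidate)
        for mi in range(k):
            lost = nearest_pos == mi
            new_costs = base + ((B - A) * lost[:, None]).sum(axis=0)
            new_costs[medoids] = np.inf
            h = int(np.argmin(new_costs))
            if best is None or new_costs[h] < best[0] - _EPS or (
                abs(new_costs[h] - best[0]) <= _EPS
                and (medoids[mi], h) < (medoids[best[1]], best[2])
            ):
                if best is None or new_costs[h] < best[0] + _EPS:
                    best = (float(new_costs[h]), mi, h)
        if best is None or best[0] >= cost - _EPS:
            return _make_clustering(D, medoids)
        medoids = medoids.copy()
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)


def pam(D: np.ndarray, k: int) -> Clustering:
    """BUILD then SWAP; deterministic for a given D and k."""
    return pam_swap(D, pam_build(D, k))
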