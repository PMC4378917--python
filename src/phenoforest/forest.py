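"""Classification random forest with proximities, built for mixed-type
clinical tables.

The ensemble grows unpruned CART trees on bootstrap samples, splitting by
Gini impurity decrease over ``mtry`` candidate variables per node.
Continuous variables split on midpoint thresholds; categorical variables
split on exhaustively enumerated level subsets (native handling, no dummy
coding). Out-of-bag (OOB) rows provide the error rate, the confusion matrix
and permutation variable importance. The unsupervised mode contrasts the
real rows against a synthetic copy drawn from the product of the empirical
marginals (Breiman's Addcl1 scheme); the fraction of trees in which two
rows share a terminal node is their proximity, a similarity valid for
mixed-type data.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` substreams, so results are bit-reproducible
and individual trees do not change when ``n_trees`` grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSchema

__all__ = [
    "ForestConfig",
    "Tree",
    "Forest",
    "ProximityMatrix",
    "ImportanceReport",
    "OOBResult",
    "encode_features",
    "grow_tree",
    "fit_supervised_forest",
    "make_synthetic_contrast",
    "fit_unsupervised_forest",
    "compute_proximity",
    "oob_evaluate",
    "permutation_importance",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters; defaults follow the classical classification
    settings: 1500 trees, ``mtry = floor(sqrt(p))``, terminal nodes grown to
    size 1 (unpruned)."""

    n_trees: int = 1500
    mtry: int | None = None
    min_node_size: int = 1
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, int(np.sqrt(p)))
        if not 1 <= m <= p:
            raise ValueError(f"mtry must be in [1, {p}], got {m}")
        return m

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic named substream of the forest's master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

def encode_features(
    cohort: Cohort, variables: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode schema variables into ``(X, col_kind, names)``.

    ``col_kind[j]`` is 0 for continuous/binary columns (binary 0/1 splits on
    a threshold, which is equivalent to a subset split) and the level count
    ``L`` for categorical columns, whose values in ``X`` are integer level
    codes ``0..L-1``.
    """
    names = list(variables) if variables is not None else cohort.schema.names
    n = cohort.n
    X = np.empty((n, len(names)), dtype=np.float64)
    col_kind = np.zeros(len(names), dtype=np.int64)
    for j, name in enumerate(names):
        var = cohort.schema[name]
        col = cohort.data[name]
        if var.role == "categorical":
            codes = pd.Categorical(col, categories=var.levels).codes
            if (codes < 0).any():
                raise ValueError(f"value outside levels for {name!r}")
            X[:, j] = codes
            col_kind[j] = len(var.levels)
        else:
            X[:, j] = col.astype(float)
    return X, col_kind, names


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Flat-array CART tree.

    ``feature[i] < 0`` marks a leaf; for internal nodes ``cat_mask`` holds a
    level bitmask when the split variable is categorical (go left iff the
    row's level bit is set), otherwise the rule is ``value <= threshold``.
    Node indices double as leaf ids.
    """

    feature: np.ndarray
    threshold: np.ndarray
    cat_mask: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray
    col_kind: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal-node index for every row (vectorised traversal)."""
        node = np.zeros(len(X), dtype=np.int64)
        active = np.nonzero(self.feature[node] >= 0)[0]
        while active.size:
            nd = node[active]
            f = self.feature[nd]
            vals = X[active, f]
            is_cat = self.col_kind[f] > 0
            go_left = np.empty(active.size, dtype=bool)
            if (~is_cat).any():
                go_left[~is_cat] = vals[~is_cat] <= self.threshold[nd[~is_cat]]
            if is_cat.any():
                codes = vals[is_cat].astype(np.int64)
                go_left[is_cat] = (self.cat_mask[nd[is_cat]] >> codes) & 1 == 1
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
            active = active[self.feature[node[active]] >= 0]
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_class[self.apply(X)]


def _best_split(X, y_codes, rows, K, mtry, col_kind, rng):
    """Best (feature, rule) by Gini decrease among ``mtry`` sampled variables.

    Ties break to the lowest variable index, then the lowest threshold /
    lowest subset bitmask. Returns None when no candidate split separates
    the node.
    """
    n_node = rows.size
    ysub = y_codes[rows]
    counts = np.bincount(ysub, minlength=K).astype(np.float64)
    gini_parent = 1.0 - np.square(counts / n_node).sum()
    p = X.shape[1]
    chosen = rng.choice(p, size=mtry, replace=False)
    chosen.sort()
    eye = np.eye(K)
    onehot = eye[ysub]

    best = None  # (gain, j, threshold, cat_mask)
    for j in chosen:
        v = X[rows, j]
        if col_kind[j] == 0:
            order = np.argsort(v, kind="stable")
            vs = v[order]
            cum = np.cumsum(onehot[order], axis=0)
            cand = np.nonzero(vs[1:] > vs[:-1])[0]
            if cand.size == 0:
                continue
            nl = (cand + 1).astype(np.float64)
            nr = n_node - nl
            lc = cum[cand]
            rc = counts - lc
            gini_l = 1.0 - np.square(lc / nl[:, None]).sum(axis=1)
            gini_r = 1.0 - np.square(rc / nr[:, None]).sum(axis=1)
            gain = gini_parent - (nl * gini_l + nr * gini_r) / n_node
            b = int(np.argmax(gain))  # first max -> lowest threshold
            # zero-gain splits are accepted (locally uninformative splits,
            # e.g. XOR structure, can still lead to pure descendants)
            if best is None or gain[b] > best[0] + _EPS:
                thr = 0.5 * (vs[cand[b]] + vs[cand[b] + 1])
                best = (gain[b], j, thr, 0)
        else:
            L = int(col_kind[j])
            codes = v.astype(np.int64)
            level_counts = np.zeros((L, K))
            np.add.at(level_counts, codes, onehot)
            level_tot = level_counts.sum(axis=1)
            # enumerate proper subsets not containing level L-1 (complements
            # are equivalent); ascending mask = deterministic tie-break
            for mask in range(1, 1 << (L - 1)):
                sel = [l for l in range(L - 1) if (mask >> l) & 1]
                nl = level_tot[sel].sum()
                if nl == 0 or nl == n_node:
                    continue
                lc = level_counts[sel].sum(axis=0)
                rc = counts - lc
                nr = n_node - nl
                gini_l = 1.0 - np.square(lc / nl).sum()
                gini_r = 1.0 - np.square(rc / nr).sum()
                gain = gini_parent - (nl * gini_l + nr * gini_r) / n_node
                if best is None or gain > best[0] + _EPS:
                    best = (gain, j, np.nan, mask)
    return best


def grow_tree(
    X: np.ndarray,
    y_codes: np.ndarray,
    col_kind: np.ndarray,
    K: int,
    config: ForestConfig,
    rng: np.random.Generator,
) -> Tree:
    """Grow one unpruned CART tree on the given rows (already bootstrapped).

    Recursion stops at pure nodes, nodes at or below ``min_node_size``, or
    nodes where no sampled variable yields a positive Gini decrease (e.g.
    all-constant features with mixed labels become a majority-class leaf).
    """
    if len(X) == 0:
        raise ValueError("cannot grow a tree on zero rows")
    mtry = config.resolve_mtry(X.shape[1])
    feature, threshold, cat_mask = [], [], []
    left, right, leaf_class = [], [], []

    def _new_node():
        feature.append(-1)
        threshold.append(np.nan)
        cat_mask.append(0)
        left.append(-1)
        right.append(-1)
        leaf_class.append(-1)
        return len(feature) - 1

    root = _new_node()
    stack = [(root, np.arange(len(X), dtype=np.int64))]
    while stack:
        node_id, rows = stack.pop()
        ysub = y_codes[rows]
        counts = np.bincount(ysub, minlength=K)
        if (
            rows.size <= config.min_node_size
            or counts.max() == rows.size  # pure
        ):
            leaf_class[node_id] = int(np.argmax(counts))
            continue
        best = _best_split(X, y_codes, rows, K, mtry, col_kind, rng)
        if best is None:
            leaf_class[node_id] = int(np.argmax(counts))
            continue
        _, j, thr, mask = best
        v = X[rows, j]
        if col_kind[j] == 0:
            go_left = v <= thr
        else:
            go_left = ((mask >> v.astype(np.int64)) & 1) == 1
        feature[node_id] = j
        threshold[node_id] = thr
        cat_mask[node_id] = mask
        lid, rid = _new_node(), _new_node()
        left[node_id], right[node_id] = lid, rid
        stack.append((rid, rows[~go_left]))
        stack.append((lid, rows[go_left]))

    return Tree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=np.float64),
        cat_mask=np.asarray(cat_mask, dtype=np.int64),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        leaf_class=np.asarray(leaf_class, dtype=np.int64),
        col_kind=col_kind,
    )


# ---------------------------------------------------------------------------
# Forest
# ---------------------------------------------------------------------------

@dataclass
class Forest:
    trees: list[Tree]
    inbag: np.ndarray  # (n_trees, n) bootstrap multiplicities
    config: ForestConfig
    class_labels: list
    col_kind: np.ndarray
    variable_names: list[str]

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def fit_supervised_forest(
    X: np.ndarray,
    labels: Sequence,
    config: ForestConfig,
    col_kind: np.ndarray | None = None,
    variable_names: Sequence[str] | None = None,
) -> Forest:
    """Fit a classification forest: ``n_trees`` trees, each on an independent
    bootstrap sample of the ``n`` rows; deterministic given ``config.seed``."""
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if col_kind is None:
        col_kind = np.zeros(p, dtype=np.int64)
    if variable_names is None:
        variable_names = [f"x{j}" for j in range(p)]
    class_labels = sorted(pd.unique(np.asarray(labels)).tolist())
    if len(class_labels) < 2:
        raise ValueError("supervised forest needs >= 2 classes")
    lab_to_code = {c: i for i, c in enumerate(class_labels)}
    y_codes = np.asarray([lab_to_code[c] for c in np.asarray(labels)], dtype=np.int64)
    K = len(class_labels)

    trees: list[Tree] = []
    inbag = np.zeros((config.n_trees, n), dtype=np.int32)
    for t in range(config.n_trees):
        rng = _substream(config.seed, 0, t)
        draw = rng.integers(0, n, size=n)
        inbag[t] = np.bincount(draw, minlength=n)
        trees.append(grow_tree(X[draw], y_codes[draw], col_kind, K, config, rng))
    forest = Forest(trees, inbag, config, class_labels, col_kind, list(variable_names))
    if (inbag.min(axis=0) > 0).any():
        warnings.warn(
            "some rows are in-bag for every tree; OOB estimates exclude them",
            stacklevel=2,
        )
    return forest


def make_synthetic_contrast(
    X: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Augment ``n`` real rows with ``n`` synthetic rows, each variable drawn
    independently with replacement from its own empirical marginal (Addcl1).

    Synthetic rows keep the marginal distributions but destroy the joint
    dependence structure, so a forest separating real from synthetic learns
    exactly that structure.
    """
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for a synthetic contrast")
    synth = np.empty_like(X)
    for j in range(p):
        synth[:, j] = X[rng.integers(0, n, size=n), j]
    X_aug = np.vstack([X, synth])
    y = np.repeat([0, 1], n)  # 0 = real, 1 = synthetic
    return X_aug, y


def fit_unsupervised_forest(
    X: np.ndarray,
    config: ForestConfig,
    col_kind: np.ndarray | None = None,
    variable_names: Sequence[str] | None = None,
) -> Forest:
    """Fit the real-vs-synthetic contrast forest whose proximities cluster
    the original rows. The forest is trained on ``2n`` rows; proximity is
    later computed over the first ``n`` (original) rows only."""
    rng = _substream(config.seed, 1)
    X_aug, y = make_synthetic_contrast(np.asarray(X, dtype=np.float64), rng)
    return fit_supervised_forest(X_aug, y, config, col_kind, variable_names)


# ---------------------------------------------------------------------------
# Proximity
# ---------------------------------------------------------------------------

@dataclass
class ProximityMatrix:
    """Pairwise co-terminal-node frequencies over the forest's trees."""

    values: np.ndarray
    ids: list | None = None

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("proximity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("proximity diagonal must be exactly 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("proximity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def dissimilarity(self) -> np.ndarray:
        """D = 1 - P, the input to PAM and to classical MDS."""
        D = 1.0 - self.values
        np.fill_diagonal(D, 0.0)
        return D

    def to_csv(self, path) -> None:
        ids = self.ids if self.ids is not None else list(range(self.n))
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ProximityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), ids=list(df.index))


def compute_proximity(
    forest: Forest,
    X: np.ndarray,
    ids: Sequence | None = None,
    oob_only: bool = False,
) -> ProximityMatrix:
    """P[i, j] = fraction of trees in which rows i and j share a terminal
    node, every row run down every tree (the all-tree convention).

    With ``oob_only`` the count is restricted to trees where both rows are
    out-of-bag, normalised per pair; this requires ``X`` to be the training
    rows (or the leading block of them, as in the unsupervised contrast).
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    P = np.zeros((n, n))
    if oob_only:
        denom = np.zeros((n, n))
        for t, tree in enumerate(forest.trees):
            leaves = tree.apply(X)
            oob = forest.inbag[t, :n] == 0
            both = np.outer(oob, oob)
            denom += both
            P += both & (leaves[:, None] == leaves[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(denom > 0, P / np.maximum(denom, 1), 0.0)
        np.fill_diagonal(P, 1.0)
    else:
        for tree in forest.trees:
            leaves = tree.apply(X)
            P += leaves[:, None] == leaves[None, :]
        P /= forest.n_trees
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 1.0)
    return ProximityMatrix(P, ids=list(ids) if ids is not None else None)


# ---------------------------------------------------------------------------
# OOB evaluation and permutation importance
# ---------------------------------------------------------------------------

@dataclass
class OOBResult:
    """Out-of-bag misclassification summary."""

    error_rate: float
    confusion: pd.DataFrame  # rows = true class, columns = OOB-predicted
    n_covered: int
    n_never_oob: int


def oob_evaluate(forest: Forest, X: np.ndarray, labels: Sequence) -> OOBResult:
    """Majority-vote OOB prediction per row; rows in-bag for every tree are
    excluded from the error denominator (their count is reported)."""
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    K = len(forest.class_labels)
    lab_to_code = {c: i for i, c in enumerate(forest.class_labels)}
    y = np.asarray([lab_to_code[c] for c in np.asarray(labels)], dtype=np.int64)
    votes = np.zeros((n, K), dtype=np.int64)
    for t, tree in enumerate(forest.trees):
        oob = np.nonzero(forest.inbag[t] == 0)[0]
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob])
        votes[oob, pred] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        raise ValueError("no row is out-of-bag for any tree; grow more trees")
    pred = votes.argmax(axis=1)  # ties -> lowest class index
    conf = np.zeros((K, K), dtype=np.int64)
    np.add.at(conf, (y[covered], pred[covered]), 1)
    error = 1.0 - conf.trace() / conf.sum()
    confusion = pd.DataFrame(conf, index=forest.class_labels,
                             columns=forest.class_labels)
    return OOBResult(float(error), confusion, int(covered.sum()),
                     int(n - covered.sum()))


@dataclass
class ImportanceReport:
    """Permutation importance: per-variable mean decrease in OOB accuracy,
    its standard error across trees, and the resulting rank (1 = most
    important; ties break to the lower variable index)."""

    table: pd.DataFrame  # columns: variable, mean_decrease_accuracy, se, rank

    def top(self, m: int) -> list[str]:
        ordered = self.table.sort_values("rank")
        return ordered["variable"].head(m).tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def permutation_importance(
    forest: Forest,
    X: np.ndarray,
    labels: Sequence,
    rng: np.random.Generator | None = None,
) -> ImportanceReport:
    """Per tree and variable: OOB accuracy before minus after permuting that
    variable's OOB values; averaged over trees, with the across-tree SE.

    A variable constant in the data has importance exactly zero because its
    permutation is the identity on values.
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    lab_to_code = {c: i for i, c in enumerate(forest.class_labels)}
    y = np.asarray([lab_to_code[c] for c in np.asarray(labels)], dtype=np.int64)
    if rng is None:
        rng = _substream(forest.config.seed, 2)
    drops = np.full((forest.n_trees, p), np.nan)
    constant = np.array([np.unique(X[:, j]).size == 1 for j in range(p)])
    for t, tree in enumerate(forest.trees):
        oob = np.nonzero(forest.inbag[t] == 0)[0]
        if oob.size == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = np.mean(tree.predict(Xo) == yo)
        for j in range(p):
            if constant[j]:
                drops[t, j] = 0.0
                continue
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            drops[t, j] = base - np.mean(tree.predict(Xp) == yo)
    valid = ~np.isnan(drops)
    n_valid = valid.sum(axis=0)
    if (n_valid == 0).any():
        raise ValueError("a variable has no tree with OOB rows")
    mean = np.nanmean(drops, axis=0)
    sd = np.nanstd(drops, axis=0, ddof=1)
    se = sd / np.sqrt(n_valid)
    order = np.lexsort((np.arange(p), -mean))  # ties -> lower index first
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame({
        "variable": forest.variable_names,
        "mean_decrease_accuracy": mean,
        "se": se,
        "rank": rank,
    })
    return ImportanceReport(table)
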