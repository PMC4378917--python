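import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phenoforest as pf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort():
    """Four hand-built subjects in two obvious groups (sick vs mild)."""
    schema = pf.default_schema()
    rows = {
        "age": [30.0, 32.0, 50.0, 52.0],
        "gender": ["female", "male", "male", "male"],
        "cftr_group": ["two_class_I_II_III"] * 2 + ["any_class_IV_V_VI"] * 2,
        "fev1_pct": [30.0, 34.0, 90.0, 94.0],
        "fvc_pct": [50.0, 54.0, 100.0, 104.0],
        "height": [1.60, 1.70, 1.80, 1.75],
        "weight": [45.0, 52.0, 80.0, 76.0],
        "brasfield": [8.0, 9.0, 22.0, 23.0],
        "pancreatic_sufficient": [0, 0, 1, 1],
    }
    for org in pf.cohort.ORGANISMS:
        rows[org] = [1, 1, 0, 0] if org == "pa" else [0, 0, 0, 0]
    df = pd.DataFrame(rows, index=pd.Index(["s1", "s2", "s3", "s4"], name="id"))
    df["bmi"] = df["weight"] / df["height"] ** 2
    df["age_fev1_product"] = df["age"] * df["fev1_pct"]
    return pf.Cohort(df, schema, label="tiny")


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated 3-class cohort used by several integration tests."""
    config = pf.preset("separable_k3", n=90, seed=1)
    return pf.simulate_cohort(config)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration with
    math.comb (no scipy)."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def bh_oracle(p):
    """Literal step-up definition: adjusted_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def trace_row_through_tree(tree, x):
    """Scalar re-trace of one row through one tree (independent of the
    vectorised Tree.apply)."""
    node = 0
    while tree.feature[node] >= 0:
        j = tree.feature[node]
        if tree.col_kind[j] > 0:
            go_left = (tree.cat_mask[node] >> int(x[j])) & 1 == 1
        else:
            go_left = x[j] <= tree.threshold[node]
        node = tree.left[node] if go_left else tree.right[node]
    return node


def proximity_oracle(forest, X):
    """Pairwise co-leaf frequency by independently tracing every pair."""
    n = len(X)
    P = np.zeros((n, n))
    for tree in forest.trees:
        leaves = [trace_row_through_tree(tree, X[i]) for i in range(n)]
        for i in range(n):
            for j in range(n):
                if leaves[i] == leaves[j]:
                    P[i, j] += 1
    return P / forest.n_trees


def pam_exhaustive_cost(D, k):
    """Globally optimal k-medoid cost by enumerating all medoid sets."""
    from itertools import combinations

    n = len(D)
    best = np.inf
    for medoids in combinations(range(n), k):
        cost = D[:, list(medoids)].min(axis=1).sum()
        best = min(best, cost)
    return best


def no_improving_swap(D, clustering):
    """Brute-force check that no single medoid/non-medoid exchange reduces
    the total cost."""
    n = len(D)
    medoids = list(clustering.medoids)
    cost = D[:, medoids].min(axis=1).sum()
    for mi in range(len(medoids)):
        for h in range(n):
            if h in medoids:
                continue
            trial = medoids.copy()
            trial[mi] = h
            if D[:, trial].min(axis=1).sum() < cost - 1e-9:
                return False
    return True
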