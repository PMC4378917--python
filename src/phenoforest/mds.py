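"""Classical (Torgerson) multidimensional scaling of a dissimilarity matrix.

Double-centre -D^2/2, eigendecompose, and embed on the leading non-negative
eigenvalues. The 1 - proximity dissimilarity from a random forest is
generally non-Euclidean, so negative eigenvalues can occur; they are
truncated to zero (standard practice) and their relative mass is reported as
a quality diagnostic. Eigenvector signs are fixed so that the
largest-magnitude entry of each axis is positive, making plots reproducible
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pam import validate_dissimilarity

__all__ = ["Embedding", "classical_mds"]


@dataclass
class Embedding:
    coordinates: np.ndarray       # (n, dims), column means zero
    eigenvalues: np.ndarray       # dims leading eigenvalues (descending)
    negative_eigenvalue_mass: float
    ids: list | None = None

    def to_frame(self) -> pd.DataFrame:
        n, d = self.coordinates.shape
        idx = self.ids if self.ids is not None else list(range(n))
        return pd.DataFrame(
            self.coordinates,
            index=pd.Index(idx, name="subject_id"),
            columns=[f"mds{i + 1}" for i in range(d)],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def classical_mds(D: np.ndarray, dims: int = 2, ids=None) -> Embedding:
    """Embed a symmetric zero-diagonal dissimilarity matrix in ``dims``
    dimensions; Euclidean-realisable distances are reproduced exactly."""
    D = validate_dissimilarity(D)
    n = len(D)
    if not 1 <= dims < n:
        raise ValueError(f"dims must be in [1, {n - 1}], got {dims}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    total = np.abs(eigval).sum()
    neg_mass = float(np.abs(eigval[eigval < 0]).sum() / total) if total > 0 else 0.0
    top = eigval[:dims]
    vecs = eigvec[:, :dims]
    coords = vecs * np.sqrt(np.clip(top, 0.0, None))
    # deterministic sign: largest-|entry| of each axis made positive
    for j in range(dims):
        col = coords[:, j]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                coords[:, j] = -col
    coords = coords - coords.mean(axis=0)
    return Embedding(coords, top, neg_mass, ids=list(ids) if ids is not None else None)
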