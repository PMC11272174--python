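"""Spatial neighbor graph construction and the corrupted contrastive view.

Spots i, j are connected when their Euclidean distance is strictly below a
threshold delta (platform units).  Applied literally this also connects every
spot to itself (d_ii = 0 < delta), so the proximity matrix A0 carries a unit
diagonal.  The hybrid adjacency A = (1 - lambda) * A0 + lambda * I blends
neighbor influence against self influence; its diagonal is exactly 1 for any
lambda.  Message passing uses the symmetric normalization
D^-1/2 A D^-1/2 with D_ii = sum_j A_ij.

The corrupted view permutes the rows of the feature matrix uniformly at
random while leaving the graph topology untouched; it supplies the negative
pairs for contrastive learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .errors import DegenerateGraphError, ParameterError, ValidationError

DEFAULT_DELTA = 250.0
DEFAULT_LAMBDA = 0.8


@dataclass
class SpatialGraph:
    """Proximity graph A0, hybrid adjacency A and its normalization."""

    A0: sp.csr_matrix
    A: sp.csr_matrix
    Anorm: sp.csr_matrix
    delta: float
    lam: float

    @property
    def n_spots(self) -> int:
        return self.A0.shape[0]


@dataclass
class CorruptedView:
    """Row-shuffled feature matrix sharing the original graph topology."""

    X_bar: np.ndarray
    permutation: np.ndarray
    seed: int


def build_adjacency(coords: np.ndarray, delta: float,
                    self_loops: bool = True) -> sp.csr_matrix:
    """Binary proximity matrix: entry (i, j) = 1 iff d_ij < delta (strict).

    ``self_loops=False`` zeroes the diagonal (ablation variant; the default
    keeps d_ii = 0 < delta, i.e. a unit diagonal).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValidationError("coords must be N x 2")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coords contain non-finite values")
    if delta <= 0:
        raise ParameterError("delta must be positive")
    n = coords.shape[0]
    tree = cKDTree(coords)
    # query_pairs uses d <= r; shrink r by the tiniest representable step to
    # realize the strict inequality d < delta even on exact lattice distances
    pairs = tree.query_pairs(r=np.nextafter(delta, 0.0), output_type="ndarray")
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.ones(rows.shape[0])
    A0 = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    if self_loops:
        A0 = A0 + sp.eye(n, format="csr")
    A0.data[:] = 1.0
    return A0


def hybridize(A0: sp.spmatrix, lam: float = DEFAULT_LAMBDA) -> sp.csr_matrix:
    """Hybrid adjacency (1 - lambda) * A0 + lambda * I."""
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lambda must lie in [0, 1], got {lam}")
    A0 = sp.csr_matrix(A0)
    A = (1.0 - lam) * A0 + lam * sp.eye(A0.shape[0], format="csr")
    A.eliminate_zeros()
    return A


def symmetric_normalize(A: sp.spmatrix) -> sp.csr_matrix:
    """D^-1/2 A D^-1/2 with D the diagonal of row sums of A."""
    A = sp.coo_matrix(A)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise DegenerateGraphError("zero row sum in adjacency")
    dinv = 1.0 / np.sqrt(deg)
    # scale each entry by the single product d_i * d_j so that the (i, j)
    # and (j, i) entries stay bit-identical (symmetry to the last ulp)
    data = A.data * (dinv[A.row] * dinv[A.col])
    return sp.csr_matrix((data, (A.row, A.col)), shape=A.shape)


def build_spatial_graph(coords: np.ndarray, delta: float = DEFAULT_DELTA,
                        lam: float = DEFAULT_LAMBDA,
                        self_loops: bool = True) -> SpatialGraph:
    """Convenience: proximity graph -> hybrid adjacency -> normalization."""
    A0 = build_adjacency(coords, delta, self_loops=self_loops)
    A = hybridize(A0, lam)
    return SpatialGraph(A0=A0, A=A, Anorm=symmetric_normalize(A),
                        delta=float(delta), lam=float(lam))


def corrupt_features(X: np.ndarray, seed: int) -> CorruptedView:
    """Uniformly random row permutation of X, reproducible from ``seed``."""
    X = np.asarray(X)
    n = X.shape[0]
    if n < 2:
        raise ParameterError("corruption needs at least 2 spots")
    perm = np.random.default_rng(seed).permutation(n)
    return CorruptedView(X_bar=X[perm], permutation=perm, seed=int(seed))


def export_edge_list(A0: sp.spmatrix, path: str) -> None:
    """Write the proximity graph as a TSV edge list (i, j, weight)."""
    coo = sp.coo_matrix(A0)
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{w:g}\n")
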