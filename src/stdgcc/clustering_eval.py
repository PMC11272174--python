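"""Domain assignment (PCA + k-means) and partition agreement metrics.

The trained embedding is reduced to its first 30 principal components and
spots are assigned to domains with k-means (k-means++ initialization, best
of 10 restarts).  Agreement with ground-truth annotations is scored with
normalized mutual information,

    NMI(U, V) = -2 * sum_ij n_ij * log(N * n_ij / (a_i * b_j))
                / [ sum_i a_i * log(a_i / N) + sum_j b_j * log(b_j / N) ],

(equivalently 2 * MI / (H(U) + H(V))) and the adjusted Rand index,

    ARI(U, V) = [ sum_ij C(n_ij, 2) - sum_i C(a_i, 2) * sum_j C(b_j, 2) / C(N, 2) ]
                / [ (sum_i C(a_i, 2) + sum_j C(b_j, 2)) / 2
                    - sum_i C(a_i, 2) * sum_j C(b_j, 2) / C(N, 2) ],

where n_ij is the contingency table of the two labelings and a_i, b_j its
margins.  Both metrics are implemented directly from the contingency table;
0 * log 0 counts as 0.  If both partitions are the single-cluster partition
the metrics return 1 (identical) and any remaining 0/0 returns 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ParameterError, ValidationError

N_COMPONENTS_DEFAULT = 30
KMEANS_N_INIT = 10
KMEANS_MAX_ITER = 300
KMEANS_TOL = 1e-4


@dataclass
class ClusterResult:
    """PCA-reduced embedding and 1-based contiguous domain labels."""

    pcs: np.ndarray
    labels_pred: np.ndarray
    k: int
    seed: int


@dataclass
class ContingencySummary:
    """Contingency table of two labelings with margins."""

    table: np.ndarray
    a: np.ndarray   # row sums (first labeling)
    b: np.ndarray   # column sums (second labeling)
    n: int


def contingency(U, V) -> ContingencySummary:
    U, V = np.asarray(U), np.asarray(V)
    if U.shape != V.shape or U.ndim != 1:
        raise ValidationError("labelings must be equal-length 1-D arrays")
    if U.size == 0:
        raise ValidationError("labelings are empty")
    _, ui = np.unique(U, return_inverse=True)
    _, vi = np.unique(V, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return ContingencySummary(table=table, a=table.sum(axis=1),
                              b=table.sum(axis=0), n=int(U.size))


def reduce_pca(H: np.ndarray, n_components: int = N_COMPONENTS_DEFAULT) -> np.ndarray:
    """Mean-centered PCA scores, components by decreasing explained variance.

    The sign of each component is fixed so that its largest-magnitude loading
    is positive, making the output deterministic.  ``n_components`` above the
    achievable rank is reduced with a warning.
    """
    H = np.asarray(H, dtype=np.float64)
    if not np.all(np.isfinite(H)):
        raise ValidationError("embedding contains non-finite values")
    max_rank = min(H.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds min(N, M)={max_rank}; "
            f"using {max_rank}", stacklevel=2)
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(H)
    # deterministic sign: largest-|loading| entry of each component positive
    comp = pca.components_
    flip = np.sign(comp[np.arange(comp.shape[0]),
                        np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip


def kmeans_assign(pcs: np.ndarray, k: int, seed: int = 0,
                  n_init: int = KMEANS_N_INIT) -> np.ndarray:
    """k-means++ / Lloyd labels, best of ``n_init`` restarts, 1-based
    contiguous label values in order of first appearance."""
    pcs = np.asarray(pcs, dtype=np.float64)
    if k < 1 or k > pcs.shape[0]:
        raise ParameterError(f"k={k} out of range for N={pcs.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=KMEANS_MAX_ITER, tol=KMEANS_TOL, random_state=seed)
    raw = km.fit_predict(pcs)
    _, first = np.unique(raw, return_index=True)
    remap = {lab: rank + 1 for rank, lab in
             enumerate(raw[np.sort(first)])}
    return np.array([remap[l] for l in raw], dtype=np.int64)


def cluster_embedding(H: np.ndarray, k: int, seed: int = 0,
                      n_components: int = N_COMPONENTS_DEFAULT,
                      n_init: int = KMEANS_N_INIT) -> ClusterResult:
    """PCA reduction followed by k-means assignment."""
    pcs = reduce_pca(H, n_components=n_components)
    labels = kmeans_assign(pcs, k, seed=seed, n_init=n_init)
    return ClusterResult(pcs=pcs, labels_pred=labels, k=k, seed=seed)


def _xlogy(x, y):
    out = np.zeros_like(x, dtype=np.float64)
    nz = x > 0
    out[nz] = x[nz] * np.log(y[nz])
    return out


def nmi(U, V) -> float:
    """Normalized mutual information 2*MI/(H(U)+H(V)) of two labelings."""
    c = contingency(U, V)
    n = float(c.n)
    nij = c.table.astype(np.float64)
    a = c.a.astype(np.float64)
    b = c.b.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nij > 0, n * nij / np.outer(a, b), 1.0)
    num = -2.0 * np.sum(_xlogy(nij, ratio))
    den = np.sum(_xlogy(a, a / n)) + np.sum(_xlogy(b, b / n))
    if den == 0.0:  # both partitions single-cluster
        return 1.0 if np.array_equal(c.table.shape, (1, 1)) else 0.0
    return float(num / den)


def ari(U, V) -> float:
    """Adjusted Rand index of two labelings, from the contingency table."""
    c = contingency(U, V)

    def comb2(x):
        x = np.asarray(x, dtype=np.float64)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(c.table).sum()
    sum_a = comb2(c.a).sum()
    sum_b = comb2(c.b).sum()
    total = comb2(np.array([c.n])).item()
    if total == 0.0:
        return 1.0  # a single element agrees with itself
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    denom = max_index - expected
    if denom == 0.0:
        # only reachable when both partitions are single-cluster or both are
        # all-singletons; either way the partitions coincide
        return 1.0
    return float((sum_ij - expected) / denom)
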