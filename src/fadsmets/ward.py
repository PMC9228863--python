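"""Agglomerative clustering with Ward's minimum-variance criterion.

Merge heights are the increase in total within-cluster sum of squares
(delta-SS), computed with the Lance-Williams recurrence

    d(i+j, k) = [(n_i + n_k) d(i,k) + (n_j + n_k) d(j,k) - n_k d(i,j)]
                / (n_i + n_j + n_k)

initialized with d(i, j) = ||x_i - x_j||^2 / 2 for singletons, so that
summing all merge heights recovers exactly the total sum of squares about
the grand mean.  (The common "Ward on Euclidean distance" convention
reports sqrt(2 * delta-SS); the two orderings are identical.)

Merge ties are broken by the smallest (min leaf id of A, min leaf id of B)
pair for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .association import ContingencyResult, pearson_chi2


@dataclass
class Dendrogram:
    """Ordered merge list; clusters 0..n-1 are leaves, n+k is the cluster
    created by merge k.  Each merge row is (cluster_a, cluster_b, height,
    size of merged cluster)."""

    n_leaves: int
    merges: np.ndarray  # shape (n-1, 4)

    def members(self) -> list[set[int]]:
        """Leaf membership of every cluster id (leaves then internal)."""
        out = [{i} for i in range(self.n_leaves)]
        for a, b, _, _ in self.merges:
            out.append(out[int(a)] | out[int(b)])
        return out

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def total_ss(self) -> float:
        return float(self.merges[:, 2].sum())


def ward_linkage(X: np.ndarray) -> Dendrogram:
    """Greedy minimum delta-SS agglomeration via the Lance-Williams recurrence."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if np.isnan(X).any():
        raise ValueError("NaN in input")

    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    D = sq / 2.0  # delta-SS for merging two singletons
    np.fill_diagonal(D, np.inf)

    size = np.ones(n)
    min_leaf = np.arange(n)          # smallest leaf id in each active cluster
    cluster_id = np.arange(n)        # dendrogram id of each active row
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        Dm = np.where(active[:, None] & active[None, :], D, np.inf)
        h = Dm.min()
        # deterministic tie-break on (min leaf of A, min leaf of B), A < B
        ii, jj = np.where(np.isclose(Dm, h, rtol=1e-12, atol=0.0))
        best = None
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            a, b = sorted((i, j), key=lambda k: min_leaf[k])
            key = (min_leaf[a], min_leaf[b])
            if best is None or key < best[0]:
                best = (key, a, b)
        _, i, j = best
        h = float(D[i, j])

        ni, nj, nk = size[i], size[j], size
        with np.errstate(invalid="ignore"):
            newrow = ((ni + nk) * D[i] + (nj + nk) * D[j] - nk * h) / (ni + nj + nk)
        merges[step] = (cluster_id[i], cluster_id[j], h, ni + nj)

        D[i, :] = newrow
        D[:, i] = newrow
        D[i, i] = np.inf
        active[j] = False
        size[i] = ni + nj
        min_leaf[i] = min(min_leaf[i], min_leaf[j])
        cluster_id[i] = n + step

    return Dendrogram(n_leaves=n, merges=merges)


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-subject label in {1..k}
    convention: str = "merge-order"

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))


def cut_k(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Undo the last k-1 merges; components become clusters 1..k, numbered
    by smallest member leaf id."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = dendrogram.merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[leaf] = roots[r]
    return ClusterAssignment(labels=labels)


def canonical_labels(assignment: ClusterAssignment, group_labels=None,
                     dgla=None, case_label="MetS") -> ClusterAssignment:
    """Name the cluster with the higher case (MetS) fraction "1".

    Ties are broken by the higher mean DGLA (20:3n-6) when provided; without
    group labels, clusters are named by decreasing size with a warning.
    """
    labels = assignment.labels
    ids = np.unique(labels)
    if len(ids) != 2:
        raise ValueError("canonical naming requires exactly two clusters")

    def mets_frac(c):
        mask = labels == c
        return float(np.mean(np.asarray(group_labels)[mask] == case_label))

    if group_labels is None:
        warnings.warn("no group labels; naming clusters by decreasing size")
        order = sorted(ids, key=lambda c: -(labels == c).sum())
    else:
        def key(c):
            tie = 0.0
            if dgla is not None:
                tie = float(np.asarray(dgla)[labels == c].mean())
            return (-mets_frac(c), -tie)
        order = sorted(ids, key=key)
    mapping = {order[0]: 1, order[1]: 2}
    return ClusterAssignment(labels=np.array([mapping[c] for c in labels]),
                             convention="case-enriched-first")


def rand_index(labels_a, labels_b) -> float:
    """Rand index: fraction of subject pairs on which two partitions agree."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same subjects")
    iu = np.triu_indices(len(a), 1)
    same_a = (a[:, None] == a[None, :])[iu]
    same_b = (b[:, None] == b[None, :])[iu]
    return float((same_a == same_b).mean())


def cluster_group_chi2(assignment: ClusterAssignment, group_labels) -> ContingencyResult:
    """Yates-corrected 2x2 chi-square of cluster membership vs group."""
    labels = assignment.labels
    groups = np.asarray(group_labels)
    glev = sorted(np.unique(groups), reverse=True)  # MetS row first when present
    clev = sorted(np.unique(labels))
    if len(glev) != 2 or len(clev) != 2:
        raise ValueError("need a 2x2 cluster-by-group table")
    table = np.array([[int(np.sum((labels == c) & (groups == g))) for c in clev]
                      for g in glev])
    return pearson_chi2(table, correction="yates")
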