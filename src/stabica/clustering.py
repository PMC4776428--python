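"""Spearman dissimilarity, average-link clustering, centrotypes, model selection.

Estimated sources from different FastICA restarts that converged to the same
underlying component are monotone transforms of one another up to sign, so
their similarity is summarized by the absolute Spearman rank correlation and
turned into the dissimilarity d_ij = 1 - |rho_ij|.  Average-link agglomeration
over this matrix groups recurring estimates; each cluster is represented by
its *centrotype*, the member with the minimal sum of dissimilarities to the
rest of the cluster.

The number of clusters c is chosen by a geometric quality index evaluated on
the 2-D projection of the bank: the ratio of the average within-cluster
distance to the average between-cluster distance.  The index typically falls
until the restarts' recurrent components are each isolated in their own
cluster and rises (or flattens) afterwards; its argmin is the selected c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .decomposition import SourceBank

logger = logging.getLogger("stabica.clustering")

__all__ = [
    "Partition",
    "CentrotypeSet",
    "spearman_dissimilarity",
    "hca_average_link",
    "cut_dendrogram",
    "centrotype",
    "extract_centrotypes",
    "quality_index",
    "select_cluster_number",
    "dendrogram_to_newick",
]


@dataclass
class Partition:
    """A flat cut of the dendrogram: labels in 1..c for every bank column."""

    labels: np.ndarray
    c: int
    merge_heights: np.ndarray  # scipy linkage record

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class CentrotypeSet:
    """Representative components: one bank column per cluster."""

    OC: np.ndarray             # n x c representative sources
    member_column: np.ndarray  # c bank-column indices
    cluster_size: np.ndarray   # c member counts
    labels: np.ndarray         # bank-column cluster labels (1..c)

    @property
    def c(self) -> int:
        return self.OC.shape[1]


def _as_bank_matrix(bank: SourceBank | np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(bank, SourceBank):
        return bank.S, bank.run_index
    return np.asarray(bank, float), None


def spearman_dissimilarity(bank: SourceBank | np.ndarray) -> np.ndarray:
    """d_ij = 1 - |Spearman rho| between bank columns, with average-rank ties."""
    S, run_index = _as_bank_matrix(bank)
    sd = S.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        run = f" (run {run_index[j]})" if run_index is not None else ""
        raise ValueError(f"bank column {j}{run} is constant; Spearman rho undefined")
    ranks = rankdata(S, axis=0)  # average ties
    R = np.corrcoef(ranks, rowvar=False)
    D = 1.0 - np.abs(R)
    np.clip(D, 0.0, 1.0, out=D)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    if not np.allclose(D, D.T, atol=1e-10) or np.any(np.diag(D) != 0):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    return D


def hca_average_link(D: np.ndarray) -> np.ndarray:
    """Average-link agglomerative clustering; returns the scipy linkage record."""
    D = _check_dissimilarity(D)
    return hierarchy.linkage(squareform(D, checks=False), method="average")


def cut_dendrogram(Z: np.ndarray, c: int) -> Partition:
    """Cut the dendrogram into exactly c clusters, labelled 1..c."""
    n_points = Z.shape[0] + 1
    if not 1 <= c <= n_points:
        raise ValueError(f"cannot cut {n_points} points into c={c} clusters")
    labels = hierarchy.cut_tree(Z, n_clusters=c).ravel() + 1
    return Partition(labels, int(labels.max()), Z)


def centrotype(D: np.ndarray, members: np.ndarray) -> int:
    """The member minimizing the sum of dissimilarities to the other members.

    Ties resolve to the smallest bank-column index.
    """
    members = np.sort(np.asarray(members, int))
    if members.size == 0:
        raise ValueError("cluster has no members")
    sub = D[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.sum(axis=1)))])


def extract_centrotypes(bank: SourceBank | np.ndarray, D: np.ndarray, partition: Partition) -> CentrotypeSet:
    """Pick the centrotype of every cluster and assemble the OC matrix."""
    S, _ = _as_bank_matrix(bank)
    cols, sizes = [], []
    for a in range(1, partition.c + 1):
        members = partition.members(a)
        cols.append(centrotype(D, members))
        sizes.append(members.size)
    cols = np.array(cols, int)
    return CentrotypeSet(S[:, cols].copy(), cols, np.array(sizes, int), partition.labels.copy())


def quality_index(
    coords: np.ndarray,
    labels: np.ndarray,
    on: str = "coords",
    D: np.ndarray | None = None,
) -> float:
    """Ratio of average within-cluster to average between-cluster distance.

    The numerator averages, over clusters, the mean pairwise distance within
    each cluster (singletons contribute 0); the denominator is the mean
    distance over all pairs of points in different clusters.  Distances are
    Euclidean on the 2-D projection coordinates by default; ``on="dissimilarity"``
    evaluates the same ratio directly on the dissimilarity matrix D for
    sensitivity checks.
    """
    labels = np.asarray(labels, int)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("quality index needs at least 2 clusters")
    if on == "coords":
        dist = squareform(pdist(np.asarray(coords, float)))
    elif on == "dissimilarity":
        if D is None:
            raise ValueError("on='dissimilarity' requires D")
        dist = _check_dissimilarity(D)
    else:
        raise ValueError(f"unknown distance source {on!r}")

    withins = []
    for a in uniq:
        idx = np.flatnonzero(labels == a)
        if idx.size < 2:
            withins.append(0.0)
            continue
        sub = dist[np.ix_(idx, idx)]
        withins.append(sub.sum() / (idx.size * (idx.size - 1)))
    numerator = float(np.mean(withins))

    same = labels[:, None] == labels[None, :]
    between = dist[~same]
    denominator = float(between.mean())
    if denominator == 0.0:
        logger.warning("all between-cluster distances are zero; index undefined, returning inf")
        return float("inf")
    return numerator / denominator


def select_cluster_number(
    D: np.ndarray,
    coords: np.ndarray,
    cluster_range: tuple[int, int],
    Z: np.ndarray | None = None,
    on: str = "coords",
) -> tuple[int, dict[int, float]]:
    """Scan c over the range and pick the argmin of the quality index.

    All cuts come from the same average-link dendrogram.  Ties resolve to the
    smallest c (parsimony); a flat curve triggers a warning and also returns
    the smallest c.
    """
    lo, hi = cluster_range
    n_points = D.shape[0]
    if not (2 <= lo <= hi <= n_points - 1):
        raise ValueError(f"cluster_range {cluster_range} invalid for {n_points} points")
    if Z is None:
        Z = hca_average_link(D)
    curve: dict[int, float] = {}
    for c in range(lo, hi + 1):
        part = cut_dendrogram(Z, c)
        curve[c] = quality_index(coords, part.labels, on=on, D=D)
    values = np.array(list(curve.values()))
    if values.max() - values.min() < 1e-12:
        logger.warning("quality-index curve is flat; no cluster structure to select")
    c_opt = int(list(curve)[int(np.argmin(values))])
    return c_opt, curve


def dendrogram_to_newick(Z: np.ndarray, labels: list[str] | None = None) -> str:
    """Serialize the linkage record as a Newick tree for external inspection."""
    tree = hierarchy.to_tree(Z)
    n_leaves = Z.shape[0] + 1
    if labels is None:
        labels = [str(i) for i in range(n_leaves)]

    def walk(node, parent_height: float) -> str:
        length = parent_height - (node.dist if not node.is_leaf() else 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
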