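"""Chemotaxonomic trees and their comparison with phylogenies.

Species x compound-class count matrices are turned into Bray-Curtis
dissimilarities, clustered agglomeratively (UPGMA by default) into a
chemotaxonomic dendrogram, and compared against a phylogenetic tree via
cophenetic correlation, the Mantel permutation test, and the normalized
Robinson-Foulds distance over unrooted bipartitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

logger = logging.getLogger("chemoclass")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarities with zero diagonal over labeled items."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} does not match "
                             f"{n} labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "d", d)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between the rows of a count matrix.

    ``d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk)``, bounded in [0, 1].
    All-zero rows (for which the quotient is undefined) are a hard error.
    """
    X = matrix.to_numpy(dtype=float)
    zero_rows = matrix.index[(X.sum(axis=1) == 0)].tolist()
    if zero_rows:
        raise ValueError(f"Bray-Curtis undefined for all-zero rows: {zero_rows}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(tuple(str(i) for i in matrix.index), d)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Ultrametric dendrogram from agglomerative clustering."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix

    def to_newick(self) -> str:
        return _linkage_to_newick(self.linkage, self.labels)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 taxon_namespace=taxon_namespace,
                                 preserve_underscores=True)


def hclust(dm: DistanceMatrix, method: str = "average") -> ClusterTree:
    """Agglomerative clustering of a dissimilarity matrix.

    ``method`` is one of single/complete/average/ward; average linkage
    (UPGMA) is the default.  Labels are processed in sorted order so tied
    merge decisions resolve deterministically by label order.
    """
    if len(dm.labels) < 2:
        raise ValueError("clustering needs at least two items")
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    dm_sorted = dm.reorder([dm.labels[i] for i in order])
    Z = _hier.linkage(dm_sorted.condensed(), method=method)
    return ClusterTree(labels=dm_sorted.labels, linkage=Z)


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths.

    Branch lengths are differences of merge heights, so leaf-to-leaf path
    lengths equal twice the cophenetic merge height (ultrametric tree).
    """
    n = len(labels)
    height = {i: 0.0 for i in range(n)}

    def name(i: int) -> str:
        if i < n:
            return labels[i]
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        h = Z[i - n, 2]
        return (f"({name(a)}:{(h - height[a]) / 2:.10g},"
                f"{name(b)}:{(h - height[b]) / 2:.10g})")

    for k in range(Z.shape[0]):
        height[n + k] = Z[k, 2]
    return name(n + Z.shape[0] - 1) + ";"


# ---------------------------------------------------------------------------
# Cophenetic distances and correlation
# ---------------------------------------------------------------------------

def cophenetic_dist(tree: ClusterTree | dendropy.Tree) -> DistanceMatrix:
    """Pairwise cophenetic distances between the leaves of a tree.

    For a dendrogram this is the merge height of the lowest common
    ancestor; for a phylogeny it is the patristic path length.  A
    phylogeny missing branch lengths falls back to unit lengths with a
    warning.
    """
    if isinstance(tree, ClusterTree):
        coph = _hier.cophenet(tree.linkage)
        return DistanceMatrix(tree.labels, squareform(coph))

    t = tree.clone(depth=1)
    if any(e.length is None for e in t.preorder_edge_iter()
           if e.head_node is not t.seed_node):
        logger.warning("tree lacks branch lengths; assuming unit lengths")
        for e in t.preorder_edge_iter():
            if e.head_node is not t.seed_node:
                e.length = 1.0
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    labels = tuple(x.label for x in taxa)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


def cophenetic_correlation(t1: ClusterTree | dendropy.Tree,
                           t2: ClusterTree | dendropy.Tree) -> float:
    """Pearson correlation of the two trees' cophenetic distance vectors."""
    d1 = cophenetic_dist(t1)
    d2 = cophenetic_dist(t2)
    if set(d1.labels) != set(d2.labels):
        diff = set(d1.labels) ^ set(d2.labels)
        raise ValueError(f"leaf sets differ: {sorted(diff)}")
    d2 = d2.reorder(d1.labels)
    r, _ = pearsonr(d1.condensed(), d2.condensed())
    return float(r)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the off-diagonal vectors;
    significance permutes the rows and columns of ``d2`` jointly, with the
    add-one right-tail p-value ``(1 + #{r_perm >= r}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set(d1.labels) != set(d2.labels):
        diff = set(d1.labels) ^ set(d2.labels)
        raise ValueError(f"label sets differ: {sorted(diff)}")
    d2 = d2.reorder(d1.labels)
    v1 = d1.condensed()
    r_obs = float(pearsonr(v1, d2.condensed())[0])

    rng = np.random.default_rng(seed)
    n = len(d1.labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = squareform(d2.d[np.ix_(perm, perm)], checks=False)
        if pearsonr(v1, v2p)[0] >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions, each as its smaller-side leaf set
    (canonicalized by excluding a fixed reference taxon)."""
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1: ClusterTree | dendropy.Tree,
                    t2: ClusterTree | dendropy.Tree,
                    normalized: bool = True) -> float:
    """Robinson-Foulds distance between two trees, treated as unrooted.

    The symmetric difference of the nontrivial bipartition sets, optionally
    normalized by the total number of nontrivial bipartitions in both trees
    (so the normalized value lies in [0, 1], 0 iff identical unrooted
    topologies).  Polytomies are allowed.
    """
    trees = []
    for t in (t1, t2):
        trees.append(t.to_dendropy() if isinstance(t, ClusterTree) else t)
    leaves1 = {l.taxon.label for l in trees[0].leaf_node_iter()}
    leaves2 = {l.taxon.label for l in trees[1].leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(f"leaf sets differ: {sorted(leaves1 ^ leaves2)}")
    if len(leaves1) < 4:
        raise ValueError("Robinson-Foulds needs at least four leaves")
    b1, b2 = _bipartitions(trees[0]), _bipartitions(trees[1])
    rf = len(b1 ^ b2)
    if not normalized:
        return float(rf)
    total = len(b1) + len(b2)
    return rf / total if total else 0.0


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a phylogenetic tree in Newick format (underscores literal)."""
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: ClusterTree | dendropy.Tree, path: str | Path) -> None:
    if isinstance(tree, ClusterTree):
        Path(path).write_text(tree.to_newick() + "\n")
    else:
        tree.write(path=str(path), schema="newick")
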