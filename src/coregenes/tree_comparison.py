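"""Leaf co-clustering tree distance with a label-shuffling permutation null.

Whole-tree metrics are sensitive to internal branch lengths and branching
conventions, which differ between neighbor-joining, maximum-likelihood and
hierarchical-clustering trees.  This statistic instead asks only whether the
same pairs of leaves sit close together: tip-to-tip path distances are
thresholded at their lowest percentile (10th by default) to give a binary
co-clustering matrix per tree, and two trees are compared by the Euclidean
(Frobenius) distance between their matrices.  Significance comes from
re-assigning one tree's leaf labels uniformly at random, keeping its shape
and branch lengths fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .phylo_trees import leaf_path_distances


@dataclass
class CoClusterMatrix:
    labels: list[str]
    m: np.ndarray  # symmetric binary, zero diagonal
    threshold_value: float
    percentile: float


@dataclass
class TreeDistanceResult:
    distance: float
    p_value: float
    n_permutations: int
    null_mean: float
    null_sd: float
    seed: int


def coclustering(dm: DistanceMatrix, percentile: float = 10.0) -> CoClusterMatrix:
    """Binary co-clustering matrix from a leaf distance matrix.

    The threshold is the ``percentile``-th linear-interpolation quantile of
    the unordered-pair (upper-triangle) distances; pairs at or below it are
    connected, so ties at the threshold are included.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    d = np.asarray(dm.data, dtype=float)
    iu = np.triu_indices(len(labels), k=1)
    vals = d[iu]
    if np.allclose(vals, vals[0]):
        warnings.warn("all pairwise distances identical; co-clustering is degenerate")
    thr = float(np.percentile(vals, percentile, method="linear"))
    m = (d <= thr).astype(np.int8)
    np.fill_diagonal(m, 0)
    return CoClusterMatrix(labels=labels, m=m, threshold_value=thr,
                           percentile=percentile)


def _aligned_cocluster(ta: TreeNode, tb: TreeNode, percentile: float):
    da = leaf_path_distances(ta)
    db = leaf_path_distances(tb)
    sa, sb = set(da.ids), set(db.ids)
    if sa != sb:
        raise ValueError(
            f"leaf label sets differ; symmetric difference: {sorted(sa ^ sb)}"
        )
    order = sorted(sa)
    da = da.filter(order)
    db = db.filter(order)
    return coclustering(da, percentile), coclustering(db, percentile)


def matrix_distance(ma: np.ndarray, mb: np.ndarray) -> float:
    """Frobenius norm of the difference of two binary adjacency matrices.

    Computed over the full symmetric matrix, so flipping one unordered pair
    changes the distance by sqrt(2).
    """
    return float(np.sqrt(((ma.astype(float) - mb.astype(float)) ** 2).sum()))


def tree_distance(ta: TreeNode, tb: TreeNode, percentile: float = 10.0) -> float:
    """Co-clustering distance between two trees over the same leaf set."""
    ca, cb = _aligned_cocluster(ta, tb, percentile)
    return matrix_distance(ca.m, cb.m)


def permutation_pvalue(
    ta: TreeNode,
    tb: TreeNode,
    n_perm: int = 1000,
    seed: int = 0,
    percentile: float = 10.0,
) -> TreeDistanceResult:
    """Significance of the co-clustering distance by leaf-label shuffling.

    Null trees relabel ``tb``'s leaves uniformly at random with its shape and
    branch lengths fixed; since the distance multiset (and hence the
    percentile threshold) is label-invariant, each shuffle amounts to
    conjugating ``tb``'s co-clustering matrix by a permutation.  The add-one
    p-value (1 + #{null <= observed}) / (1 + n_perm) is reported, so the
    smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ca, cb = _aligned_cocluster(ta, tb, percentile)
    observed = matrix_distance(ca.m, cb.m)
    rng = np.random.default_rng(seed)
    n = len(ca.labels)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        mb = cb.m[np.ix_(perm, perm)]
        null[i] = matrix_distance(ca.m, mb)
    p = (1 + int((null <= observed).sum())) / (1 + n_perm)
    return TreeDistanceResult(
        distance=observed,
        p_value=p,
        n_permutations=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        seed=seed,
    )
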