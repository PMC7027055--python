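"""Hierarchical clustering with Pearson-correlation distance.

Samples (or peaks) are compared by ``d(i, j) = 1 - r(i, j)`` where r is the
Pearson correlation of their intensity vectors, and merged by average
linkage (UPGMA): the distance between two clusters is the unweighted mean of
all cross-pair distances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import CountMatrix, Dendrogram

logger = logging.getLogger(__name__)


def correlation_distance(
    m: CountMatrix | pd.DataFrame, axis: str = "samples"
) -> tuple[np.ndarray, list[str]]:
    """Pairwise ``1 - Pearson r`` distances between samples or peaks.

    Returns the symmetric distance matrix (zero diagonal) and the vector
    labels.  Constant vectors have undefined correlation and are rejected;
    filter them out first (e.g. with :func:`quantify.filter_min_signal`).
    """
    df = m.df if isinstance(m, CountMatrix) else m
    if axis == "samples":
        data = df.to_numpy(dtype=float).T
        labels = list(df.columns)
    elif axis == "peaks":
        data = df.to_numpy(dtype=float)
        labels = list(df.index)
    else:
        raise ValueError(f"axis must be 'samples' or 'peaks', got {axis!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 vectors to compute distances")
    sds = data.std(axis=1)
    if (sds == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant vector(s): {bad[:5]}; filter before clustering")
    r = np.corrcoef(data)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None), labels


def average_linkage(d: np.ndarray, labels: list[str]) -> Dendrogram:
    """UPGMA clustering of a precomputed distance matrix.

    Inter-cluster distance is the unweighted mean over all cross-pairs.
    Merge order follows SciPy's deterministic average-linkage algorithm;
    equal-height merges resolve to the lowest-index pair.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] != len(labels):
        raise ValueError("label count does not match matrix size")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(merges=merges, labels=list(labels), linkage=Z)


def cut_tree(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into k clusters.

    Cluster ids are renumbered deterministically by first occurrence in leaf
    order (cluster 0 contains the first leaf).
    """
    n = len(dend.labels)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        raw = np.arange(n)
    else:
        raw = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, c in zip(dend.labels, raw):
        if c not in remap:
            remap[c] = len(remap)
        out[label] = remap[c]
    return out


def to_newick(dend: Dendrogram) -> str:
    """Serialize the merge tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(dend.linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return dend.labels[node.id]
        left, right = node.get_left(), node.get_right()
        bl = lambda child: max(node.dist - child.dist, 0.0) / 2 if not child.is_leaf() else node.dist / 2
        return (
            f"({walk(left)}:{bl(left):.6g},{walk(right)}:{bl(right):.6g})"
        )

    return walk(tree) + ";"
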