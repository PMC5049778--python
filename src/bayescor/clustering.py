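"""Hierarchical clustering on correlation matrices.

Because the Bayesian correlation is a kernel, ``1 - r`` is a legitimate
dissimilarity and the correlation matrix can feed any similarity-based
learner directly.  Two dissimilarity modes are offered:

* ``one_minus_r`` — cluster entities with distance ``1 - r`` (the natural
  choice for grouping co-expressed entities);
* ``euclidean`` — Euclidean distance between rows of the correlation
  matrix (the choice typically used to order heatmap rows/columns).

Linkage and tree utilities come from :mod:`scipy.cluster.hierarchy`; the
merge tree can be serialized as a Newick string with branch lengths equal to
merge-height differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .correlation import CorrelationResult

__all__ = ["ClusterResult", "cluster_correlation", "linkage_to_newick"]


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of entities from a correlation matrix."""

    linkage: np.ndarray
    entity_ids: tuple
    distance: str
    linkage_method: str

    @property
    def leaf_order(self) -> list:
        """Entity ids in dendrogram leaf order."""
        return [self.entity_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage, list(self.entity_ids))


def _check_square_symmetric(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.isnan(M).any():
        raise ValueError("correlation matrix contains undefined (NaN) entries")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    return 0.5 * (M + M.T)


def cluster_correlation(
    result: CorrelationResult,
    distance: str = "one_minus_r",
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomeratively cluster entities from their correlation matrix.

    ``distance='one_minus_r'`` uses ``1 - r`` (entries in [0, 2], zero for
    perfectly correlated entities, so identical rows merge first);
    ``distance='euclidean'`` uses Euclidean distance between correlation
    profiles.  Default linkage is average (UPGMA).
    """
    M = _check_square_symmetric(result.matrix)
    if M.shape[0] < 2:
        raise ValueError("need at least two entities to cluster")
    if distance == "one_minus_r":
        D = 1.0 - M
        np.fill_diagonal(D, 0.0)
        condensed = squareform(np.clip(D, 0.0, None), checks=False)
    elif distance == "euclidean":
        condensed = pdist(M, metric="euclidean")
    else:
        raise ValueError(
            f"unknown distance {distance!r}; expected 'one_minus_r' or 'euclidean'")
    Z = hierarchy.linkage(condensed, method=linkage_method)
    return ClusterResult(
        linkage=Z,
        entity_ids=result.entity_ids,
        distance=distance,
        linkage_method=linkage_method,
    )


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a linkage matrix as a Newick tree with branch lengths.

    Branch lengths are differences of merge heights, so leaves sit at height
    zero and the root at the final merge height.
    """
    tree = hierarchy.to_tree(Z, rd=False)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
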