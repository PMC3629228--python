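"""Hierarchical clustering of expression profiles for heatmap ordering.

Dissimilarity between profiles is 1 − Spearman ρ (rank correlation), so
the ordering is invariant to any monotone transform of the values.
Agglomeration uses average linkage (UPGMA).  Profiles with zero variance
have undefined rank correlation; their dissimilarity to every other
profile is set to the maximum of 2.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["Dendrogram", "spearman_dissimilarity", "cluster_rows_cols"]

MAX_DISSIMILARITY = 2.0  # 1 - (-1), assigned when rho is undefined


@dataclass
class Dendrogram:
    """Merge history (scipy linkage matrix) plus labelled leaf order."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialize with branch lengths = parent height − child height."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def spearman_dissimilarity(rows: np.ndarray) -> np.ndarray:
    """Condensed 1 − Spearman-ρ dissimilarity between the rows."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 profiles")
    if rows.shape[1] < 2:
        raise ValueError("need at least 2 observations per profile")
    ranks = np.apply_along_axis(rankdata, 1, rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    d = 1.0 - np.asarray(rho)
    undef = np.isnan(d)
    if undef.any():
        logger.warning(
            "%d profile pairs have undefined rank correlation; "
            "dissimilarity set to %.1f", undef.sum() // 2, MAX_DISSIMILARITY,
        )
        d[undef] = MAX_DISSIMILARITY
    np.fill_diagonal(d, 0.0)
    # numerical symmetry for squareform
    d = (d + d.T) / 2.0
    return squareform(d, checks=False)


def cluster_rows_cols(values: np.ndarray, row_labels, col_labels
                      ) -> tuple[Dendrogram, Dendrogram]:
    """Average-linkage dendrograms for both axes of a complete matrix."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix must be complete (impute first)")
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    zr = hierarchy.linkage(spearman_dissimilarity(values), method="average")
    zc = hierarchy.linkage(spearman_dissimilarity(values.T), method="average")
    return Dendrogram(zr, list(row_labels)), Dendrogram(zc, list(col_labels))
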