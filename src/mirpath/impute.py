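"""K-nearest-neighbour imputation with correlation similarity.

Missing entries of a miRNA × cell-line matrix are filled from the rows
most similar to the incomplete row, where similarity is the Pearson
correlation computed over jointly observed columns.  A neighbour only
contributes to a given cell if it has a value in that column; otherwise
the next-nearest row is used.  Cells with no eligible neighbour fall back
to the row mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ImputedMatrix", "knn_impute"]


@dataclass
class ImputedMatrix:
    values: np.ndarray
    imputed_mask: np.ndarray
    # (row, col) cells filled by the row-mean fallback rather than neighbours
    fallback_cells: list[tuple[int, int]] = field(default_factory=list)


def _row_correlations(values: np.ndarray, i: int, min_overlap: int) -> np.ndarray:
    """Pairwise-complete Pearson correlation of row i against every row.

    Rows with fewer than ``min_overlap`` jointly observed columns, or with
    zero variance on the overlap, get NaN (ineligible neighbours).
    """
    n_rows = values.shape[0]
    out = np.full(n_rows, np.nan)
    xi = values[i]
    obs_i = ~np.isnan(xi)
    for r in range(n_rows):
        if r == i:
            continue
        both = obs_i & ~np.isnan(values[r])
        if both.sum() < min_overlap:
            continue
        a = xi[both]
        b = values[r][both]
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            continue
        out[r] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return out


def knn_impute(
    values: np.ndarray, k: int = 3, min_overlap: int = 3
) -> ImputedMatrix:
    """Fill NaN entries from the k most-correlated rows.

    Parameters
    ----------
    values : array, miRNAs × cell lines, NaN = missing
    k : number of neighbours averaged per cell (default 3)
    min_overlap : minimum jointly observed columns for a usable correlation

    Each row must retain at least 2 observed entries (sparser rows are
    expected to be filtered out upstream).  Neighbour ties in correlation
    break by row order.  Idempotent on complete matrices.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    values = np.asarray(values, dtype=float)
    filled = values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return ImputedMatrix(filled, missing)
    if (np.sum(~missing, axis=1) < 2).any():
        raise ValueError("every row must have at least 2 observed entries")

    fallback: list[tuple[int, int]] = []
    for i in np.flatnonzero(missing.any(axis=1)):
        corr = _row_correlations(values, i, min_overlap)
        # stable descending order: most similar first, ties by row index
        order = np.argsort(-corr, kind="stable")
        order = [r for r in order if np.isfinite(corr[r])]
        row_mean = np.nanmean(values[i])
        for j in np.flatnonzero(missing[i]):
            donors = [r for r in order if not np.isnan(values[r, j])][:k]
            if donors:
                filled[i, j] = np.mean(values[donors, j])
            else:
                filled[i, j] = row_mean
                fallback.append((int(i), int(j)))
                logger.warning(
                    "no eligible neighbour for cell (%d, %d); row-mean fallback", i, j
                )
    return ImputedMatrix(filled, missing, fallback)
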