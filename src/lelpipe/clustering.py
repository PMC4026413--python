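"""Heatmap preparation: gene-wise z-transform and row clustering.

Rows (genes) are standardized to zero mean and unit sample variance,
then ordered by agglomerative hierarchical clustering with complete
linkage on Euclidean distances — the standard expression-heatmap recipe.
Columns are left in their experimental order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = ["Dendrogram", "z_transform_rows", "hierarchical_cluster"]


@dataclass
class Dendrogram:
    """Merge sequence and leaf order of an agglomerative clustering.

    ``merges`` is the (n-1) x 4 linkage matrix (cluster id, cluster id,
    merge height, new cluster size); leaves are numbered 0..n-1 in input
    order and internal clusters n..2n-2 in merge order.
    """

    merges: np.ndarray
    leaf_order: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def z_transform_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Standardize each row to mean 0, sample sd 1 (ddof=1).

    Constant rows cannot be scaled; they are set to all-zero and their
    ids returned as the second element.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-transform needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return out, matrix.index[constant]


def hierarchical_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Complete-linkage, Euclidean-distance clustering of the rows.

    Leaf order is the depth-first traversal of the resulting dendrogram.
    Raises ValueError on non-finite values or fewer than 2 rows.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values")
    merges = linkage(pdist(values, metric="euclidean"), method="complete")
    return Dendrogram(merges=merges, leaf_order=leaves_list(merges))


def ordered_heatmap(matrix: pd.DataFrame) -> tuple[pd.DataFrame, Dendrogram, pd.Index]:
    """Z-transform rows, cluster them, and return the re-ordered matrix."""
    z, constant = z_transform_rows(matrix)
    dendro = hierarchical_cluster(z)
    return z.iloc[dendro.leaf_order], dendro, constant
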