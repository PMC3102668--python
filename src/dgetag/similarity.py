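"""Library-to-library similarity: correlation matrix and hierarchical clustering.

Libraries are compared by Pearson correlation of log2(TPM + 1) over all genes
(or a supplied subset, e.g. a curated myogenesis list), then agglomerated on
distance 1 - r (average linkage by default) and exported as a Newick tree
with branch lengths equal to merge-height differences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def correlation_matrix(
    tpm: pd.DataFrame,
    gene_subset: list[str] | None = None,
    log: bool = True,
) -> pd.DataFrame:
    """Pairwise Pearson correlation between libraries (columns of ``tpm``).

    Zero-variance libraries yield NaN correlations (reported with a warning);
    the diagonal is always 1.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    m = tpm.loc[gene_subset] if gene_subset is not None else tpm
    vals = np.log2(m.to_numpy(dtype=float) + 1.0) if log else m.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    degenerate = [lib for lib, s in zip(m.columns, sd) if s == 0]
    if degenerate:
        warnings.warn(f"zero-variance libraries, correlations undefined: {degenerate}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = pd.DataFrame(corr, index=m.columns, columns=m.columns)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def hierarchical_cluster(corr: pd.DataFrame, method: str = "average") -> str:
    """Agglomerate libraries on distance 1 - r and return a Newick string.

    Libraries with any undefined correlation are dropped with a warning.
    Branch lengths are the difference between a node's merge height and its
    child's; leaves sit at height 0.
    """
    bad = corr.columns[corr.isna().any(axis=0)].tolist()
    if bad:
        warnings.warn(f"dropping libraries with undefined correlations: {bad}")
        keep = [c for c in corr.columns if c not in bad]
        corr = corr.loc[keep, keep]
    labels = list(corr.columns)
    if len(labels) < 2:
        raise ValueError("need at least 2 usable libraries to cluster")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.10g}"

    left = newick(tree.left, tree.dist)
    right = newick(tree.right, tree.dist)
    return f"({left},{right});"
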