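"""Cross-dataset comparison of kinetic measurements.

Published half-life and synthesis-rate datasets differ wildly in absolute
scale but are expected to agree in rank; the comparison therefore rests
on per-dataset distribution summaries, pairwise Spearman correlation
matrices over pairwise-complete gene overlaps, and hierarchical
clustering of the datasets by the Euclidean distance between their rows
of the correlation matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .association import spearman


def pairwise_spearman_matrix(
    mat: pd.DataFrame, min_n: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations between dataset columns.

    Each pair uses its pairwise-complete gene overlap; pairs with fewer
    than ``min_n`` common genes yield a missing cell with a warning.
    Returns (rho matrix, n matrix); the rho matrix is symmetric with unit
    diagonal.
    """
    cols = list(mat.columns)
    if len(cols) != len(set(cols)):
        raise ValueError("dataset column names must be unique")
    k = len(cols)
    rho = np.eye(k)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = int(mat[cols[i]].notna().sum())
    for i in range(k):
        for j in range(i + 1, k):
            pair = mat[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < min_n:
                warnings.warn(
                    f"{cols[i]} vs {cols[j]}: only {len(pair)} common genes; "
                    "correlation set missing",
                    stacklevel=2,
                )
                rho[i, j] = rho[j, i] = np.nan
                continue
            res = spearman(pair[cols[i]].to_numpy(), pair[cols[j]].to_numpy())
            rho[i, j] = rho[j, i] = res.rho
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(n, index=cols, columns=cols),
    )


def cluster_order(
    corr_matrix: pd.DataFrame, linkage: str = "complete"
) -> tuple[list[str], np.ndarray, str]:
    """Agglomerative clustering of datasets by their correlation profiles.

    Rows of the correlation matrix are treated as points; distances are
    Euclidean, linkage is complete by default.  Returns (leaf order,
    scipy linkage matrix, newick string).  Ties are broken
    deterministically by input order (scipy's convention).
    """
    if corr_matrix.isna().any().any():
        raise ValueError(
            "correlation matrix has missing cells; subset the datasets or "
            "impute before clustering"
        )
    labels = list(corr_matrix.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 datasets to cluster")
    dists = pdist(corr_matrix.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(dists, method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return order, Z, _to_newick(Z, labels)


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


def dataset_summary(mat: pd.DataFrame, sort_by_median: bool = False) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) and n per dataset.

    Quartiles use linear interpolation.  All-missing columns yield missing
    summaries; ``sort_by_median`` orders rows by median with a stable sort.
    """
    rows = {}
    for col in mat.columns:
        vals = mat[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            rows[col] = dict.fromkeys(("min", "q1", "median", "q3", "max"), np.nan)
            rows[col]["n"] = 0
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows[col] = {
            "min": vals.min(), "q1": q1, "median": med, "q3": q3,
            "max": vals.max(), "n": len(vals),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "dataset"
    if sort_by_median:
        out = out.sort_values("median", kind="stable")
    return out
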