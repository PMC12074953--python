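"""Exploratory views of a methylation matrix: top-variance feature
selection, sample correlation, PCA, hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import BetaMatrix
from .errors import DegenerateInputError, InsufficientDataError

#: feature counts used for the standard views: genome-wide, promoter-CGI,
#: enhancer blocks
DEFAULT_TOP_SD = {"genome": 30_000, "promoter_cgi": 1_000, "enhancer": 2_000}


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # components x features
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray    # scipy linkage encoding (merge order + heights)
    leaf_order: list[str]
    metric: str
    linkage: str
    newick: str


def select_top_sd(matrix: BetaMatrix, n: int) -> BetaMatrix:
    """Keep the ``n`` rows with the highest sample standard deviation.

    SD uses the n-1 denominator with NA excluded; ties are broken by row
    id lexicographic order so selection is deterministic.
    """
    if n > matrix.shape[0]:
        raise InsufficientDataError(
            f"requested top {n} rows of a {matrix.shape[0]}-row matrix"
        )
    sd = matrix.values.std(axis=1, ddof=1, skipna=True)
    # mergesort is stable; pre-sorting the index gives the lexicographic tie-break
    order = (
        pd.DataFrame({"sd": sd})
        .sort_index()
        .sort_values("sd", ascending=False, kind="mergesort")
    )
    keep = order.index[:n]
    return BetaMatrix(matrix.values.loc[keep], matrix.feature_level)


def spearman_matrix(matrix: BetaMatrix, min_rows: int = 3) -> pd.DataFrame:
    """Sample × sample Spearman correlation, midrank ties, pairwise-complete.

    Pairs sharing fewer than ``min_rows`` non-missing features get NA.
    """
    corr = matrix.values.corr(method="spearman", min_periods=min_rows)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pca(matrix: BetaMatrix, n_components: int | None = None) -> PCAResult:
    """PCA with samples as observations and features centered (not scaled)."""
    X = matrix.values.to_numpy(dtype=float).T  # samples x features
    n_samples, n_features = X.shape
    if n_samples < 2 or n_features < 2:
        raise InsufficientDataError("PCA needs >= 2 samples and >= 2 features")
    if np.isnan(X).any():
        raise InsufficientDataError("PCA input must be complete (no NA)")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise DegenerateInputError("zero-variance matrix")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    max_comp = min(n_samples, n_features)
    k = max_comp if n_components is None else min(n_components, max_comp)
    ev = S**2 / (n_samples - 1)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        (U[:, :k] * S[:k]), index=matrix.sample_ids, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:k], index=comp_names, columns=matrix.row_ids)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=ev[:k],
        explained_variance_ratio=ev[:k] / ev.sum(),
    )


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    parts = []
    for child in (node.get_left(), node.get_right()):
        branch = node.dist if child.is_leaf() else node.dist - child.dist
        parts.append(f"{_tree_to_newick(child, labels)}:{branch:.6g}")
    return "(" + ",".join(parts) + ")"


def hierarchical_cluster(
    matrix: BetaMatrix, metric: str = "euclidean", linkage: str = "ward"
) -> ClusterResult:
    """Agglomerative clustering of samples; deterministic for fixed input.

    Feature rows containing any NA are dropped before computing distances
    (documented behaviour); the dendrogram is also rendered as a Newick
    string with branch lengths from merge heights.
    """
    vals = matrix.values.dropna(axis=0, how="any")
    if vals.shape[1] < 2:
        raise InsufficientDataError("clustering needs >= 2 samples")
    if vals.shape[0] < 1:
        raise InsufficientDataError("no complete feature rows for clustering")
    X = vals.to_numpy(dtype=float).T
    dist = pdist(X, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    tree = hierarchy.to_tree(Z)
    labels = matrix.sample_ids
    newick = _tree_to_newick(tree, labels) + ";"
    leaf_order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        linkage_matrix=Z,
        leaf_order=leaf_order,
        metric=metric,
        linkage=linkage,
        newick=newick,
    )
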