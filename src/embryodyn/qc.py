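"""Sample-level structure checks: clustering, PCA, pairwise correlation.

Expression is log10(FPKM + 1) throughout (the offset keeps zeros finite).
Clustering uses 1 − Pearson r distance with average linkage on a chosen
gene subset (conventionally the DEG union); PCA filters to genes with mean
FPKM ≥ 1 and centers per gene; the correlation matrix reports squared
Pearson coefficients (R²) for every sample pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA


@dataclass
class LinkageTree:
    """Agglomerative merge history over samples.

    ``merges`` is the scipy linkage matrix (left, right, height, size);
    nodes 0..n−1 are leaves in ``labels`` order, later rows define nodes
    n, n+1, ...
    """

    merges: np.ndarray
    labels: list[str]
    metric: str = "1-pearson"
    linkage: str = "average"

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.merges)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["left", "right", "height", "n_leaves"])


def _log_expr(fpkm: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    return np.log10(fpkm + offset)


def hclust_samples(fpkm: pd.DataFrame, gene_subset=None, offset: float = 1.0,
                   linkage: str = "average") -> LinkageTree:
    """Average-linkage clustering on 1 − Pearson r of log10(FPKM+offset)."""
    if fpkm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sub = fpkm if gene_subset is None else fpkm.loc[list(gene_subset)]
    if sub.empty:
        raise ValueError("gene subset is empty")
    mat = _log_expr(sub, offset).to_numpy(float)
    sd = mat.std(axis=0)
    if (sd == 0).any():
        bad = fpkm.columns[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero variance under the gene subset")
    corr = np.corrcoef(mat.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    merges = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return LinkageTree(merges=merges, labels=list(fpkm.columns), linkage=linkage)


def pca_samples(fpkm: pd.DataFrame, min_mean_fpkm: float = 1.0,
                offset: float = 1.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance-explained fractions.

    Genes are filtered to mean FPKM ≥ min_mean_fpkm, log-transformed and
    centered per gene; fractions over all components sum to 1.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    keep = fpkm.mean(axis=1) >= min_mean_fpkm
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes pass the mean-FPKM filter")
    mat = _log_expr(fpkm[keep], offset).to_numpy(float)
    centered = (mat - mat.mean(axis=1, keepdims=True)).T  # samples × genes
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(centered)
    coords = pd.DataFrame(
        scores, index=fpkm.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    return coords, pca.explained_variance_ratio_


def pairwise_r2(fpkm: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Squared Pearson correlation of log10(FPKM+offset) per sample pair.

    Zero-variance samples yield missing entries (NaN), never 0.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = _log_expr(fpkm, offset).to_numpy(float)
    sd = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat.T)
    r2 = corr**2
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=fpkm.columns, columns=fpkm.columns)
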