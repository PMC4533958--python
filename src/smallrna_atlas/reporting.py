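"""Expression reporting: top-N selection, sample clustering, volcano and
heatmap table export.

Samples are clustered on variance-stabilized expression of the most
highly expressed features with Euclidean distances and complete-linkage
agglomeration; heatmap output is data (ordered matrix), not an image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)


def top_n_features(vst_matrix: pd.DataFrame, n: int) -> pd.DataFrame:
    """The n features with the highest mean expression across samples.

    Ties are broken lexicographically on the feature id so the selection
    is deterministic.  n larger than the matrix returns every feature
    with a warning.
    """
    if n > len(vst_matrix):
        log.warning("requested top %d of %d features: returning all",
                    n, len(vst_matrix))
        n = len(vst_matrix)
    order = pd.DataFrame({
        "_mean": vst_matrix.mean(axis=1),
        "_id": vst_matrix.index.astype(str),
    }).sort_values(["_mean", "_id"], ascending=[False, True], kind="stable")
    return vst_matrix.loc[order.index[:n]]


@dataclass
class Dendrogram:
    """Complete-linkage sample dendrogram.

    ``linkage`` is a scipy linkage matrix over the samples in ``labels``
    order; merge heights are non-decreasing (complete linkage is
    monotone).
    """

    linkage: np.ndarray
    labels: list[str]

    def cut(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, n_clusters,
                                    criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                # quoting keeps underscores literal in newick consumers
                return "'" + self.labels[node.id].replace("'", "''") + "'"
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left},{right}):{node.dist:.6g}"

        body = walk(tree)
        # root branch length is meaningless; strip it
        if ":" in body:
            body = body.rsplit(":", 1)[0]
        return body + ";"


def cluster_samples(vst_matrix: pd.DataFrame,
                    feature_subset: pd.Index | list[str] | None = None
                    ) -> Dendrogram:
    """Euclidean complete-linkage clustering of the samples (columns)."""
    if vst_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    mat = (vst_matrix.loc[feature_subset] if feature_subset is not None
           else vst_matrix)
    dist = pdist(mat.to_numpy(float).T, metric="euclidean")
    linkage = hierarchy.linkage(dist, method="complete")
    return Dendrogram(linkage=linkage, labels=list(mat.columns))


def heatmap_table(vst_matrix: pd.DataFrame, feature_subset,
                  dendrogram: Dendrogram) -> pd.DataFrame:
    """VST matrix restricted to the subset, columns in dendrogram leaf
    order and rows by descending mean expression (plot-ready)."""
    sub = vst_matrix.loc[feature_subset, dendrogram.leaf_order]
    return sub.loc[sub.mean(axis=1).sort_values(ascending=False,
                                                kind="stable").index]


def volcano_table(de_results: pd.DataFrame, padj_threshold: float = 1e-8,
                  lfc_threshold: float = 5.0) -> pd.DataFrame:
    """Plot-ready volcano columns from a differential expression table.

    Infinite fold changes are clamped to ±(max finite |log2FC| + 1) and
    marked ``is_infinite`` so a plotting layer can show them at the
    margin.  The significance flag follows the configured thresholds
    (default padj < 1e-8 and |log2FC| > 5).
    """
    lfc = de_results["log2FoldChange"].to_numpy(float)
    finite = np.isfinite(lfc)
    clamp = (np.nanmax(np.abs(lfc[finite])) + 1.0) if finite.any() else 1.0
    plot_lfc = np.where(np.isposinf(lfc), clamp,
                        np.where(np.isneginf(lfc), -clamp, lfc))
    padj = de_results["padj"].to_numpy(float)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(padj)
    sig = (padj < padj_threshold) & (np.abs(lfc) > lfc_threshold)
    return pd.DataFrame({
        "feature": de_results.index,
        "log2FoldChange": plot_lfc,
        "neg_log10_padj": neglog,
        "baseMean": de_results["baseMean"].to_numpy(float),
        "is_infinite": ~np.isfinite(lfc) & ~np.isnan(lfc),
        "significant": sig,
    }).set_index("feature")
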