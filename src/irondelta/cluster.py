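"""Row z-scoring, hierarchical clustering of iron-regulated genes, and a
generic over-representation test for cluster annotation.

The clustering view averages replicates within each genotype x condition
cell (four columns), z-scores each gene across the four cells (so the
heat-map scale is standard deviations from the gene's mean) and
agglomerates genes with Euclidean distance and average linkage. Cluster
annotation uses a one-tailed hypergeometric over-representation test per
term with BH correction across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .quantify import normalized_counts
from .simulate import CONDITIONS, GENOTYPES, CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    gene_order: list[str]
    z_matrix: pd.DataFrame
    linkage: np.ndarray
    cut_assignments: pd.Series | None


def condition_means(counts: CountMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    """Mean normalized count per gene in each genotype x condition cell."""
    norm = normalized_counts(counts)
    if genes is not None:
        norm = norm.loc[genes]
    cols = {}
    for g in GENOTYPES:
        for c in CONDITIONS:
            mask = counts.sample_mask(g, c)
            if not mask.any():
                raise ValueError(f"missing design cell: ({g}, {c})")
            cols[f"{g}_{c}"] = norm.to_numpy()[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=norm.index)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores with the n-1 denominator; constant rows dropped.

    Dropped rows are reported through the module logger.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to z-score rows")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info(
            "dropping %d constant row(s): %s",
            int(constant.sum()),
            list(matrix.index[constant]),
        )
    vals = vals[~constant]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[~constant, None]
    return pd.DataFrame(z, index=matrix.index[~constant], columns=matrix.columns)


def hierarchical_cluster(
    z: pd.DataFrame,
    distance: str = "euclidean",
    linkage_method: str = "average",
    k: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering of genes; leaf order from the dendrogram."""
    if len(z) < 2:
        raise ValueError("need >= 2 genes to cluster")
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError("non-finite values in z matrix")
    dists = pdist(z.to_numpy(), metric=distance)
    link = hierarchy.linkage(dists, method=linkage_method)
    order = hierarchy.leaves_list(link)
    cut = None
    if k is not None:
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        cut = pd.Series(labels, index=z.index, name="cluster")
    return ClusterResult(
        gene_order=[z.index[i] for i in order],
        z_matrix=z,
        linkage=link,
        cut_assignments=cut,
    )


def overrepresentation(
    cluster_genes, annotation: pd.DataFrame, universe
) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation of terms in a cluster.

    ``annotation`` is a two-column table (gene_id, term); multiple terms
    per gene are allowed. Returns per term: count (overlap with the
    cluster), expected count under random draws, upper-tail p, BH padj.
    """
    cluster = set(cluster_genes)
    uni = set(universe)
    outside = cluster - uni
    if outside:
        raise ValueError(f"cluster gene(s) outside universe: {sorted(outside)}")
    ann = annotation[annotation["gene_id"].isin(uni)]
    M, n = len(uni), len(cluster)
    rows = []
    for term, grp in ann.groupby("term", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & cluster)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {"term": term, "count": k, "expected": n * K / M, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term", "count", "expected", "p_value"])
    out["padj"] = bh_adjust(out["p_value"]) if len(out) else out["p_value"]
    return out
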