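"""Unsupervised molecular clustering of baseline expression.

Gene clusters come from k-means on per-gene z-scored VST expression of the
most-expressed genes (the ``cluster_expr`` filter decides membership);
sample structure comes from hierarchical clustering with Pearson
correlation distance and complete linkage. Cross-cohort gene-cluster
overlap is scored hypergeometrically, and cluster-phenotype association
uses chi-square / Fisher tests for categorical variables and
Kruskal-Wallis for continuous ones.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .diffexp import _bh

__all__ = [
    "zscore_genes",
    "kmeans_gene_clusters",
    "hcluster_samples",
    "cut_sample_tree",
    "cluster_overlap",
    "cluster_association",
    "linkage_to_newick",
]


def zscore_genes(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each gene (row) to mean 0, sd 1; zero-variance rows are an error."""
    mat = values.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=ddof)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        raise ValueError(f"zero-variance gene(s) cannot be z-scored: {bad[:5]}")
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def kmeans_gene_clusters(
    z: pd.DataFrame, k: int = 3, seed: int = 0, n_init: int = 25
) -> pd.Series:
    """K-means clustering of genes (rows), Lloyd's algorithm with seeded
    k-means++ restarts; the best within-cluster SSE solution is kept."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > z.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes ({z.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(z.to_numpy(dtype=float))
    return pd.Series(labels, index=z.index, name="gene_cluster")


def hcluster_samples(values: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples (columns).

    Distance is 1 - Pearson correlation between sample profiles over the
    supplied genes; linkage is complete. Returns the scipy linkage matrix
    and the sample IDs in leaf order.
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = values.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    if (sd == 0).any():
        bad = list(values.columns[sd == 0])
        raise ValueError(f"zero-variance sample(s) under correlation distance: {bad}")
    corr = np.corrcoef(mat.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    order = hierarchy.leaves_list(Z)
    return Z, [values.columns[i] for i in order]


def cut_sample_tree(Z: np.ndarray, sample_ids, k: int) -> pd.Series:
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(sample_ids), name="sample_cluster")


def correlation_distance(values: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns."""
    mat = values.to_numpy(dtype=float)
    corr = np.corrcoef(mat.T)
    return pd.DataFrame(1.0 - corr, index=values.columns, columns=values.columns)


def cluster_overlap(
    sets_a: dict, sets_b: dict, universe
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise overlap of two gene clusterings with hypergeometric p-values.

    Returns (overlap count matrix, BH-adjusted one-sided p matrix), rows =
    clusters of A, columns = clusters of B.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    for name, s in {**{f"A:{k}": v for k, v in sets_a.items()},
                    **{f"B:{k}": v for k, v in sets_b.items()}}.items():
        if not set(s) <= uni:
            raise ValueError(f"cluster {name} not a subset of the universe")
    N = len(uni)
    counts = pd.DataFrame(0, index=list(sets_a), columns=list(sets_b))
    pvals = pd.DataFrame(1.0, index=list(sets_a), columns=list(sets_b))
    for a, ga in sets_a.items():
        sa = set(ga)
        for b, gb in sets_b.items():
            sb = set(gb)
            k = len(sa & sb)
            counts.loc[a, b] = k
            pvals.loc[a, b] = stats.hypergeom.sf(k - 1, N, len(sa), len(sb))
    flat = _bh(pvals.to_numpy().ravel())
    qmat = pd.DataFrame(
        flat.reshape(pvals.shape), index=pvals.index, columns=pvals.columns
    )
    return counts, qmat


def cluster_association(
    labels: pd.Series,
    clinical: pd.DataFrame,
    categorical: list[str] | None = None,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Per-variable association between sample clusters and phenotypes.

    Categorical variables get a chi-square test of the contingency table,
    falling back to Fisher's exact test (2x2 tables) when any expected
    count is at or below ``min_expected``; continuous variables get a
    Kruskal-Wallis test across clusters.
    """
    labels = labels.loc[clinical.index]
    if labels.nunique() < 2:
        raise ValueError("all samples in one cluster")
    if categorical is None:
        categorical = [
            c for c in clinical.columns
            if clinical[c].dtype == object or clinical[c].dtype == bool
        ]
    rows = []
    for col in clinical.columns:
        x = clinical[col]
        if col in categorical:
            tab = pd.crosstab(labels, x)
            chi2, p, dof, expected = stats.chi2_contingency(tab)
            test = "chi2"
            if (expected <= min_expected).any() and tab.shape == (2, 2):
                _, p = stats.fisher_exact(tab.to_numpy())
                test = "fisher"
        else:
            groups = [x[labels == g].to_numpy(dtype=float) for g in labels.unique()]
            groups = [g for g in groups if len(g)]
            if len(groups) < 2 or all(np.all(g == groups[0][0]) for g in groups):
                rows.append((col, "kruskal", 1.0))
                continue
            _, p = stats.kruskal(*groups)
            test = "kruskal"
        rows.append((col, test, float(p)))
    return pd.DataFrame(rows, columns=["variable", "test", "p_value"]).set_index("variable")


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def build(node):
        if node.is_leaf():
            return names[node.id], 0.0
        ls, lh = build(node.left)
        rs, rh = build(node.right)
        bl_l = node.dist - lh
        bl_r = node.dist - rh
        return f"({ls}:{bl_l:.6g},{rs}:{bl_r:.6g})", node.dist

    s, _ = build(tree)
    return s + ";"
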