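"""Trajectory clustering of per-(species, stage) expression profiles.

Each gene's profile is the vector of mean normalized counts per
(species, stage) cell, ordered species-major then stage-ordinal, Z-scored
per gene (sample standard deviation, n-1 denominator).  Genes with a
constant profile cannot be scaled and are excluded with a report.  The
scaled profiles are clustered agglomeratively (complete linkage on
Euclidean distance by default, correlation distance selectable) and the
tree is cut into exactly K flat clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA


@dataclass
class ClusterAssignment:
    """Flat K-cluster membership plus the scaled profiles it was cut from."""

    labels: pd.Series          # gene_id -> cluster label in 1..k
    scaled: pd.DataFrame       # genes x (species, stage) Z-scored profiles
    k: int
    metric: str
    method: str


def stage_profiles(norm_counts: pd.DataFrame, meta: pd.DataFrame,
                   stage_order: list[str] | None = None) -> pd.DataFrame:
    """Mean normalized count per (species, stage) cell, per gene.

    Columns are a (species, stage) MultiIndex ordered species-major then by
    stage ordinal (``stage_order``, or order of first appearance in the
    metadata).  Every (species, stage) combination must have at least one
    sample; missing cells are an error listing the offenders.
    """
    species = list(dict.fromkeys(meta["species"]))
    stages = stage_order or list(dict.fromkeys(meta["stage"]))
    cells = [(sp, st) for sp in species for st in stages]
    missing = [c for c in cells
               if not ((meta["species"] == c[0]) & (meta["stage"] == c[1])).any()]
    if missing:
        raise ValueError(f"missing (species, stage) cells: {missing}")
    cols = {}
    for sp, st in cells:
        samples = meta.index[(meta["species"] == sp) & (meta["stage"] == st)]
        cols[(sp, st)] = norm_counts[samples].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(cells, names=["species", "stage"])
    return out


def zscore(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Z-scores (n-1 sd); constant genes excluded and reported."""
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    excluded = list(profiles.index[~keep])
    z = (x[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=profiles.index[keep],
                        columns=profiles.columns), excluded


def hcluster_cut(scaled: pd.DataFrame, k: int = 7, metric: str = "euclidean",
                 method: str = "complete") -> ClusterAssignment:
    """Agglomerative hierarchy cut into exactly ``k`` flat clusters.

    Labels are relabelled to 1..k in order of first gene appearance so the
    assignment is deterministic given the input order.
    """
    n = len(scaled)
    if k < 2 or k > n:
        raise ValueError(f"k must lie in [2, n_genes={n}], got {k}")
    metric_name = "correlation" if metric == "correlation" else "euclidean"
    link = linkage(scaled.to_numpy(dtype=float), method=method,
                   metric=metric_name)
    raw = fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(
            f"could not cut the tree into exactly {k} clusters "
            f"(got {len(np.unique(raw))}); identical profiles may collide")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return ClusterAssignment(
        labels=pd.Series(labels, index=scaled.index, name="cluster"),
        scaled=scaled, k=k, metric=metric_name, method=method)


def cluster_trajectories(assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-cluster mean and sd trajectory over (species, stage) cells.

    The returned long table (cluster, species, stage, mean, sd) is the
    substrate for trajectory plots; sd uses the n-1 denominator and is 0
    for singleton clusters.
    """
    rows = []
    for cl in range(1, assignment.k + 1):
        sub = assignment.scaled[assignment.labels == cl]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1).fillna(0.0) if len(sub) > 1 else mean * 0.0
        for (sp, st) in assignment.scaled.columns:
            rows.append((cl, sp, st, float(mean[(sp, st)]), float(sd[(sp, st)])))
    return pd.DataFrame(rows, columns=["cluster", "species", "stage",
                                       "mean", "sd"])


def pca_qc(norm_counts: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample-level PCA on centered, unit-variance log1p normalized counts.

    A thin QC utility: returns per-sample PC coordinates with the variance
    fraction of each component in the column name.
    """
    x = np.log1p(norm_counts.to_numpy(dtype=float)).T  # samples x genes
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    x = x[:, sd > 0] / sd[sd > 0]
    n_components = min(n_components, min(x.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1} ({100 * v:.1f}%)"
            for i, v in enumerate(pca.explained_variance_ratio_)]
    return pd.DataFrame(coords, index=norm_counts.columns, columns=cols)
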