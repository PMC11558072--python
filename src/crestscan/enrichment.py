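"""Size-matched permutation test for selection-signal enrichment.

Question: do the genes of one expression cluster (optionally intersected
with a functional gene set) sit near unusually strong cross-population
haplotype-homozygosity signal?

Each gene is summarized by the median scan statistic (``-log10 p`` by
default, ``|z|`` selectable) over the SNPs falling in a fixed-length window
immediately upstream of its TSS (strand-aware, clipped at the chromosome
start).  Genes whose window contains no scanned SNP are undefined and
excluded, with a report.  The observed cluster statistic is the median (or
mean) of the per-gene values; the null is built by repeatedly drawing the
same number of genes, without replacement, from the background of genes
outside the cluster that have defined window statistics — size-matched
genic windows by construction, since every window has the same length and
is anchored at a gene TSS.  The empirical p-value is
``(1 + #{null >= observed}) / (B + 1)``, one-sided in the enrichment
direction, and can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import GenomeAnnotation


@dataclass
class EnrichmentConfig:
    """Parameters of the window statistic and the permutation null.

    upstream_window_bp
        Length of the strand-aware window upstream of each TSS (default
        25 kb).
    n_perm
        Number of permutation draws B (default 1000).
    gene_stat
        Per-SNP quantity whose window median summarizes a gene:
        ``median_neglogp`` or ``median_z_abs``.
    summary_stat
        How per-gene values are pooled into the cluster statistic:
        ``median`` (default) or ``mean``.
    """

    upstream_window_bp: int = 25_000
    n_perm: int = 1000
    gene_stat: str = "median_neglogp"
    summary_stat: str = "median"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upstream_window_bp < 1:
            raise ValueError("upstream_window_bp must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.gene_stat not in ("median_neglogp", "median_z_abs"):
            raise ValueError("gene_stat must be median_neglogp or median_z_abs")
        if self.summary_stat not in ("median", "mean"):
            raise ValueError("summary_stat must be median or mean")


@dataclass
class EnrichmentResult:
    """Observed cluster statistic, its permutation null and empirical p."""

    cluster: str
    gene_set_name: str
    n_genes_used: int
    observed_stat: float
    null_stats: np.ndarray = field(repr=False)
    empirical_p: float = 1.0


def gene_window_stat(gene: pd.Series, scan: pd.DataFrame,
                     cfg: EnrichmentConfig | None = None) -> float | None:
    """Median scan statistic over SNPs in the gene's upstream window.

    ``gene`` needs fields chrom, start, end, strand.  Returns ``None``
    (undefined) when no scanned SNP falls in the window.
    """
    cfg = cfg or EnrichmentConfig()
    w = cfg.upstream_window_bp
    if gene["strand"] == "+":
        lo, hi = max(1, int(gene["start"]) - w), int(gene["start"]) - 1
    else:
        lo, hi = int(gene["end"]) + 1, int(gene["end"]) + w
    if hi < lo:
        return None
    sub = scan[(scan["chrom"] == gene["chrom"])
               & (scan["pos"] >= lo) & (scan["pos"] <= hi)]
    if sub.empty:
        return None
    col = "neg_log10_p" if cfg.gene_stat == "median_neglogp" else "xpehh_std"
    vals = sub[col].to_numpy(dtype=float)
    if cfg.gene_stat == "median_z_abs":
        vals = np.abs(vals)
    return float(np.median(vals))


def compute_gene_stats(annotation: GenomeAnnotation, scan: pd.DataFrame,
                       cfg: EnrichmentConfig | None = None) -> pd.Series:
    """Window statistic for every annotated gene (NaN where undefined).

    Vectorized over genes with a position-sorted scan table; equivalent to
    calling :func:`gene_window_stat` per gene.
    """
    cfg = cfg or EnrichmentConfig()
    col = "neg_log10_p" if cfg.gene_stat == "median_neglogp" else "xpehh_std"
    out = pd.Series(np.nan, index=annotation.genes["gene_id"].to_numpy(),
                    name="window_stat")
    w = cfg.upstream_window_bp
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        vals = sub[col].to_numpy(dtype=float)
        if cfg.gene_stat == "median_z_abs":
            vals = np.abs(vals)
        genes = annotation.genes[annotation.genes["chrom"] == chrom]
        plus = genes["strand"].to_numpy() == "+"
        lo = np.where(plus, np.maximum(1, genes["start"].to_numpy() - w),
                      genes["end"].to_numpy() + 1)
        hi = np.where(plus, genes["start"].to_numpy() - 1,
                      genes["end"].to_numpy() + w)
        i0 = np.searchsorted(pos, lo, side="left")
        i1 = np.searchsorted(pos, hi, side="right")
        for gid, a, b in zip(genes["gene_id"], i0, i1):
            if b > a:
                out[gid] = float(np.median(vals[a:b]))
    return out


def _summary(vals: np.ndarray, cfg: EnrichmentConfig) -> float:
    return float(np.median(vals) if cfg.summary_stat == "median" else vals.mean())


def cluster_enrichment(cluster_genes: Iterable[str], all_genes: Iterable[str],
                       gene_stats: pd.Series,
                       cfg: EnrichmentConfig | None = None,
                       cluster_label: str = "cluster",
                       gene_set_name: str = "all") -> EnrichmentResult:
    """Permutation enrichment of a gene cluster against a genic background.

    ``gene_stats`` maps gene id to its window statistic (NaN = undefined),
    e.g. from :func:`compute_gene_stats`.  The null resamples
    ``n_genes_used`` background genes (all_genes minus cluster_genes, with
    defined statistics) without replacement, B times, deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or EnrichmentConfig()
    cluster_genes = list(dict.fromkeys(cluster_genes))
    all_set = set(all_genes)
    stray = [g for g in cluster_genes if g not in all_set]
    if stray:
        raise ValueError(f"cluster genes outside the gene pool: {stray[:5]}")
    obs_vals = gene_stats.reindex(cluster_genes).dropna().to_numpy(dtype=float)
    n_used = obs_vals.size
    if n_used == 0:
        raise ValueError("no cluster gene has a defined window statistic")
    cluster_set = set(cluster_genes)
    bg_ids = [g for g in all_genes if g not in cluster_set]
    bg_vals = gene_stats.reindex(bg_ids).dropna().to_numpy(dtype=float)
    if bg_vals.size < n_used:
        raise ValueError(
            f"background has {bg_vals.size} eligible genes, fewer than the "
            f"{n_used} cluster genes to match")
    observed = _summary(obs_vals, cfg)
    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_perm)
    for b in range(cfg.n_perm):
        draw = rng.choice(bg_vals, size=n_used, replace=False)
        null[b] = _summary(draw, cfg)
    emp_p = (1.0 + int((null >= observed).sum())) / (cfg.n_perm + 1.0)
    return EnrichmentResult(cluster=str(cluster_label),
                            gene_set_name=gene_set_name,
                            n_genes_used=n_used, observed_stat=observed,
                            null_stats=null, empirical_p=emp_p)


def ranksum_enrichment(cluster_genes: Iterable[str], all_genes: Iterable[str],
                       gene_stats: pd.Series) -> float:
    """Alternative whole-distribution comparison (non-default).

    One-sided Mann–Whitney p for cluster gene statistics being larger than
    the background's; provided as a cross-check on the permutation summary.
    """
    cluster_set = set(cluster_genes)
    obs = gene_stats.reindex(list(cluster_set)).dropna().to_numpy()
    bg = gene_stats.reindex(
        [g for g in all_genes if g not in cluster_set]).dropna().to_numpy()
    return float(mannwhitneyu(obs, bg, alternative="greater").pvalue)


def enrich_all_clusters(labels: pd.Series, gene_stats: pd.Series,
                        cfg: EnrichmentConfig | None = None,
                        gene_set: set[str] | None = None,
                        gene_set_name: str = "all") -> pd.DataFrame:
    """Run :func:`cluster_enrichment` for every cluster label.

    ``labels`` maps gene id to cluster; ``gene_set`` optionally restricts
    the cluster genes tested (the background stays genome-wide).  Clusters
    whose test is infeasible (no defined statistic) are reported with NaN.
    Per-cluster seeds are derived from ``cfg.seed``.
    """
    cfg = cfg or EnrichmentConfig()
    pool = list(gene_stats.index)
    rows = []
    for cl in sorted(labels.unique()):
        genes = [g for g in labels.index[labels == cl]]
        if gene_set is not None:
            genes = [g for g in genes if g in gene_set]
        sub_cfg = EnrichmentConfig(
            upstream_window_bp=cfg.upstream_window_bp, n_perm=cfg.n_perm,
            gene_stat=cfg.gene_stat, summary_stat=cfg.summary_stat,
            seed=int(np.random.SeedSequence([cfg.seed, int(cl)]).generate_state(1)[0] % (2**31)))
        try:
            res = cluster_enrichment(genes, pool, gene_stats, sub_cfg,
                                     cluster_label=str(cl),
                                     gene_set_name=gene_set_name)
            rows.append((str(cl), gene_set_name, res.n_genes_used,
                         res.observed_stat, res.empirical_p))
        except ValueError:
            rows.append((str(cl), gene_set_name, 0, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["cluster", "gene_set", "n_genes_used",
                                       "observed_stat", "empirical_p"])
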