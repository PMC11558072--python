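"""Count normalization and stage-matched two-species differential expression.

Normalization uses the median-of-ratios method: each sample's size factor is
the median, over genes positive in every sample, of the ratio of that
sample's count to the gene's geometric-mean count across samples.

The per-stage test is a transparent negative-binomial Wald scheme on
normalized counts: group means ``m_A, m_B``, ``log2FC = log2((m_B + c) /
(m_A + c))`` with pseudo-count ``c``; per-gene dispersion ``alpha`` by the
method of moments (``(var - mean) / mean^2`` per group, maximum over the
two groups, floored at 1e-8); the standard error of the log fold change by
the delta method from the NB variance ``var(m) = (m + alpha m^2) / n``.
This is deliberately simpler than shrinkage-based NB GLM fitters — no
empirical-Bayes dispersion moderation, no fold-change shrinkage — because
the downstream pipeline is defined entirely by the thresholds applied to
``log2FC`` and the BH-adjusted p-value.

A gene is a DEG at a stage when ``|log2FC| >= lfc_threshold`` (default
0.585, i.e. a 1.5-fold difference) and BH-adjusted p < alpha (default
0.05), with BH applied within each stage contrast.  A gene is a pooled DEG
when it is a DEG in at least one (non-excluded) stage contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

LN2 = math.log(2.0)

#: Valid readings of the low-count filter rule.
FILTER_RULES = ("both_species_all", "either_species_all", "mean")


@dataclass
class CountMatrix:
    """Gene-level counts (genes x samples) with sample metadata.

    ``counts`` is indexed by gene id with one column per sample id;
    ``meta`` is indexed by sample id with columns ``species, stage,
    replicate``.  (species, stage, replicate) must be unique per sample.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            self.meta = self.meta.loc[self.counts.columns]
        required = {"species", "stage", "replicate"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        key = self.meta[["species", "stage", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(species, stage, replicate) must be unique")
        species = self.meta["species"].unique()
        if len(species) != 2:
            raise ValueError(f"expected exactly 2 species, got {list(species)}")

    @property
    def species(self) -> list[str]:
        return list(self.meta["species"].unique())

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.meta["stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_of(self, species: str, stage: str) -> list[str]:
        m = self.meta
        return list(m.index[(m["species"] == species) & (m["stage"] == stage)])


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    The reference for each gene is the geometric mean of its counts across
    samples; a sample's factor is the median ratio over genes with strictly
    positive counts in all samples.  With ``pseudo_reference=True`` the
    geometric mean is taken over positive entries only, rescuing datasets
    without any all-positive gene.
    """
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    if pseudo_reference:
        finite = np.isfinite(logx)
        usable = finite.any(axis=1)
        ref = np.full(x.shape[0], np.nan)
        ref[usable] = np.exp([logx[i, finite[i]].mean()
                              for i in np.flatnonzero(usable)])
        ratios = np.where(finite, x / ref[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        all_pos = np.isfinite(logx).all(axis=1)
        if not all_pos.any():
            raise ValueError(
                "no gene has positive counts in every sample; re-run with "
                "pseudo_reference=True (geometric mean over positive entries)")
        ref = np.exp(logx[all_pos].mean(axis=1))
        factors = np.median(x[all_pos] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(cm: CountMatrix, pseudo_reference: bool = False) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    s = size_factors(cm.counts, pseudo_reference=pseudo_reference)
    return cm.counts / s


def low_count_filter(cm: CountMatrix, min_count: int = 10,
                     rule: str = "both_species_all") -> CountMatrix:
    """Remove genes whose counts are uniformly low in both species.

    Rules (a gene is REMOVED when the condition holds):

    * ``both_species_all`` (default): every sample of species A has count
      < ``min_count`` AND every sample of species B does — the most
      permissive retention rule;
    * ``either_species_all``: all samples below threshold in at least one
      species;
    * ``mean``: the per-sample mean count is below threshold in each
      species.
    """
    if rule not in FILTER_RULES:
        raise ValueError(f"rule must be one of {FILTER_RULES}")
    sp_a, sp_b = cm.species
    cols_a = cm.meta.index[cm.meta["species"] == sp_a]
    cols_b = cm.meta.index[cm.meta["species"] == sp_b]
    a = cm.counts[cols_a]
    b = cm.counts[cols_b]
    if rule == "both_species_all":
        low = (a < min_count).all(axis=1) & (b < min_count).all(axis=1)
    elif rule == "either_species_all":
        low = (a < min_count).all(axis=1) | (b < min_count).all(axis=1)
    else:
        low = (a.mean(axis=1) < min_count) & (b.mean(axis=1) < min_count)
    kept = cm.counts[~low]
    if kept.empty:
        raise ValueError("low-count filter removed every gene")
    return CountMatrix(kept, cm.meta)


def collapse_technical_replicates(counts: pd.DataFrame,
                                  meta: pd.DataFrame) -> CountMatrix:
    """Sum counts of samples sharing (species, stage, replicate).

    Operates on raw frames (technical replicates violate the uniqueness
    invariant of :class:`CountMatrix`) and returns a valid matrix.
    """
    meta = meta.loc[counts.columns]
    key = (meta["species"].astype(str) + "|" + meta["stage"].astype(str)
           + "|" + meta["replicate"].astype(str))
    collapsed = counts.T.groupby(key.to_numpy()).sum().T
    rows = []
    for k in collapsed.columns:
        sp, st, rep = k.split("|")
        rows.append((k, sp, st, rep))
    meta = pd.DataFrame(rows, columns=["sample_id", "species", "stage",
                                       "replicate"]).set_index("sample_id")
    return CountMatrix(collapsed, meta)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def de_test(norm_counts: pd.DataFrame, samples_a: list[str],
            samples_b: list[str], stage: str, *, pseudo: float = 1.0,
            lfc_threshold: float = 0.585, alpha: float = 0.05,
            dispersion_mode: str = "pooled_floor") -> pd.DataFrame:
    """NB Wald test of species B over species A at one matched stage.

    Operates on *normalized* counts.  Returns a table with columns
    ``gene_id, stage, log2fc, se, wald_z, p, padj, is_deg``.

    ``dispersion_mode`` controls the floor under the per-gene moment
    dispersion: ``pooled_floor`` (default) floors at the median of the
    positive gene-wise estimates — at two or three replicates the per-gene
    moment estimate is noisy enough that chance under-dispersion inflates
    the Wald statistic, and the data-driven floor restores error control —
    while ``moments`` floors at 1e-8 (pure per-gene estimates).

    Raises when either group has fewer than two replicates (no dispersion
    estimate is possible).
    """
    if dispersion_mode not in ("pooled_floor", "moments"):
        raise ValueError("dispersion_mode must be 'pooled_floor' or 'moments'")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"stage {stage!r}: each group needs >= 2 replicates "
            f"(got {len(samples_a)}, {len(samples_b)})")
    a = norm_counts[samples_a].to_numpy(dtype=float)
    b = norm_counts[samples_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    v_a, v_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(m_a > 0, (v_a - m_a) / m_a**2, 0.0)
        alpha_b = np.where(m_b > 0, (v_b - m_b) / m_b**2, 0.0)
    disp = np.maximum(alpha_a, alpha_b)
    floor = 1e-8
    if dispersion_mode == "pooled_floor" and (disp > 0).any():
        floor = max(float(np.median(disp[disp > 0])), 1e-8)
    disp = np.maximum(disp, floor)

    log2fc = np.log2((m_b + pseudo) / (m_a + pseudo))
    var_ma = (m_a + disp * m_a**2) / na
    var_mb = (m_b + disp * m_b**2) / nb
    se = np.sqrt(var_ma / (m_a + pseudo)**2 + var_mb / (m_b + pseudo)**2) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    padj = bh_adjust(p)
    is_deg = (np.abs(log2fc) >= lfc_threshold) & (padj < alpha)
    return pd.DataFrame({
        "gene_id": norm_counts.index,
        "stage": stage,
        "log2fc": log2fc,
        "se": se,
        "wald_z": z,
        "p": p,
        "padj": padj,
        "is_deg": is_deg,
    }).reset_index(drop=True)


def run_stage_contrasts(cm: CountMatrix, *, pseudo: float = 1.0,
                        lfc_threshold: float = 0.585, alpha: float = 0.05,
                        stage_exclusions: list[str] | None = None,
                        stage_matching: dict[str, str] | None = None,
                        pseudo_reference: bool = False,
                        dispersion_mode: str = "pooled_floor") -> pd.DataFrame:
    """All stage-matched contrasts of species B over species A.

    ``stage_matching`` maps species-A stage labels to species-B stage
    labels (identity by default); stages in ``stage_exclusions`` never
    enter a contrast.  Returns the concatenation of per-stage
    :func:`de_test` tables.
    """
    stage_exclusions = list(stage_exclusions or [])
    norm = normalize(cm, pseudo_reference=pseudo_reference)
    sp_a, sp_b = cm.species
    results = []
    for stage_a in cm.stages:
        if stage_a in stage_exclusions:
            continue
        stage_b = (stage_matching or {}).get(stage_a, stage_a)
        if stage_b in stage_exclusions:
            continue
        cols_a = cm.samples_of(sp_a, stage_a)
        cols_b = cm.samples_of(sp_b, stage_b)
        if not cols_a or not cols_b:
            continue
        results.append(de_test(norm, cols_a, cols_b, stage_a, pseudo=pseudo,
                               lfc_threshold=lfc_threshold, alpha=alpha,
                               dispersion_mode=dispersion_mode))
    if not results:
        raise ValueError("no stage contrast could be formed")
    return pd.concat(results, ignore_index=True)


def pool_degs(results: pd.DataFrame,
              stage_exclusions: list[str] | None = None) -> pd.DataFrame:
    """Per-gene pooled DEG call: significant in >= 1 retained stage contrast.

    Returns a gene x stage boolean table with a final ``pooled`` column.
    """
    stage_exclusions = set(stage_exclusions or [])
    kept = results[~results["stage"].isin(stage_exclusions)]
    flags = kept.pivot_table(index="gene_id", columns="stage",
                             values="is_deg", aggfunc="any", fill_value=False)
    flags = flags.astype(bool)
    flags["pooled"] = flags.any(axis=1)
    return flags
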