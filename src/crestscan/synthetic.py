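"""Synthetic haplotype panels, count matrices and gene annotations.

The generators emulate the statistical structure the pipeline assumes —
not any particular genome.  All are deterministic given their integer seed;
child random streams are derived from it via ``numpy.random.SeedSequence``.

Haplotype model (founder mosaic)
--------------------------------
1. Site positions are drawn uniformly without replacement from
   ``[1, chrom_length_bp]`` and sorted (strictly increasing).
2. ``n_founders`` founder haplotypes are drawn with a per-site allele-1
   probability from a symmetric Beta(0.5, 0.5) — a U-shaped site-frequency
   spectrum.
3. Each sample haplotype is a founder mosaic: it starts from a uniformly
   random founder and, between consecutive sites separated by ``gap_bp``,
   switches to a uniformly random founder with probability
   ``1 - exp(-switch_rate_per_bp * gap_bp)``.
4. Every allele is flipped independently with ``mutation_rate_per_site``.
5. If a sweep is configured, one founder is designated "swept" and the
   allele at the site nearest ``sweep_pos_bp`` is forced to 1 on it; a
   ``sweep_fraction`` of the ``sweep_pop`` haplotypes copy the swept
   founder with the switch probability multiplied by 0 inside
   ``+/- sweep_halfwidth_bp`` of the sweep position (identity-by-descent
   copying, a star-like sweep), and carry the core allele.

This produces background linkage disequilibrium decaying with distance and,
under a sweep, a long shared haplotype in one population — the footprint
the EHH statistics detect.  It is not a coalescent or fitness model.

Count model
-----------
``mu(g, species, stage) = baseline_g * pattern_{cluster(g)}(species, stage)
* 2^(+/- deg_log2fc for DEG genes, applied to species B) * libsize_j``;
counts are negative binomial with variance ``mu + alpha * mu^2``
(``alpha = 0`` degenerates to Poisson).  Baselines are log-normal; library
size factors log-normal; the DEG sign is random per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import CountMatrix
from .io import GenomeAnnotation, HaplotypePanel


class ConfigurationError(ValueError):
    """A simulator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Haplotype simulation
# ---------------------------------------------------------------------------

@dataclass
class HapSimConfig:
    """Two-population founder-mosaic haplotype simulation parameters.

    Defaults give a desk-scale neutral panel: 50 haplotypes per population
    over 2000 SNPs on a 2 Mb chromosome, with LD decaying over tens of kb.
    """

    n_hap_per_pop: int = 50
    n_sites: int = 2000
    chrom_length_bp: int = 2_000_000
    n_founders: int = 20
    switch_rate_per_bp: float = 1e-4
    mutation_rate_per_site: float = 0.005
    founder_beta: float = 0.5
    sweep_pos_bp: int | None = None
    sweep_pop: str = "A"
    sweep_fraction: float = 0.9
    sweep_halfwidth_bp: int = 150_000
    seed: int = 0
    chrom: str = "chr1"
    pop_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_hap_per_pop < 1 or self.n_sites < 1 or self.chrom_length_bp < 1:
            raise ConfigurationError("panel dimensions must be positive")
        if self.n_sites > self.chrom_length_bp:
            raise ConfigurationError("n_sites cannot exceed chrom_length_bp")
        if self.n_founders < 1:
            raise ConfigurationError("n_founders must be >= 1")
        if self.switch_rate_per_bp < 0:
            raise ConfigurationError("switch_rate_per_bp must be >= 0")
        if not (0.0 <= self.mutation_rate_per_site <= 1.0):
            raise ConfigurationError("mutation_rate_per_site must be in [0,1]")
        if not (0.0 <= self.sweep_fraction <= 1.0):
            raise ConfigurationError("sweep_fraction must be in [0,1]")
        if self.sweep_pos_bp is not None and not (
                1 <= self.sweep_pos_bp <= self.chrom_length_bp):
            raise ConfigurationError(
                "sweep_pos_bp must lie in [1, chrom_length_bp]")
        if self.sweep_pop not in self.pop_labels:
            raise ConfigurationError("sweep_pop must be one of pop_labels")


def strong_sweep_config(seed: int = 0, **overrides) -> HapSimConfig:
    """The strong-sweep preset: a 90%-frequency swept core in population A
    with suppressed founder switching over +/- 150 kb at mid-chromosome.

    The chromosome is 8 Mb so the swept window is < 4% of scanned sites:
    genome-wide standardization assumes sweeps are rare, and a sweep
    occupying a large fraction of a short chromosome inflates the scale of
    its own null distribution.
    """
    cfg = HapSimConfig(n_sites=4000, chrom_length_bp=8_000_000,
                       sweep_pos_bp=4_000_000, sweep_pop="A",
                       sweep_fraction=0.9, sweep_halfwidth_bp=150_000,
                       seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SyntheticTruth:
    """Declared ground truth of a synthetic dataset."""

    true_deg_ids: set[str] = field(default_factory=set)
    true_cluster_of_gene: dict[str, int] = field(default_factory=dict)
    sweep_pos_bp: int | None = None
    sweep_pop: str | None = None
    sweep_core_site_pos: int | None = None
    planted_selected_genes: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "true_deg_ids": sorted(self.true_deg_ids),
            "true_cluster_of_gene": self.true_cluster_of_gene,
            "sweep_pos_bp": self.sweep_pos_bp,
            "sweep_pop": self.sweep_pop,
            "sweep_core_site_pos": self.sweep_core_site_pos,
            "planted_selected_genes": sorted(self.planted_selected_genes),
        }


def _mosaic(rng: np.random.Generator, n_hap: int, positions: np.ndarray,
            n_founders: int, switch_rate: float) -> np.ndarray:
    """Founder index per (haplotype, site) under the switching process."""
    n_sites = positions.size
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    founder = np.empty((n_hap, n_sites), dtype=np.int32)
    founder[:, 0] = rng.integers(0, n_founders, size=n_hap)
    switch = rng.random((n_hap, n_sites - 1)) < p_switch[None, :]
    targets = rng.integers(0, n_founders, size=(n_hap, n_sites - 1))
    for j in range(1, n_sites):
        founder[:, j] = np.where(switch[:, j - 1], targets[:, j - 1],
                                 founder[:, j - 1])
    return founder


def simulate_haplotypes(cfg: HapSimConfig) -> tuple[HaplotypePanel, SyntheticTruth]:
    """Simulate a two-population phased haplotype panel.

    See the module docstring for the generative model.  Returns the panel
    and a :class:`SyntheticTruth` recording the sweep (if any).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_sites, rng_founders, rng_mosaic, rng_mut, rng_sweep = (
        np.random.default_rng(s) for s in ss.spawn(5))

    positions = np.sort(rng_sites.choice(
        np.arange(1, cfg.chrom_length_bp + 1), size=cfg.n_sites,
        replace=False))
    p1 = rng_founders.beta(cfg.founder_beta, cfg.founder_beta,
                           size=cfg.n_sites)
    founders = (rng_founders.random((cfg.n_founders, cfg.n_sites))
                < p1[None, :]).astype(np.uint8)

    n_hap = 2 * cfg.n_hap_per_pop
    founder_idx = _mosaic(rng_mosaic, n_hap, positions, cfg.n_founders,
                          cfg.switch_rate_per_bp)

    core_j = None
    carriers = np.zeros(n_hap, dtype=bool)
    if cfg.sweep_pos_bp is not None:
        core_j = int(np.argmin(np.abs(positions - cfg.sweep_pos_bp)))
        swept_founder = 0
        founders[swept_founder, core_j] = 1
        in_window = np.abs(positions - cfg.sweep_pos_bp) <= cfg.sweep_halfwidth_bp
        pop_offset = 0 if cfg.sweep_pop == cfg.pop_labels[0] else cfg.n_hap_per_pop
        n_carriers = int(round(cfg.sweep_fraction * cfg.n_hap_per_pop))
        chosen = rng_sweep.choice(cfg.n_hap_per_pop, size=n_carriers,
                                  replace=False) + pop_offset
        carriers[chosen] = True
        # IBD copying: switch probability x0 inside the window, i.e. the
        # carrier's founder is pinned to the swept founder there
        founder_idx[np.ix_(carriers, np.flatnonzero(in_window))] = swept_founder

    alleles = founders[founder_idx, np.arange(cfg.n_sites)[None, :]]
    if cfg.mutation_rate_per_site > 0:
        flips = rng_mut.random(alleles.shape) < cfg.mutation_rate_per_site
        alleles = alleles ^ flips.astype(np.uint8)
    if core_j is not None:
        alleles[carriers, core_j] = 1  # carriers keep the core allele

    pop_a, pop_b = cfg.pop_labels
    pop_of_hap = np.array([pop_a] * cfg.n_hap_per_pop
                          + [pop_b] * cfg.n_hap_per_pop)
    # two haplotype rows per diploid sample, within each population
    sample_of_hap = np.array(
        [f"{pop_a}{i // 2:03d}" for i in range(cfg.n_hap_per_pop)]
        + [f"{pop_b}{i // 2:03d}" for i in range(cfg.n_hap_per_pop)])
    panel = HaplotypePanel(cfg.chrom, positions, alleles, pop_of_hap,
                           sample_of_hap)
    truth = SyntheticTruth(
        sweep_pos_bp=cfg.sweep_pos_bp, sweep_pop=cfg.sweep_pop
        if cfg.sweep_pos_bp is not None else None,
        sweep_core_site_pos=int(positions[core_j]) if core_j is not None else None)
    return panel, truth


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

DEFAULT_STAGES = ("14ss", "19ss", "24ss", "30ss", "35ss")


def default_pattern_bank(stages: Sequence[str],
                         species: Sequence[str]) -> np.ndarray:
    """Seven distinct positive trajectory shapes over species x stage.

    Shapes (per species s in {A, B}, stage fraction t in [0, 1]): rising,
    falling, mid-peak, mid-trough, rising in A only, rising in B only,
    opposed (falling in A, rising in B).  Returned as a
    ``(7, n_species * n_stages)`` array, species-major.
    """
    t = (np.linspace(0.0, 1.0, len(stages)) if len(stages) > 1
         else np.array([0.5]))
    rising, falling = 1.0 + 3.0 * t, 4.0 - 3.0 * t
    peak = 1.0 + 3.0 * np.exp(-((t - 0.5) ** 2) / 0.045)
    trough = 4.0 - 3.0 * np.exp(-((t - 0.5) ** 2) / 0.045)
    flat = np.full_like(t, 2.0)
    shapes = [
        (rising, rising), (falling, falling), (peak, peak), (trough, trough),
        (rising, flat), (flat, rising), (falling, rising),
    ]
    return np.array([np.concatenate([a, b]) for a, b in shapes])


def shared_pattern_bank(stages: Sequence[str],
                        species: Sequence[str] = ("A", "B")) -> np.ndarray:
    """Seven trajectory shapes identical between the two species.

    With this bank the planted DEG multipliers are the *only* species
    difference, so the DEG truth set is exactly the set of genes that are
    differentially expressed — the substrate for sensitivity/FDR checks of
    the DE module.
    """
    t = (np.linspace(0.0, 1.0, len(stages)) if len(stages) > 1
         else np.array([0.5]))
    shapes = [
        1.0 + 3.0 * t,
        4.0 - 3.0 * t,
        1.0 + 3.0 * np.exp(-((t - 0.5) ** 2) / 0.045),
        4.0 - 3.0 * np.exp(-((t - 0.5) ** 2) / 0.045),
        1.0 + 3.0 * np.exp(-((t - 0.15) ** 2) / 0.02),
        1.0 + 3.0 * np.exp(-((t - 0.85) ** 2) / 0.02),
        1.0 + 3.0 * t ** 3,
    ]
    return np.array([np.concatenate([s, s]) for s in shapes])


@dataclass
class CountSimConfig:
    """Negative-binomial developmental count-matrix parameters.

    Defaults emulate a two-species somite-stage series with three
    biological replicates per (species, stage) cell.
    """

    n_genes: int = 2000
    stages: tuple[str, ...] = DEFAULT_STAGES
    species: tuple[str, str] = ("A", "B")
    n_reps: int = 3
    n_clusters_true: int = 7
    pattern_bank: np.ndarray | None = None
    baseline_logmean: float = np.log(300.0)
    baseline_logmean_sd: float = 1.0
    nb_dispersion: float = 0.05
    libsize_factor_sd: float = 0.15
    frac_deg: float = 0.2
    deg_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps < 1:
            raise ConfigurationError("n_genes and n_reps must be positive")
        if len(self.stages) == 0:
            raise ConfigurationError("stages must be non-empty")
        if len(self.species) != 2:
            raise ConfigurationError("exactly two species labels required")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if not (0.0 <= self.frac_deg <= 1.0):
            raise ConfigurationError("frac_deg must be in [0,1]")
        if self.pattern_bank is None:
            self.pattern_bank = default_pattern_bank(self.stages, self.species)
        self.pattern_bank = np.asarray(self.pattern_bank, dtype=float)
        if self.pattern_bank.shape != (self.n_clusters_true,
                                       2 * len(self.stages)):
            raise ConfigurationError(
                "pattern_bank must be (n_clusters_true, 2 * n_stages)")
        if (self.pattern_bank <= 0).any():
            raise ConfigurationError("pattern values must be > 0")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(cfg: CountSimConfig,
                    cluster_override: Mapping[str, int] | None = None,
                    deg_override: Sequence[str] | None = None,
                    deg_override_sign: float | None = None
                    ) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a stage-series count matrix with planted clusters and DEGs.

    ``cluster_override`` optionally pins named genes (``gene0001`` style
    ids) to a true cluster; ``deg_override`` forces named genes into the
    DEG truth set.  Both support coordinated end-to-end simulations where
    genes near a simulated sweep must land in one expression cluster.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_assign, rng_base, rng_lib, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4))

    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]
    cluster = rng_assign.integers(1, cfg.n_clusters_true + 1,
                                  size=cfg.n_genes)
    if cluster_override:
        idx = {g: i for i, g in enumerate(gene_ids)}
        for g, cl in cluster_override.items():
            if g not in idx:
                raise ConfigurationError(f"cluster_override gene {g!r} "
                                         "not in the simulated gene set")
            if not (1 <= cl <= cfg.n_clusters_true):
                raise ConfigurationError("cluster_override labels must lie "
                                         "in 1..n_clusters_true")
            cluster[idx[g]] = cl
    baseline = np.exp(rng_base.normal(cfg.baseline_logmean,
                                      cfg.baseline_logmean_sd, cfg.n_genes))
    n_deg = int(round(cfg.frac_deg * cfg.n_genes))
    deg_idx = rng_assign.choice(cfg.n_genes, size=n_deg, replace=False)
    forced: list[int] = []
    if deg_override:
        idx = {g: i for i, g in enumerate(gene_ids)}
        forced = [idx[g] for g in deg_override]
        deg_idx = np.unique(np.concatenate([deg_idx, forced])).astype(int)
    deg_sign = rng_assign.choice([-1.0, 1.0], size=deg_idx.size)
    if forced and deg_override_sign is not None:
        deg_sign[np.isin(deg_idx, forced)] = deg_override_sign
    deg_mult = np.ones(cfg.n_genes)
    deg_mult[deg_idx] = 2.0 ** (deg_sign * cfg.deg_log2fc)

    sp_a, sp_b = cfg.species
    sample_rows = []
    for s_i, sp in enumerate(cfg.species):
        for st in cfg.stages:
            for r in range(1, cfg.n_reps + 1):
                sample_rows.append((f"{sp}_{st}_r{r}", sp, st, r))
    meta = pd.DataFrame(sample_rows, columns=["sample_id", "species",
                                              "stage", "replicate"]
                        ).set_index("sample_id")
    libsize = np.exp(rng_lib.normal(0.0, cfg.libsize_factor_sd, len(meta)))

    n_stage = len(cfg.stages)
    counts = np.empty((cfg.n_genes, len(meta)), dtype=np.int64)
    for j, (sid, row) in enumerate(meta.iterrows()):
        s_i = 0 if row["species"] == sp_a else 1
        st_i = cfg.stages.index(row["stage"])
        pat = cfg.pattern_bank[cluster - 1, s_i * n_stage + st_i]
        mu = baseline * pat * libsize[j]
        if s_i == 1:
            mu = mu * deg_mult
        counts[:, j] = _nb_draw(rng_counts, mu, cfg.nb_dispersion)
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids,
                                  columns=meta.index), meta)
    truth = SyntheticTruth(
        true_deg_ids={gene_ids[i] for i in deg_idx},
        true_cluster_of_gene={g: int(c) for g, c in zip(gene_ids, cluster)})
    return cm, truth


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------

def simulate_annotation(n_genes: int, chrom_length_bp: int, seed: int = 0,
                        chrom: str = "chr1",
                        length_logmean: float = np.log(8000.0),
                        length_logsd: float = 0.6) -> GenomeAnnotation:
    """Non-overlapping gene models with log-normal lengths.

    Lengths are log-normal (default median 8 kb, log-sd 0.6, floor 200 bp);
    the leftover chromosome space is split uniformly into inter-gene gaps,
    so placement is uniform subject to pairwise disjointness and gene
    order.  Gene ids (``gene0001``...) match those of
    :func:`simulate_counts` when the gene counts agree.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA110]))
    lengths = np.maximum(
        200, rng.lognormal(length_logmean, length_logsd, n_genes).astype(int))
    total = int(lengths.sum())
    free = chrom_length_bp - total - (n_genes - 1)  # >= 1 bp between genes
    if free < 0:
        raise ConfigurationError(
            f"cannot place {n_genes} disjoint genes totalling {total} bp on "
            f"a {chrom_length_bp} bp chromosome; use a longer chromosome")
    # split the free space: n_genes sorted draws partition it into gaps
    cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
    starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1] + 1))) + 1
    ends = starts + lengths - 1
    strands = rng.choice(["+", "-"], size=n_genes)
    df = pd.DataFrame({
        "gene_id": [f"gene{i + 1:04d}" for i in range(n_genes)],
        "chrom": chrom,
        "start": starts.astype(int),
        "end": ends.astype(int),
        "strand": strands,
    })
    return GenomeAnnotation(df)


def genes_near_sweep(annotation: GenomeAnnotation, sweep_pos_bp: int,
                     sweep_halfwidth_bp: int) -> set[str]:
    """Gene ids whose body lies within the sweep window (planted targets)."""
    g = annotation.genes
    mid = (g["start"] + g["end"]) / 2
    hit = np.abs(mid - sweep_pos_bp) <= sweep_halfwidth_bp
    return set(g.loc[hit, "gene_id"])
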