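# Methods

This note documents the models, conventions and design choices behind
`crestscan`, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Haplotype model

The synthetic haplotype panels are founder mosaics, not coalescent or
forward simulations. For each panel:

1. site positions are drawn uniformly without replacement from
   `[1, chrom_length_bp]` and sorted;
2. `n_founders` founder haplotypes get allele 1 at each site with
   probability drawn from Beta(0.5, 0.5) — a U-shaped site-frequency
   spectrum resembling real panels;
3. each sample haplotype starts from a uniformly random founder and, over
   each inter-site gap of `g` bp, switches to a uniformly random founder
   with probability `1 − exp(−switch_rate_per_bp · g)`;
4. every allele is flipped independently with `mutation_rate_per_site`;
5. under a sweep, one founder is designated swept and carries allele 1 at
   the site nearest `sweep_pos_bp`; a `sweep_fraction` of one population's
   haplotypes have their founder pinned to the swept founder inside
   `± sweep_halfwidth_bp` (switch probability × 0 there), and always carry
   the core allele.

Both populations share the founder pool, which yields correlated allele
frequencies and background linkage disequilibrium decaying on the scale of
`1 / switch_rate_per_bp` — the two properties the EHH statistics actually
consume. The sweep is identity-by-descent copying (a star-like sweep), not
a fitness model: only the long-shared-haplotype footprint matters to the
statistics under test. Mutation is applied to carriers too, so EHH decays
gradually (not degenerately 1) across the swept window.

Defaults: 50 haplotypes per population (close to the 43–90 haplotypes of
typical wild-caught resequencing panels at desk scale), 2000 sites on 2 Mb
(1 SNP/kb), 20 founders, `switch_rate_per_bp = 1e−4` (LD decay over tens
of kb), `mutation_rate_per_site = 0.005`. The strong-sweep preset uses an
8 Mb chromosome with 4000 sites and a ±150 kb sweep at 90 % carrier
frequency: the swept window is then < 4 % of scanned sites, respecting the
genome-wide standardization assumption that sweeps are rare — on a short
chromosome where the sweep is a large fraction of all sites, the sweep
inflates the scale of its own null distribution and suppresses its z-scores.

What the generator does *not* emulate: demography (bottlenecks, migration,
admixture), recombination-rate variation, allele ages or ancestral states,
genotyping error and phasing switch errors. Passing calibration on these
panels shows the statistics behave correctly under clean haplotype
structure; it does not certify behaviour under demographic confounding.

## Selection scan

EHH is computed by partition refinement over carrier haplotypes; the
reported sequence includes the first site below the truncation threshold,
which also serves as the final trapezoid endpoint of the iES integral
(both sides summed; a core without flanking sites has iES 0). Truncation
defaults to EHH < 0.05; integration can also be aborted at inter-site gaps
larger than `max_gap_bp` (off by default — the simulated panels have no
assembly gaps). Distances are physical bp; no genetic-map weighting.

The core allele is fixed to allele 1. Sites where either population has
fewer than two carriers, or where an iES is zero, are skipped and written
to a skip-log so site totals are auditable. `xpEHH = ln(iES_A / iES_B)`,
positive when haplotypes are longer in population A.

Standardization converts raw values to z-scores. Default: within 20
equal-width bins of pooled allele-1 frequency (bins with fewer than 10
sites fall back to the global moments), with the moments computed after
discarding values more than 4 robust standard deviations (1.4826 × MAD)
from the median. Both choices are calibration-driven and exposed in
`ScanConfig`:

* the sampling variance of the log iES ratio grows sharply when one
  population has few core-allele carriers, so a single global distribution
  is heavy-tailed and plain-normal p-values are anticonservative —
  frequency binning (also the dominant convention for this statistic)
  restores the nominal error rate;
* without outlier clipping a strong sweep inflates the standard deviation
  of the bins it occupies, biasing the location of the maximum |z| toward
  the sweep shoulder.

Plain global standardization (`standardize="global"`, `clip_k=None`) is
exactly `(raw − mean)/sd` and is the mode on which the mean-0/sd-1
identity is asserted in tests. Two-sided p-values use the normal log
survival function (no underflow at extreme z); `−log10 p ≥ 3` flags
significance. Whether the underlying threshold refers to a one- or
two-sided p is ambiguous in the field's reporting; two-sided is
implemented.

## Islands and gene linkage

"Significant sites within 50 kb are grouped" is read as pad-each-SNP-by-
50 kb and merge overlapping or touching windows (slop + merge semantics):
consecutive significant SNPs join one island iff their distance is
≤ 2·`slop_bp`. The stricter gap ≤ 50 kb reading is available by halving
`slop_bp`. Island coordinates are member-SNP min/max, so singleton islands
span exactly 1 bp — consistent with reported island-size minima of 1 bp.

Linking precedence per island: any overlapping gene body (distance 0);
otherwise any overlapping promoter, a `promoter_bp = 5000` window
immediately upstream of the strand-aware TSS (promoter length is a
convention, not a reconstruction — it is rarely stated in analyses of this
kind); otherwise the single nearest gene within `link_max_dist_bp =
200000`, with exact ties linking all tied genes. Unlinked islands are
reported, never dropped silently.

## Differential expression

Size factors are median-of-ratios: per sample, the median over genes with
positive counts in all samples of `count / geometric-mean count`. The
median is taken over the ratios in linear space (with an even number of
reference genes this differs from exponentiating the median log-ratio). A
`pseudo_reference` mode (geometric mean over positive entries only)
rescues matrices with no all-positive gene.

The low-count filter removes a gene only when every sample in species A
*and* every sample in species B is below `min_count = 10` — the most
permissive of the defensible readings of "counts < 10 per sample in each
species"; the two stricter readings are selectable via `filter_rule`.

The per-stage test is deliberately transparent rather than a reimplementation
of a shrinkage NB GLM: group means on normalized counts, `log2FC` with
pseudo-count 1.0, per-gene moment dispersion `α = max over groups of
(var − mean)/mean²`, Wald z from the delta-method standard error with
`var(mean) = (m + α m²)/n`, BH adjustment within the stage contrast
(delegated to statsmodels), and the |log2FC| ≥ 0.585 / padj < 0.05 DEG
rule. With two or three replicates the raw moment estimate is noisy enough
that chance under-dispersion inflates z and breaks FDR control (measured
≈ 19 % at nominal 5–10 % in the calibration setting); the default
`dispersion_mode="pooled_floor"` therefore floors each gene's dispersion
at the median of the positive gene-wise estimates, restoring measured FDR
to ≈ 5 % with no sensitivity loss. Pure per-gene moments (floor 1e−8)
remain selectable. This scheme differs by design from empirical-Bayes
tools; the thresholds, not the estimator internals, define the downstream
pipeline.

Technical replicates sharing (species, stage, replicate-group) can be
collapsed by summation before analysis. Stage matching between species is
an explicit table in the pipeline configuration (with an exclusion list
for stages lacking an equivalent in the other species), not an inference.

## Clustering

Profiles are per-gene means of normalized counts per (species, stage)
cell, species-major, Z-scored per gene with the n−1 standard deviation;
constant profiles are excluded and reported. Clustering is complete
linkage on Euclidean distance of Z-scores (correlation distance
selectable; the metric is a convention — only the linkage method is
standard in this analysis style), cut into exactly K = 7 flat clusters.
Equal-distance merge ties are resolved by scipy's linkage ordering; ties
have measure zero on continuous profiles. Labels are renumbered 1..K by
first gene appearance so assignments are deterministic given input order.
A thin sample-QC PCA (centered, scaled, SVD-based) is provided alongside.

## Permutation enrichment

Per gene: the median of `−log10 p` (or |z|) over scan SNPs in the
`upstream_window_bp = 25000` window upstream of the TSS, strand-aware,
clipped at the chromosome start; genes with empty windows are excluded and
reported. Per cluster: the median (or mean) of its genes' values, compared
with B = 1000 draws of the same number of genes, without replacement, from
the background of genes outside the cluster with defined statistics —
size-matched genic windows by construction, since every window has the
same length and is anchored at a gene TSS. `empirical p = (1 + #{null ≥
observed})/(B + 1)`, one-sided in the enrichment direction, never zero,
deterministic given the seed. The background excludes the tested cluster
to avoid self-contamination. The scalar median-of-medians observed
statistic is one reading of comparing "distributions"; a whole-distribution
rank-sum comparison is provided as a clearly non-default alternative.

## The planted end-to-end study

The pipeline's synthetic study couples the generators: genes whose bodies
lie within the sweep window become the "planted selected" module; they are
assigned their own true expression cluster with a species-divergent
zigzag/anti-zigzag trajectory (zigzag in species A, mirrored in B), making
them differentially expressed at every stage by shape and unlike any other
profile group, so that complete-linkage clustering isolates the module.
The demo study keeps `frac_deg = 0` so species differences come only from
divergent trajectory shapes and the number of natural profile groups stays
below K; with many planted fold-change groups a K = 7 cut is forced to
merge profile groups and dilutes the planted cluster. This is the
synthetic analogue of a co-regulated module under lineage-specific
selection with a divergent developmental trajectory.

## Validation problem sizes

The test suite and acceptance script use desk-scale sizes chosen to make
each property measurable in seconds to a couple of minutes: 200 random
panels (≤ 20 haplotypes, ≤ 50 sites) for exact EHH oracle equivalence;
20 seeds of 50+50 haplotypes × 2000 sites for neutral calibration (bound:
≤ 1 % of sites at −log10 p ≥ 3); 20 strong-sweep replicates for sweep
localization; 100 random instances against a quadratic merge oracle for
islands; 10 seeds of 2000 genes for DE sensitivity/FDR; 10 seeds of 350
genes for cluster recovery (ARI); 200 seeded runs for permutation-p
uniformity and 10 full pipeline runs for planted-cluster power.

## Known limitations

* No iHS/nSL, no ancestral-allele polarization, no genetic-map distances.
* The DE test has no covariates, batch terms or shrinkage; it is a
  calibrated screen, not a DESeq2 substitute.
* Enrichment treats genes as exchangeable units; gene length, SNP density
  and LD between neighbouring windows are not modelled beyond the
  size-matching of window counts.
* All simulators are single-chromosome; multi-chromosome input is handled
  in the scan/island/enrichment path but not generated synthetically.
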