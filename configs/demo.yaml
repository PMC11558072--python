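# Demo study: a strong selective sweep in population A at mid-chromosome,
# with genes near the sweep planted into expression cluster 1 as DEGs.
seed: 1

haplotypes:
  n_hap_per_pop: 40
  n_sites: 1600
  chrom_length_bp: 4000000
  n_founders: 20
  switch_rate_per_bp: 1.0e-4
  mutation_rate_per_site: 0.005
  sweep_pos_bp: 2000000
  sweep_pop: A
  sweep_fraction: 0.9
  sweep_halfwidth_bp: 100000

annotation:
  n_genes: 200

counts:
  stages: [14ss, 19ss, 24ss, 30ss]
  n_reps: 3
  n_clusters_true: 7
  nb_dispersion: 0.05
  libsize_factor_sd: 0.15
  frac_deg: 0.0
  deg_log2fc: 2.0

scan:
  maf_min: 0.05
  sig_neglogp: 3.0

islands:
  slop_bp: 50000
  promoter_bp: 5000
  link_max_dist_bp: 200000

de:
  min_count: 10
  filter_rule: both_species_all
  lfc_threshold: 0.585
  alpha: 0.05
  stage_exclusions: []

clustering:
  k: 7
  metric: euclidean
  method: complete

enrichment:
  upstream_window_bp: 25000
  n_perm: 500
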