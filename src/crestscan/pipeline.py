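"""End-to-end orchestration: simulate -> scan -> islands -> de -> cluster
-> enrich, driven by a single YAML configuration with one global seed.

Every stage writes its tabular outputs into the run directory; a manifest
records the fully resolved configuration, the derived per-stage seeds, the
SHA-256 checksum of every output file and per-stage row counts, so that two
runs with the same configuration and seed are byte-identical and the audit
trail (significant SNPs -> islands -> linked genes -> DEGs) is
reproducible on any dataset.  Outputs of a failed run are quarantined under
``failed/`` inside the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, de, enrichment, islands, io, scan, synthetic

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


#: Recognized configuration sections and keys (unknown keys are errors).
CONFIG_SCHEMA: dict[str, set[str]] = {
    "seed": set(),
    "haplotypes": {"n_hap_per_pop", "n_sites", "chrom_length_bp",
                   "n_founders", "switch_rate_per_bp",
                   "mutation_rate_per_site", "founder_beta", "sweep_pos_bp",
                   "sweep_pop", "sweep_fraction", "sweep_halfwidth_bp",
                   "chrom"},
    "annotation": {"n_genes", "length_logmean", "length_logsd"},
    "counts": {"n_genes", "stages", "n_reps", "n_clusters_true",
               "baseline_logmean", "baseline_logmean_sd", "nb_dispersion",
               "libsize_factor_sd", "frac_deg", "deg_log2fc"},
    "scan": {"maf_min", "ehh_truncation", "max_gap_bp", "sig_neglogp",
             "standardize", "n_freq_bins", "clip_k"},
    "islands": {"slop_bp", "promoter_bp", "link_max_dist_bp"},
    "de": {"min_count", "filter_rule", "lfc_threshold", "alpha", "pseudo",
           "stage_exclusions", "stage_matching"},
    "clustering": {"k", "metric", "method"},
    "enrichment": {"upstream_window_bp", "n_perm", "gene_stat",
                   "summary_stat"},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("configuration must be a YAML mapping")
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Check every key and invariant; return all errors at once."""
    errors: list[str] = []
    for section, value in cfg.items():
        if section not in CONFIG_SCHEMA:
            errors.append(f"unknown section {section!r}")
            continue
        if section == "seed":
            if not isinstance(value, int):
                errors.append("seed must be an integer")
            continue
        if not isinstance(value, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key in value:
            if key not in CONFIG_SCHEMA[section]:
                errors.append(f"unknown key {section}.{key}")
    # delegate invariant checks to the module configs
    def _try(build, label):
        try:
            build()
        except Exception as exc:  # aggregate, do not raise
            errors.append(f"{label}: {exc}")

    known = {k: {kk: vv for kk, vv in v.items()
                 if kk in CONFIG_SCHEMA.get(k, set())}
             for k, v in cfg.items() if isinstance(v, dict)}
    _try(lambda: synthetic.HapSimConfig(**known.get("haplotypes", {})),
         "haplotypes")
    counts_kw = dict(known.get("counts", {}))
    if "stages" in counts_kw:
        counts_kw["stages"] = tuple(counts_kw["stages"])
    _try(lambda: synthetic.CountSimConfig(**counts_kw), "counts")
    _try(lambda: scan.ScanConfig(**known.get("scan", {})), "scan")
    _try(lambda: enrichment.EnrichmentConfig(**known.get("enrichment", {})),
         "enrichment")
    de_cfg = known.get("de", {})
    if de_cfg.get("filter_rule") not in (None, *de.FILTER_RULES):
        errors.append(f"de.filter_rule must be one of {de.FILTER_RULES}")
    n_ann = known.get("annotation", {}).get("n_genes")
    n_cnt = known.get("counts", {}).get("n_genes")
    if n_ann is not None and n_cnt is not None and n_ann != n_cnt:
        errors.append("annotation.n_genes and counts.n_genes must agree so "
                      "gene ids map between expression and genome")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _child_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(cfg: dict, outdir: str | Path,
                 seed: int | None = None) -> Path:
    """Run every stage on a synthetic dataset; return the run directory."""
    errors = validate_config(cfg)
    if errors:
        raise PipelineError("invalid configuration: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}, "files": {}}

    stage = "simulate"
    try:
        hap_cfg = synthetic.HapSimConfig(**cfg.get("haplotypes", {}),
                                         seed=_child_seed(seed, "hap"))
        panel, hap_truth = synthetic.simulate_haplotypes(hap_cfg)
        ann_kw = dict(cfg.get("annotation", {}))
        n_genes = ann_kw.pop("n_genes", 150)
        annotation = synthetic.simulate_annotation(
            n_genes, hap_cfg.chrom_length_bp, seed=_child_seed(seed, "ann"),
            chrom=hap_cfg.chrom, **ann_kw)
        planted: set[str] = set()
        if hap_cfg.sweep_pos_bp is not None:
            planted = synthetic.genes_near_sweep(
                annotation, hap_cfg.sweep_pos_bp, hap_cfg.sweep_halfwidth_bp)
        counts_kw = dict(cfg.get("counts", {}))
        counts_kw.setdefault("n_genes", n_genes)
        if "stages" in counts_kw:
            counts_kw["stages"] = tuple(counts_kw["stages"])
        if planted and "pattern_bank" not in counts_kw:
            # the planted selected module gets a species-divergent zigzag
            # trajectory (zigzag in A, anti-zigzag in B): it is
            # differentially expressed at every stage by shape, and no
            # other pattern (nor a pattern plus a species offset)
            # resembles it, so expression clustering isolates the module
            stages_t = tuple(counts_kw.get("stages", synthetic.DEFAULT_STAGES))
            bank = synthetic.default_pattern_bank(stages_t, ("A", "B"))
            n_true = counts_kw.get("n_clusters_true", 7)
            bank = bank[:n_true]
            zig = np.where(np.arange(len(stages_t)) % 2 == 0, 1.0, 4.0)
            bank[0] = np.concatenate([zig, 5.0 - zig])
            counts_kw["pattern_bank"] = bank
            counts_kw.setdefault("stages", stages_t)
        cnt_cfg = synthetic.CountSimConfig(**counts_kw,
                                           seed=_child_seed(seed, "cnt"))
        # planted selected genes form their own true expression cluster
        # (cluster 1, coherent DEG direction); the rest rotate over 2..K
        gene_ids = [f"gene{i + 1:04d}" for i in range(cnt_cfg.n_genes)]
        override: dict[str, int] = {}
        if planted:
            nxt = 0
            for g in gene_ids:
                if g in planted:
                    override[g] = 1
                else:
                    override[g] = 2 + nxt % (cnt_cfg.n_clusters_true - 1)
                    nxt += 1
        cm, cnt_truth = synthetic.simulate_counts(
            cnt_cfg, cluster_override=override)
        truth = synthetic.SyntheticTruth(
            true_deg_ids=cnt_truth.true_deg_ids,
            true_cluster_of_gene=cnt_truth.true_cluster_of_gene,
            sweep_pos_bp=hap_truth.sweep_pos_bp,
            sweep_pop=hap_truth.sweep_pop,
            sweep_core_site_pos=hap_truth.sweep_core_site_pos,
            planted_selected_genes=planted)

        io.write_phased_vcf(panel, outdir / "panel.vcf")
        pops = pd.DataFrame({
            "sample_id": pd.unique(panel.sample_of_hap),
        })
        pop_map = {s: p for s, p in zip(panel.sample_of_hap,
                                        panel.pop_of_hap)}
        pops["population"] = pops["sample_id"].map(pop_map)
        pops.to_csv(outdir / "populations.tsv", sep="\t", index=False)
        io.write_gene_annotation(annotation, outdir / "genes.gff3", "gff3")
        io.write_gene_annotation(annotation, outdir / "genes.tsv", "tsv")
        io.write_counts_tsv(cm.counts, cm.meta, outdir / "counts.tsv",
                            outdir / "samples.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))
        manifest["stages"][stage] = {
            "seed_hap": hap_cfg.seed, "seed_ann": _child_seed(seed, "ann"),
            "seed_counts": cnt_cfg.seed, "n_sites": panel.n_sites,
            "n_haplotypes": panel.n_hap, "n_genes": n_genes,
            "n_planted_selected": len(planted)}

        stage = "scan"
        pop_assign = dict(zip(pops["sample_id"], pops["population"]))
        panel2 = io.read_phased_vcf(outdir / "panel.vcf", pop_assign)
        scan_cfg = scan.ScanConfig(**cfg.get("scan", {}))
        pop_a, pop_b = panel2.populations
        scan_df, skip_log = scan.scan_two_pop_panel(panel2, pop_a, pop_b,
                                                    scan_cfg)
        scan_df.to_csv(outdir / "scan.tsv", sep="\t", index=False)
        skip_log.to_csv(outdir / "scan_skipped.tsv", sep="\t", index=False)
        n_sig = int(scan_df["significant"].sum())
        manifest["stages"][stage] = {"n_scanned": len(scan_df),
                                     "n_skipped": len(skip_log),
                                     "n_significant": n_sig}

        stage = "islands"
        isl_kw = cfg.get("islands", {})
        isls = islands.call_islands(scan_df,
                                    slop_bp=isl_kw.get("slop_bp", 50_000))
        io.write_islands_bed(isls, outdir / "islands.bed")
        islands.islands_to_frame(isls).to_csv(outdir / "islands.tsv",
                                              sep="\t", index=False)
        links, unlinked = islands.link_genes(
            isls, annotation, promoter_bp=isl_kw.get("promoter_bp", 5_000),
            link_max_dist_bp=isl_kw.get("link_max_dist_bp", 200_000))
        links.to_csv(outdir / "island_gene_links.tsv", sep="\t", index=False)
        (outdir / "islands_unlinked.txt").write_text(
            "\n".join(unlinked) + ("\n" if unlinked else ""))
        manifest["stages"][stage] = {
            "n_islands": len(isls), "n_links": len(links),
            "n_linked_genes": int(links["gene_id"].nunique()),
            "n_unlinked_islands": len(unlinked)}

        stage = "de"
        de_kw = cfg.get("de", {})
        filtered = de.low_count_filter(cm, de_kw.get("min_count", 10),
                                       de_kw.get("filter_rule",
                                                 "both_species_all"))
        results = de.run_stage_contrasts(
            filtered, pseudo=de_kw.get("pseudo", 1.0),
            lfc_threshold=de_kw.get("lfc_threshold", 0.585),
            alpha=de_kw.get("alpha", 0.05),
            stage_exclusions=de_kw.get("stage_exclusions"),
            stage_matching=de_kw.get("stage_matching"))
        results.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        pooled = de.pool_degs(results, de_kw.get("stage_exclusions"))
        pooled.to_csv(outdir / "degs.tsv", sep="\t")
        deg_ids = list(pooled.index[pooled["pooled"]])
        manifest["stages"][stage] = {"n_genes_tested": len(filtered.counts),
                                     "n_contrasts": results["stage"].nunique(),
                                     "n_pooled_degs": len(deg_ids)}

        stage = "cluster"
        cl_kw = cfg.get("clustering", {})
        norm = de.normalize(filtered)
        profiles = clustering.stage_profiles(norm.loc[deg_ids], filtered.meta)
        scaled, excluded = clustering.zscore(profiles)
        assignment = clustering.hcluster_cut(
            scaled, k=cl_kw.get("k", 7), metric=cl_kw.get("metric",
                                                          "euclidean"),
            method=cl_kw.get("method", "complete"))
        assignment.labels.to_frame().to_csv(outdir / "clusters.tsv",
                                            sep="\t", index_label="gene_id")
        clustering.cluster_trajectories(assignment).to_csv(
            outdir / "cluster_trajectories.tsv", sep="\t", index=False)
        (outdir / "clustering_excluded.txt").write_text(
            "\n".join(excluded) + ("\n" if excluded else ""))
        manifest["stages"][stage] = {"n_clustered": len(scaled),
                                     "k": assignment.k,
                                     "n_excluded": len(excluded)}

        stage = "enrich"
        en_cfg = enrichment.EnrichmentConfig(
            **cfg.get("enrichment", {}), seed=_child_seed(seed, "enrich"))
        gene_stats = enrichment.compute_gene_stats(annotation, scan_df,
                                                   en_cfg)
        table = enrichment.enrich_all_clusters(assignment.labels, gene_stats,
                                               en_cfg)
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_clusters_tested": len(table),
            "n_genes_with_stat": int(gene_stats.notna().sum())}
    except Exception as exc:
        quarantine = outdir / "failed"
        quarantine.mkdir(exist_ok=True)
        for f in outdir.iterdir():
            if f.is_file():
                shutil.move(str(f), quarantine / f.name)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return outdir
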