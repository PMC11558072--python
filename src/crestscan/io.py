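"""Standard-format input/output and the core genomic containers.

All in-memory coordinates are 1-based inclusive.  The only exception is BED
output, which follows the BED convention of 0-based half-open intervals.
Gzip-compressed inputs are handled transparently on read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violated the expectations of its declared dialect."""


class EmptyPanelError(ValueError):
    """No usable sites were retained from a variant file."""


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased binary allele matrix over ordered sites.

    Parameters
    ----------
    chrom
        Chromosome name shared by all sites.
    positions
        Strictly increasing 1-based bp positions, one per site.
    alleles
        ``(n_haplotypes, n_sites)`` matrix with entries in ``{0, 1}``.
    pop_of_hap
        Population label per haplotype row.
    sample_of_hap
        Sample id per haplotype row (two rows per diploid sample).
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    pop_of_hap: np.ndarray
    sample_of_hap: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.pop_of_hap = np.asarray(self.pop_of_hap)
        self.sample_of_hap = np.asarray(self.sample_of_hap)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x sites) matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("number of sites in alleles and positions disagree")
        if self.alleles.shape[0] != self.pop_of_hap.size:
            raise ValueError("pop_of_hap length must equal number of haplotypes")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be binary")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.pop_of_hap:
            if p not in seen:
                seen.append(p)
        return seen

    def subset_pop(self, pop: str) -> "HaplotypePanel":
        """Panel restricted to haplotypes of one population."""
        mask = self.pop_of_hap == pop
        if not mask.any():
            raise ValueError(f"no haplotypes with population label {pop!r}")
        return HaplotypePanel(
            self.chrom,
            self.positions,
            self.alleles[mask],
            self.pop_of_hap[mask],
            self.sample_of_hap[mask],
        )

    def subset_sites(self, mask: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to a boolean or index selection of sites."""
        mask = np.asarray(mask)
        return HaplotypePanel(
            self.chrom,
            self.positions[mask],
            self.alleles[:, mask],
            self.pop_of_hap,
            self.sample_of_hap,
        )

    def allele1_freq(self) -> np.ndarray:
        """Per-site frequency of allele 1 across all haplotypes."""
        return self.alleles.mean(axis=0)


def read_phased_vcf(path: str | Path, pop_assignment: Mapping[str, str]) -> HaplotypePanel:
    """Read a phased, biallelic-SNP VCF into a :class:`HaplotypePanel`.

    Multiallelic, non-SNP, unphased or partially missing sites are skipped
    and the counts logged.  Each diploid sample contributes two haplotype
    rows (in header order, haplotype 0 then 1).

    Raises
    ------
    KeyError
        If a VCF sample is missing from ``pop_assignment``.
    EmptyPanelError
        If no site survives the filters.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_assignment]
    if missing:
        raise KeyError(
            "samples missing from population assignment: " + ", ".join(missing)
        )

    chrom: str | None = None
    positions: list[int] = []
    columns: list[np.ndarray] = []
    skipped = {"multiallelic_or_not_snp": 0, "missing_gt": 0, "unphased": 0,
               "other_chrom": 0}
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["multiallelic_or_not_snp"] += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            skipped["other_chrom"] += 1
            continue
        gts = v.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.int16)
        ok = True
        for i, g in enumerate(gts):
            a, b, phased = g[0], g[1], g[-1]
            if a < 0 or b < 0:
                skipped["missing_gt"] += 1
                ok = False
                break
            if not phased:
                skipped["unphased"] += 1
                ok = False
                break
            col[2 * i] = a
            col[2 * i + 1] = b
        if ok:
            positions.append(v.POS)
            columns.append(col)
    if not columns:
        raise EmptyPanelError(f"no phased biallelic SNPs retained from {path}")
    n_skipped = sum(skipped.values())
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d sites (%s)", n_skipped, skipped)

    alleles = np.stack(columns, axis=1).astype(np.uint8)
    pop_of_hap = np.array([pop_assignment[s] for s in samples for _ in (0, 1)])
    sample_of_hap = np.array([s for s in samples for _ in (0, 1)])
    return HaplotypePanel(chrom or "chr1", np.array(positions), alleles,
                          pop_of_hap, sample_of_hap)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF 4.2 (GT fields only).

    Alleles 0/1 are written as REF=A, ALT=T.  Haplotype rows are paired into
    diploid samples by their ``sample_of_hap`` labels, which must appear in
    consecutive pairs.
    """
    sample_ids: list[str] = []
    for i in range(0, panel.n_hap, 2):
        if panel.sample_of_hap[i] != panel.sample_of_hap[i + 1]:
            raise ValueError("haplotype rows are not paired by sample")
        sample_ids.append(str(panel.sample_of_hap[i]))
    length = int(panel.positions[-1]) if panel.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{panel.alleles[2 * i, j]}|{panel.alleles[2 * i + 1, j]}"
                for i in range(len(sample_ids))
            )
            fh.write(f"{panel.chrom}\t{panel.positions[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Gene models with 1-based inclusive coordinates.

    ``genes`` has columns ``gene_id, chrom, start, end, strand``.  The TSS
    is the gene start on the + strand and the gene end on the − strand.
    """

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end", "strand"]
        if self.genes.empty:
            self.genes = pd.DataFrame(columns=required)
        missing = [c for c in required if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        g = self.genes
        bad = g[g["start"] > g["end"]]
        if len(bad):
            raise FormatError(
                "start > end for gene record(s): "
                + ", ".join(bad["gene_id"].astype(str))
            )
        if g["gene_id"].duplicated().any():
            dups = g.loc[g["gene_id"].duplicated(), "gene_id"].unique()
            raise FormatError("duplicate gene_id: " + ", ".join(map(str, dups)))
        if len(g) and not set(g["strand"]).issubset({"+", "-"}):
            raise FormatError("strand must be '+' or '-'")
        self.genes = g.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def tss(self) -> pd.Series:
        """Strand-aware transcription start site per gene (gene_id index)."""
        g = self.genes
        tss = np.where(g["strand"] == "+", g["start"], g["end"])
        return pd.Series(tss, index=g["gene_id"].to_numpy(), name="tss")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_gene_annotation(path: str | Path, dialect: str = "tsv") -> GenomeAnnotation:
    """Read gene models from GFF3 (type ``gene`` only) or a 5-column TSV.

    Both dialects use 1-based inclusive coordinates.  Unknown GFF3 feature
    types are ignored; an annotation with no gene records is returned empty
    with a warning.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return GenomeAnnotation(df[["gene_id", "chrom", "start", "end", "strand"]])
    if dialect != "gff3":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype != "gene":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if gene_id is None:
                raise FormatError(f"gene record without ID attribute: {line!r}")
            rows.append((gene_id, chrom, int(start), int(end), strand))
    if not rows:
        logger.warning("read_gene_annotation: no 'gene' records in %s", path)
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GenomeAnnotation(df)


def write_gene_annotation(ann: GenomeAnnotation, path: str | Path,
                          dialect: str = "tsv") -> None:
    """Write gene models as TSV or minimal GFF3 (type ``gene``)."""
    if dialect == "tsv":
        ann.genes[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
            path, sep="\t", index=False)
        return
    if dialect != "gff3":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in ann.genes.itertuples(index=False):
            fh.write(f"{r.chrom}\tcrestscan\tgene\t{r.start}\t{r.end}\t.\t"
                     f"{r.strand}\t.\tID={r.gene_id}\n")


# ---------------------------------------------------------------------------
# Islands as BED
# ---------------------------------------------------------------------------

def write_islands_bed(islands: Sequence, path: str | Path) -> None:
    """Write selection islands as BED3+ (0-based half-open).

    Extra columns: island_id, n_snps, peak_neglogp.  Input must already be
    sorted by (chrom, start); unsorted input is an error, never silently
    sorted.
    """
    keys = [(isl.chrom, isl.start) for isl in islands]
    if keys != sorted(keys):
        raise ValueError("islands must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tisland_id\tn_snps\tpeak_neglogp\n")
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\t"
                     f"{isl.island_id}\t{isl.n_snps}\t{isl.peak_neglogp:.6g}\n")


# ---------------------------------------------------------------------------
# Count matrices and metadata
# ---------------------------------------------------------------------------

def read_counts_tsv(counts_path: str | Path,
                    meta_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x samples count TSV plus its sample-metadata TSV.

    The counts table must have gene ids in the first column; metadata must
    have columns ``sample_id, species, stage, replicate``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t",
                       dtype={"sample_id": str, "species": str, "stage": str})
    required = {"sample_id", "species", "stage", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"sample metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    unknown = [s for s in counts.columns if s not in meta.index]
    if unknown:
        raise FormatError(f"count columns without metadata: {unknown}")
    return counts, meta.loc[counts.columns]


def write_counts_tsv(counts: pd.DataFrame, meta: pd.DataFrame,
                     counts_path: str | Path, meta_path: str | Path) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")
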