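import numpy as np
import pandas as pd
import pytest

from crestscan.io import GenomeAnnotation, HaplotypePanel


def make_panel(alleles, positions=None, pops=None, chrom="chr1"):
    """Build a small HaplotypePanel from a nested list / array."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_sites = alleles.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if pops is None:
        pops = ["A"] * n_hap
    samples = [f"s{i // 2:03d}" for i in range(n_hap)]
    return HaplotypePanel(chrom, np.asarray(positions), alleles,
                          np.asarray(pops), np.asarray(samples))


def random_panel(rng, n_hap=10, n_sites=20, pops=None):
    """Random biallelic panel with correlated columns (founder pairs)."""
    founders = rng.integers(0, 2, size=(4, n_sites), dtype=np.uint8)
    which = rng.integers(0, 4, size=n_hap)
    alleles = founders[which] ^ (rng.random((n_hap, n_sites)) < 0.2).astype(np.uint8)
    positions = np.sort(rng.choice(np.arange(1, 100 * n_sites), size=n_sites,
                                   replace=False))
    return make_panel(alleles, positions, pops)


def make_annotation(rows):
    """rows: (gene_id, chrom, start, end, strand)."""
    return GenomeAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def scan_frame(positions, neglogp, sig=None, chrom="chr1"):
    """Minimal scan table for islands/enrichment tests."""
    neglogp = np.asarray(neglogp, dtype=float)
    if sig is None:
        sig = neglogp >= 3.0
    return pd.DataFrame({
        "chrom": chrom, "pos": list(positions),
        "xpehh_std": neglogp,  # stand-in, only used where |z| is requested
        "neg_log10_p": neglogp, "significant": list(sig),
    })


@pytest.fixture
def rng():
    return np.random.default_rng(42)
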