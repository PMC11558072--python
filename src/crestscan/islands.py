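"""Merge significant scan SNPs into islands and link islands to genes.

Islands are formed by padding each significant SNP by ``slop_bp`` on both
sides and merging windows that overlap or touch (transitively), the slop /
merge semantics of interval tools.  Equivalently: consecutive significant
SNPs on a chromosome join one island iff their distance is at most
``2 * slop_bp``.  Island coordinates are the min/max member SNP positions,
so a singleton island spans exactly 1 bp.

Gene linking classifies each island by precedence: overlap with any gene
body; otherwise overlap with any promoter (a fixed window immediately
upstream of the TSS, strand-aware); otherwise the nearest gene within a
maximum distance (exact ties link all tied genes).  Islands beyond that
distance from every gene are reported unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeAnnotation


@dataclass
class SelectionIsland:
    """A merged run of significant SNPs (1-based inclusive coordinates)."""

    island_id: str
    chrom: str
    start: int
    end: int
    member_positions: list[int] = field(default_factory=list)
    peak: int = 0                # position of the max -log10 p member
    peak_neglogp: float = 0.0

    @property
    def n_snps(self) -> int:
        return len(self.member_positions)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


def call_islands(scan: pd.DataFrame, slop_bp: int = 50_000) -> list[SelectionIsland]:
    """Group significant SNPs into islands by +/- ``slop_bp`` window overlap.

    ``scan`` is a scan table (see :data:`crestscan.scan.SCAN_COLUMNS`) and
    must be sorted by (chrom, pos).  Only rows with ``significant`` True
    enter islands.  Returns islands sorted by (chrom, start).
    """
    if slop_bp < 0:
        raise ValueError("slop_bp must be non-negative")
    key = list(zip(scan["chrom"], scan["pos"]))
    if key != sorted(key):
        raise ValueError("scan records must be sorted by (chrom, pos)")
    sig = scan[scan["significant"]]
    islands: list[SelectionIsland] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        nlp = grp["neg_log10_p"].to_numpy()
        start_idx = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > 2 * slop_bp:
                members = pos[start_idx:i]
                scores = nlp[start_idx:i]
                peak_i = int(np.argmax(scores))
                islands.append(SelectionIsland(
                    island_id=f"island_{len(islands) + 1:04d}",
                    chrom=str(chrom),
                    start=int(members[0]),
                    end=int(members[-1]),
                    member_positions=[int(p) for p in members],
                    peak=int(members[peak_i]),
                    peak_neglogp=float(scores[peak_i]),
                ))
                start_idx = i
    return islands


def islands_to_frame(islands: list[SelectionIsland]) -> pd.DataFrame:
    """Tabular view of islands (one row each)."""
    return pd.DataFrame(
        [(i.island_id, i.chrom, i.start, i.end, i.span_bp, i.n_snps,
          i.peak, i.peak_neglogp) for i in islands],
        columns=["island_id", "chrom", "start", "end", "span_bp", "n_snps",
                 "peak", "peak_neglogp"],
    )


def _promoter_interval(start: int, end: int, strand: str,
                       promoter_bp: int) -> tuple[int, int]:
    """Promoter window immediately upstream of the TSS, clipped at 1."""
    if strand == "+":
        return max(1, start - promoter_bp), start - 1
    return end + 1, end + promoter_bp


def link_genes(islands: list[SelectionIsland], annotation: GenomeAnnotation,
               promoter_bp: int = 5_000, link_max_dist_bp: int = 200_000
               ) -> tuple[pd.DataFrame, list[str]]:
    """Classify each island against gene bodies, promoters and neighbors.

    Returns ``(links, unlinked)``: a table with columns
    ``island_id, gene_id, relation, distance_bp`` (relation one of
    gene_body / promoter / intergenic; distance 0 for the first two), and
    the ids of islands with no gene within ``link_max_dist_bp``.
    """
    g = annotation.genes
    links: list[tuple[str, str, str, int]] = []
    unlinked: list[str] = []
    for isl in islands:
        on_chrom = g[g["chrom"] == isl.chrom]
        if on_chrom.empty:
            unlinked.append(isl.island_id)
            continue
        gs = on_chrom["start"].to_numpy()
        ge = on_chrom["end"].to_numpy()
        gids = on_chrom["gene_id"].to_numpy()
        strands = on_chrom["strand"].to_numpy()

        body = (gs <= isl.end) & (ge >= isl.start)
        if body.any():
            links.extend((isl.island_id, gid, "gene_body", 0)
                         for gid in gids[body])
            continue

        prom_hits = []
        for gid, s, e, st in zip(gids, gs, ge, strands):
            ps, pe = _promoter_interval(int(s), int(e), st, promoter_bp)
            if ps <= pe and ps <= isl.end and pe >= isl.start:
                prom_hits.append(gid)
        if prom_hits:
            links.extend((isl.island_id, gid, "promoter", 0)
                         for gid in prom_hits)
            continue

        # nearest gene: min gap between the island and the gene interval
        gap = np.where(ge < isl.start, isl.start - ge,
                       np.where(gs > isl.end, gs - isl.end, 0))
        dmin = int(gap.min())
        if dmin == 0 or dmin > link_max_dist_bp:
            # dmin == 0 cannot occur here (body overlap handled above)
            unlinked.append(isl.island_id)
            continue
        for gid in gids[gap == dmin]:
            links.append((isl.island_id, gid, "intergenic", dmin))
    frame = pd.DataFrame(links, columns=["island_id", "gene_id", "relation",
                                         "distance_bp"])
    return frame, unlinked
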