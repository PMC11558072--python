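"""Extended haplotype homozygosity (EHH), iES and cross-population xpEHH.

The statistics follow the standard selection-scan conventions:

* ``EHH(x)`` for a core site and core allele is the probability that two
  randomly chosen carrier haplotypes are identical over the interval from
  the core to site ``x``;
* ``iES`` is the area under the EHH decay curve against physical position,
  integrated outward in both directions from the core with the trapezoid
  rule, truncating each side where EHH first drops below a threshold;
* ``xpEHH = ln(iES_A / iES_B)`` contrasts two populations at a site —
  positive values mean longer haplotypes (stronger homozygosity) in
  population A — and is standardized genome-wide into a z-score from which
  a two-sided normal p-value is derived.

Distances are physical base pairs; no recombination-map weighting is
applied.  The core allele is fixed to allele 1; no ancestral/derived
polarization is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import EmptyPanelError, HaplotypePanel

logger = logging.getLogger(__name__)

LOG10 = math.log(10.0)

#: Columns of the scan table produced by :func:`xpehh_scan`.
SCAN_COLUMNS = [
    "chrom", "pos", "freq1_a", "freq1_b", "ies_a", "ies_b",
    "xpehh_raw", "xpehh_std", "p_two_sided", "neg_log10_p", "significant",
]


class EHHUndefinedError(ValueError):
    """Fewer than two haplotypes carry the core allele."""


class InsufficientSitesError(ValueError):
    """Too few scannable sites to standardize the scan."""


class DegenerateScanError(ValueError):
    """Raw xpEHH has zero variance; standardization is undefined."""


@dataclass
class ScanConfig:
    """Parameters of the xpEHH scan.

    maf_min
        Sites are retained when the pooled minor allele frequency is
        strictly greater than this value.
    ehh_truncation
        EHH integration stops at the first site where EHH falls below this
        value (that site is included as the final trapezoid endpoint).
    max_gap_bp
        If set, integration aborts before crossing a gap larger than this.
    sig_neglogp
        A site is significant when -log10(p) >= this value.
    standardize
        ``"freq_bins"`` (default: standardize within equal-width bins of
        pooled allele-1 frequency, falling back to the global moments for
        sparse bins) or ``"global"`` (one genome-wide distribution).
        Binning is the default because the sampling variance of
        ``ln(iES_A/iES_B)`` grows sharply at sites where one population has
        few core-allele carriers; a single global distribution is then
        heavy-tailed and the normal p-values are anticonservative.
    clip_k
        If set, the standardization moments (mean, sd) are computed after
        discarding raw values more than ``clip_k`` robust standard
        deviations (1.4826 x MAD) from the median, so that a strong sweep
        does not inflate the scale of its own null distribution.  ``None``
        uses plain moments over all scanned sites.
    """

    maf_min: float = 0.05
    ehh_truncation: float = 0.05
    max_gap_bp: int | None = None
    sig_neglogp: float = 3.0
    standardize: str = "freq_bins"
    n_freq_bins: int = 20
    clip_k: float | None = 4.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must satisfy 0 <= maf_min < 0.5")
        if not (0.0 < self.ehh_truncation < 1.0):
            raise ValueError("ehh_truncation must lie in (0, 1)")
        if self.sig_neglogp <= 0:
            raise ValueError("sig_neglogp must be positive")
        if self.standardize not in ("global", "freq_bins"):
            raise ValueError("standardize must be 'global' or 'freq_bins'")
        if self.standardize == "freq_bins" and self.n_freq_bins < 1:
            raise ValueError("n_freq_bins must be >= 1")


def maf_filter(panel: HaplotypePanel, maf_min: float = 0.05) -> HaplotypePanel:
    """Retain sites whose pooled minor allele frequency is > ``maf_min``.

    The frequency pools all haplotypes of the panel (both populations);
    the inequality is strict.  Site order is preserved.
    """
    freq = panel.allele1_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > maf_min
    if not keep.any():
        raise EmptyPanelError("MAF filter removed all sites")
    return panel.subset_sites(keep)


def ehh(panel: HaplotypePanel, core_site_index: int, core_allele: int,
        direction: str, *, truncation: float = 0.05,
        max_gap_bp: int | None = None) -> list[tuple[int, float]]:
    """EHH decay sequence outward from a core site, for one direction.

    Carrier haplotypes are partitioned by identity of their allele vector
    over ``[core..x]``; ``EHH(x)`` is the fraction of carrier pairs falling
    in the same class.  The sequence starts with ``(core, 1.0)`` and extends
    until EHH drops below ``truncation`` (that site included), the
    chromosome ends, or a gap exceeds ``max_gap_bp``.

    Raises :class:`EHHUndefinedError` when fewer than two haplotypes carry
    ``core_allele`` — callers must skip such sites.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    H = panel.alleles
    carriers = H[:, core_site_index] == core_allele
    n_c = int(carriers.sum())
    if n_c < 2:
        raise EHHUndefinedError(
            f"site {core_site_index}: {n_c} carrier(s) of allele {core_allele}")
    sub = H[carriers]
    denom = n_c * (n_c - 1) / 2.0
    step = 1 if direction == "right" else -1
    pos = panel.positions
    out = [(core_site_index, 1.0)]
    ids = np.zeros(n_c, dtype=np.int64)
    j = core_site_index
    while True:
        nj = j + step
        if nj < 0 or nj >= panel.n_sites:
            break
        if max_gap_bp is not None and abs(int(pos[nj]) - int(pos[j])) > max_gap_bp:
            break
        # refine the identity partition with the next column
        key = ids * 2 + sub[:, nj]
        _, ids = np.unique(key, return_inverse=True)
        counts = np.bincount(ids)
        val = float((counts * (counts - 1)).sum() / 2.0 / denom)
        out.append((nj, val))
        j = nj
        if val < truncation:
            break
    return out


def ies(panel: HaplotypePanel, core_site_index: int, core_allele: int,
        cfg: ScanConfig | None = None) -> float:
    """Integrated EHH (bp): trapezoidal area of the EHH decay, both sides.

    Each side is truncated at the first site with EHH below the threshold,
    which is included as the final trapezoid endpoint.  A core with no
    flanking site contributes zero area.
    """
    cfg = cfg or ScanConfig()
    pos = panel.positions
    total = 0.0
    for direction in ("left", "right"):
        seq = ehh(panel, core_site_index, core_allele, direction,
                  truncation=cfg.ehh_truncation, max_gap_bp=cfg.max_gap_bp)
        for (i1, e1), (i2, e2) in zip(seq, seq[1:]):
            total += abs(int(pos[i2]) - int(pos[i1])) * (e1 + e2) / 2.0
    return total


def _clipped_moments(v: np.ndarray, clip_k: float | None) -> tuple[float, float]:
    """Mean and sd, optionally after discarding points beyond
    ``clip_k`` robust standard deviations of the median."""
    if clip_k is not None:
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        if mad > 0:
            v = v[np.abs(v - med) <= clip_k * mad]
    return float(v.mean()), float(v.std(ddof=0))


def _standardize(raw: np.ndarray, freq_pooled: np.ndarray,
                 cfg: ScanConfig) -> np.ndarray:
    mu, sd = _clipped_moments(raw, cfg.clip_k)
    if sd == 0.0:
        raise DegenerateScanError("raw xpEHH has zero variance")
    z = (raw - mu) / sd
    if cfg.standardize == "global":
        return z
    # frequency-binned mode: equal-width bins of pooled allele-1 frequency;
    # bins with fewer than 10 sites fall back to the global standardization
    edges = np.linspace(0.0, 1.0, cfg.n_freq_bins + 1)
    which = np.clip(np.digitize(freq_pooled, edges[1:-1]), 0, cfg.n_freq_bins - 1)
    for b in range(cfg.n_freq_bins):
        m = which == b
        if m.sum() >= 10:
            bmu, bsd = _clipped_moments(raw[m], cfg.clip_k)
            if bsd > 0:
                z[m] = (raw[m] - bmu) / bsd
    return z


def xpehh_scan(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
               cfg: ScanConfig | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site xpEHH scan between two populations.

    Both panels must share chromosome and positions (filter the pooled
    panel for MAF first, then split by population).  Sites where either
    population has fewer than two carriers of allele 1, or where an iES is
    zero, are skipped with a logged reason.

    Returns ``(scan, skip_log)``: the scan table (columns
    :data:`SCAN_COLUMNS`) and a table of skipped sites with reasons.
    """
    cfg = cfg or ScanConfig()
    if panel_a.chrom != panel_b.chrom or not np.array_equal(
            panel_a.positions, panel_b.positions):
        raise ValueError("panels must share chromosome and positions")
    n_sites = panel_a.n_sites
    rows: list[tuple] = []
    skips: list[tuple[int, str]] = []
    count_a = panel_a.alleles.sum(axis=0, dtype=np.int64)
    count_b = panel_b.alleles.sum(axis=0, dtype=np.int64)
    na, nb = panel_a.n_hap, panel_b.n_hap
    fa_all = count_a / na
    fb_all = count_b / nb
    for j in range(n_sites):
        ca = int(count_a[j])
        cb = int(count_b[j])
        if ca < 2 or cb < 2:
            skips.append((int(panel_a.positions[j]), "lt2_carriers"))
            continue
        ies_a = ies(panel_a, j, 1, cfg)
        ies_b = ies(panel_b, j, 1, cfg)
        if ies_a == 0.0 or ies_b == 0.0:
            skips.append((int(panel_a.positions[j]), "zero_ies"))
            continue
        rows.append((panel_a.chrom, int(panel_a.positions[j]),
                     float(fa_all[j]), float(fb_all[j]), ies_a, ies_b,
                     math.log(ies_a / ies_b)))
    skip_log = pd.DataFrame(skips, columns=["pos", "reason"])
    if len(skips):
        logger.info("xpehh_scan: skipped %d/%d sites", len(skips), n_sites)
    if len(rows) < 10:
        raise InsufficientSitesError(
            f"only {len(rows)} scannable sites; need >= 10 to standardize")
    scan = pd.DataFrame(rows, columns=["chrom", "pos", "freq1_a", "freq1_b",
                                       "ies_a", "ies_b", "xpehh_raw"])
    raw = scan["xpehh_raw"].to_numpy()
    pooled = (scan["freq1_a"].to_numpy() * na + scan["freq1_b"].to_numpy() * nb) / (na + nb)
    z = _standardize(raw, pooled, cfg)
    # logsf keeps precision for extreme z where 2*sf underflows
    log_p = math.log(2.0) + norm.logsf(np.abs(z))
    neg_log10_p = -log_p / LOG10
    scan["xpehh_std"] = z
    scan["p_two_sided"] = np.exp(log_p)
    scan["neg_log10_p"] = neg_log10_p
    scan["significant"] = neg_log10_p >= cfg.sig_neglogp
    return scan[SCAN_COLUMNS], skip_log


def scan_two_pop_panel(panel: HaplotypePanel, pop_a: str, pop_b: str,
                       cfg: ScanConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: pooled MAF filter, split by population, scan."""
    cfg = cfg or ScanConfig()
    filtered = maf_filter(panel, cfg.maf_min)
    return xpehh_scan(filtered.subset_pop(pop_a), filtered.subset_pop(pop_b), cfg)
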