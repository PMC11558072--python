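"""Unit tests for EHH, iES and the xpEHH scan."""

import numpy as np
import pytest

from crestscan import scan
from crestscan.io import EmptyPanelError
from crestscan.scan import (DegenerateScanError, EHHUndefinedError,
                            InsufficientSitesError, ScanConfig, ehh, ies,
                            maf_filter, xpehh_scan)

import oracles
from conftest import make_panel, random_panel


class TestMafFilter:
    def test_balanced_site_retained(self):
        panel = make_panel([[0], [1]])
        assert maf_filter(panel, 0.05).n_sites == 1

    def test_boundary_maf_removed_strictly(self):
        """Pooled MAF exactly at the threshold is removed (strict >)."""
        alleles = np.zeros((20, 2), dtype=np.uint8)
        alleles[0, 0] = 1           # MAF exactly 0.05
        alleles[:10, 1] = 1         # MAF 0.5 keeps the panel non-empty
        panel = make_panel(alleles)
        kept = maf_filter(panel, 0.05)
        assert kept.n_sites == 1
        assert kept.positions.tolist() == [panel.positions[1]]

    def test_matches_direct_count_oracle(self, rng):
        panel = random_panel(rng, n_hap=30, n_sites=50)
        kept = maf_filter(panel, 0.05)
        freqs = panel.alleles.mean(axis=0)
        expect = [i for i, f in enumerate(freqs) if min(f, 1 - f) > 0.05]
        assert kept.positions.tolist() == panel.positions[expect].tolist()

    def test_all_removed_is_error(self):
        panel = make_panel(np.zeros((10, 3), dtype=np.uint8))
        with pytest.raises(EmptyPanelError):
            maf_filter(panel, 0.05)


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        alleles = np.ones((4, 5), dtype=np.uint8)
        panel = make_panel(alleles)
        seq = ehh(panel, 2, 1, "right")
        assert [v for _, v in seq] == [1.0, 1.0, 1.0]

    def test_worked_four_carrier_example(self):
        """Carriers extending to vectors {00, 00, 01, 11}: one identical
        pair of C(4,2)=6 gives EHH = 1/6."""
        # core at column 0 (all ones); columns 1..2 encode the vectors
        alleles = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 1],
            [1, 1, 1],
        ], dtype=np.uint8)
        panel = make_panel(alleles)
        seq = ehh(panel, 0, 1, "right", truncation=0.01)
        assert seq[2][1] == pytest.approx(1 / 6)

    def test_monotone_nonincreasing_and_core_one(self, rng):
        for _ in range(20):
            panel = random_panel(rng, n_hap=12, n_sites=30)
            core = int(rng.integers(0, panel.n_sites))
            for allele in (0, 1):
                if np.sum(panel.alleles[:, core] == allele) < 2:
                    continue
                for direction in ("left", "right"):
                    seq = ehh(panel, core, allele, direction, truncation=1e-9)
                    vals = [v for _, v in seq]
                    assert vals[0] == 1.0
                    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_pair_counting_oracle_exact(self, rng):
        for _ in range(30):
            panel = random_panel(rng, n_hap=int(rng.integers(4, 12)),
                                 n_sites=int(rng.integers(5, 25)))
            core = int(rng.integers(0, panel.n_sites))
            if np.sum(panel.alleles[:, core] == 1) < 2:
                continue
            for direction in ("left", "right"):
                got = ehh(panel, core, 1, direction)
                exp = oracles.ehh_pair_counting(panel.alleles, core, 1,
                                                direction)
                assert [(i, pytest.approx(v)) for i, v in exp] == got

    def test_too_few_carriers_raises(self):
        panel = make_panel([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(EHHUndefinedError):
            ehh(panel, 0, 1, "right")

    def test_max_gap_aborts_extension(self):
        alleles = np.ones((4, 3), dtype=np.uint8)
        panel = make_panel(alleles, positions=[100, 200, 50_000])
        seq = ehh(panel, 0, 1, "right", max_gap_bp=1000)
        assert [i for i, _ in seq] == [0, 1]


class TestIes:
    def test_unit_plateau_equals_span(self):
        alleles = np.ones((4, 5), dtype=np.uint8)
        panel = make_panel(alleles, positions=[1000, 2000, 3000, 4000, 5000])
        assert ies(panel, 2, 1) == pytest.approx(4000.0)  # both sides

    def test_no_flanking_sites_zero(self):
        panel = make_panel([[1], [1]])
        assert ies(panel, 0, 1) == 0.0

    def test_matches_trapezoid_oracle(self, rng):
        cfg = ScanConfig()
        for _ in range(20):
            panel = random_panel(rng, n_hap=10, n_sites=20)
            core = int(rng.integers(0, panel.n_sites))
            if np.sum(panel.alleles[:, core] == 1) < 2:
                continue
            seqs = [ehh(panel, core, 1, d, truncation=cfg.ehh_truncation)
                    for d in ("left", "right")]
            assert ies(panel, core, 1, cfg) == pytest.approx(
                oracles.trapezoid_ies(panel.positions, seqs))

    def test_grows_when_truncation_lowered(self, rng):
        panel = random_panel(rng, n_hap=14, n_sites=40)
        core = 20
        if np.sum(panel.alleles[:, core] == 1) >= 2:
            hi = ies(panel, core, 1, ScanConfig(ehh_truncation=0.4))
            lo = ies(panel, core, 1, ScanConfig(ehh_truncation=0.01))
            assert lo >= hi - 1e-12


def two_pop_panels(rng, n_hap=20, n_sites=40):
    pa = random_panel(rng, n_hap=n_hap, n_sites=n_sites)
    alleles_b = pa.alleles.copy()
    flip = rng.random(alleles_b.shape) < 0.1
    alleles_b = alleles_b ^ flip.astype(np.uint8)
    pb = make_panel(alleles_b, positions=pa.positions)
    return pa, pb


class TestXpehhScan:
    def test_identical_panels_degenerate(self, rng):
        pa, _ = two_pop_panels(rng)
        with pytest.raises(DegenerateScanError):
            xpehh_scan(pa, pa, ScanConfig(standardize="global", clip_k=None))

    def test_swapping_populations_negates_raw(self, rng):
        pa, pb = two_pop_panels(rng)
        fwd, _ = xpehh_scan(pa, pb)
        rev, _ = xpehh_scan(pb, pa)
        assert np.allclose(fwd["xpehh_raw"].to_numpy(),
                           -rev["xpehh_raw"].to_numpy())

    def test_global_standardization_identity(self, rng):
        pa, pb = two_pop_panels(rng)
        df, _ = xpehh_scan(pa, pb, ScanConfig(standardize="global",
                                              clip_k=None))
        z = df["xpehh_std"].to_numpy()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1.0) < 1e-9

    def test_straightline_reimplementation_agrees(self, rng):
        """Raw per-site values equal an independent straight-line
        reimplementation on small two-population panels."""
        for _ in range(5):
            pa, pb = two_pop_panels(rng, n_hap=8, n_sites=15)
            try:
                df, skip = xpehh_scan(pa, pb, ScanConfig(standardize="global",
                                                         clip_k=None))
            except (InsufficientSitesError, DegenerateScanError):
                continue
            pos_o, raw_o = oracles.xpehh_straightline(
                pa.alleles, pb.alleles, pa.positions)
            assert df["pos"].tolist() == pos_o
            assert np.allclose(df["xpehh_raw"].to_numpy(), raw_o)

    def test_skip_log_accounts_for_all_sites(self, rng):
        pa, pb = two_pop_panels(rng)
        df, skip = xpehh_scan(pa, pb)
        assert len(df) + len(skip) == pa.n_sites
        assert set(skip["reason"]) <= {"lt2_carriers", "zero_ies"}

    def test_too_few_sites_refuses_standardization(self):
        pa = make_panel(np.tile([[1], [1], [0], [0]], (1, 3)))
        pb = make_panel((np.tile([[1], [0], [1], [0]], (1, 3))),
                        positions=pa.positions)
        with pytest.raises(InsufficientSitesError):
            xpehh_scan(pa, pb)

    def test_significance_flag_matches_threshold(self, rng):
        pa, pb = two_pop_panels(rng)
        df, _ = xpehh_scan(pa, pb, ScanConfig(sig_neglogp=0.5))
        assert (df["significant"] == (df["neg_log10_p"] >= 0.5)).all()
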