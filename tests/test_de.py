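"""Unit tests for normalization, filtering and the NB Wald DE test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crestscan import de
from crestscan.de import (CountMatrix, bh_adjust, collapse_technical_replicates,
                          de_test, low_count_filter, normalize, pool_degs,
                          run_stage_contrasts, size_factors)

import oracles


def make_cm(counts, species, stages=None, reps=None):
    counts = pd.DataFrame(np.asarray(counts),
                          index=[f"g{i}" for i in range(len(counts))])
    n = counts.shape[1]
    counts.columns = [f"s{j}" for j in range(n)]
    meta = pd.DataFrame({
        "species": species,
        "stage": stages or ["st1"] * n,
        "replicate": reps or list(range(n)),
    }, index=counts.columns)
    return CountMatrix(counts, meta)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame([[10, 10], [3, 3]], columns=["a", "b"])
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_worked_example(self):
        """Sample 2 = 2 x sample 1: ratios to the geometric-mean reference
        give factors (1/sqrt(2), sqrt(2))."""
        counts = pd.DataFrame({"a": [10, 4, 100], "b": [20, 8, 200]})
        s = size_factors(counts)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_naive_oracle_exactly(self, rng):
        for _ in range(10):
            x = rng.integers(0, 500, size=(30, 6))
            x[:5] += 1  # guarantee some all-positive genes
            counts = pd.DataFrame(x)
            assert np.allclose(size_factors(counts).to_numpy(),
                               oracles.size_factors_naive(x), rtol=0, atol=0)

    def test_scale_equivariance_of_factor_ratios(self, rng):
        """Size factors are defined up to a constant: scaling one sample
        by c scales its factor relative to every other sample by c."""
        x = rng.integers(1, 500, size=(40, 5))
        base = size_factors(pd.DataFrame(x))
        x2 = x.copy().astype(float)
        x2[:, 2] *= 3.0
        scaled = size_factors(pd.DataFrame(x2))
        assert (scaled.iloc[2] / scaled.iloc[0]
                == pytest.approx(3 * base.iloc[2] / base.iloc[0]))

    def test_no_all_positive_gene_errors_with_fallback_hint(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(counts)
        s = size_factors(counts, pseudo_reference=True)
        assert (s > 0).all()


class TestLowCountFilter:
    def test_all_zero_gene_removed(self):
        cm = make_cm([[0, 0, 0, 0], [20, 20, 20, 20]], ["A", "A", "B", "B"])
        kept = low_count_filter(cm)
        assert list(kept.counts.index) == ["g1"]

    def test_single_sample_at_threshold_retained(self):
        """One species-A sample reaching min_count rescues the gene under
        the default (most permissive) rule."""
        cm = make_cm([[10, 0, 0, 0], [20, 20, 20, 20]], ["A", "A", "B", "B"])
        assert "g0" in low_count_filter(cm).counts.index
        assert "g0" not in low_count_filter(
            cm, rule="either_species_all").counts.index

    def test_high_count_gene_retained_all_rules(self):
        cm = make_cm([[12, 15, 11, 30]], ["A", "A", "B", "B"])
        for rule in de.FILTER_RULES:
            assert len(low_count_filter(cm, rule=rule).counts) == 1

    def test_all_removed_is_error(self):
        cm = make_cm([[0, 0, 1, 2]], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="every gene"):
            low_count_filter(cm)


class TestBH:
    def test_worked_stepup_example(self):
        """p = (0.01, 0.02, 0.03, 0.04) all adjust to 0.04."""
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
                           [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_naive_stepup(self, pvals):
        p = np.array(pvals)
        got = bh_adjust(p)
        exp = oracles.bh_naive(p)
        assert np.allclose(got, exp)
        assert (got >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(got[order]) >= -1e-12).all()


class TestDeTest:
    def _norm_cm(self, rng, n_genes=200, mu=300.0, lfc_genes=0):
        a = rng.poisson(mu, size=(n_genes, 3))
        b = rng.poisson(mu, size=(n_genes, 3))
        if lfc_genes:
            b[:lfc_genes] = rng.poisson(mu * 4, size=(lfc_genes, 3))
        counts = pd.DataFrame(
            np.hstack([a, b]), index=[f"g{i}" for i in range(n_genes)],
            columns=[f"A{r}" for r in range(3)] + [f"B{r}" for r in range(3)])
        return counts

    def test_identical_groups_no_calls(self):
        counts = pd.DataFrame([[7, 8, 9, 7, 8, 9], [50, 60, 55, 50, 60, 55]],
                              index=["g0", "g1"],
                              columns=list("abcdef"))
        res = de_test(counts, ["a", "b", "c"], ["d", "e", "f"], "st1")
        assert np.allclose(res["log2fc"], 0.0)
        assert not res["is_deg"].any()

    def test_antisymmetry_under_group_swap(self, rng):
        counts = self._norm_cm(rng, lfc_genes=20)
        ga, gb = ["A0", "A1", "A2"], ["B0", "B1", "B2"]
        fwd = de_test(counts, ga, gb, "st1")
        rev = de_test(counts, gb, ga, "st1")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_planted_fold_change_detected(self, rng):
        counts = self._norm_cm(rng, lfc_genes=30)
        res = de_test(counts, ["A0", "A1", "A2"], ["B0", "B1", "B2"], "st1")
        called = set(res.loc[res["is_deg"], "gene_id"])
        planted = {f"g{i}" for i in range(30)}
        assert len(called & planted) >= 24
        assert len(called - planted) <= 5

    def test_deg_flag_definition(self, rng):
        counts = self._norm_cm(rng, lfc_genes=10)
        res = de_test(counts, ["A0", "A1", "A2"], ["B0", "B1", "B2"], "st1")
        expect = (res["log2fc"].abs() >= 0.585) & (res["padj"] < 0.05)
        assert (res["is_deg"] == expect).all()
        assert (res["padj"] >= res["p"] - 1e-12).all()

    def test_single_replicate_group_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], index=["g0"],
                              columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="2 replicates"):
            de_test(counts, ["a"], ["b", "c"], "st1")


class TestPoolingAndCollapse:
    def _results(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g1", "g2", "g2", "g3", "g3"],
            "stage": ["s1", "s2"] * 3,
            "is_deg": [True, False, False, False, False, True],
        })

    def test_single_stage_deg_pools(self):
        pooled = pool_degs(self._results())
        assert pooled.loc["g1", "pooled"]
        assert not pooled.loc["g2", "pooled"]

    def test_excluded_stage_removes_only_contrast(self):
        pooled = pool_degs(self._results(), stage_exclusions=["s2"])
        assert not pooled.loc["g3", "pooled"]
        assert pooled.loc["g1", "pooled"]

    def test_union_matches_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        rows = [(g, s, bool(rng.random() < 0.2))
                for g in genes for s in ("s1", "s2", "s3")]
        res = pd.DataFrame(rows, columns=["gene_id", "stage", "is_deg"])
        pooled = pool_degs(res)
        expect = {g for g, s, d in rows if d}
        assert set(pooled.index[pooled["pooled"]]) == expect

    def test_collapse_sums_shared_replicate_groups(self):
        counts = pd.DataFrame([[1, 2, 4, 8]], index=["g0"],
                              columns=["s0", "s1", "s2", "s3"])
        meta = pd.DataFrame({"species": ["A", "A", "B", "B"],
                             "stage": ["s1"] * 4,
                             "replicate": [1, 1, 1, 2]}, index=counts.columns)
        collapsed = collapse_technical_replicates(counts, meta)
        assert sorted(collapsed.counts.iloc[0].tolist()) == [3, 4, 8]


class TestStageContrasts:
    def test_excluded_stage_absent_from_results(self, rng):
        from crestscan.synthetic import CountSimConfig, simulate_counts
        cfg = CountSimConfig(n_genes=80, stages=("s1", "s2", "s3"), seed=3)
        cm, _ = simulate_counts(cfg)
        res_all = run_stage_contrasts(cm)
        res_exc = run_stage_contrasts(cm, stage_exclusions=["s2"])
        assert set(res_all["stage"]) == {"s1", "s2", "s3"}
        assert set(res_exc["stage"]) == {"s1", "s3"}

    def test_normalization_removes_library_size(self, rng):
        from crestscan.synthetic import CountSimConfig, simulate_counts
        cfg = CountSimConfig(n_genes=300, libsize_factor_sd=0.4, frac_deg=0.0,
                             seed=8)
        cm, _ = simulate_counts(cfg)
        norm = normalize(cm)
        col_sums = norm.sum(axis=0)
        assert col_sums.std() / col_sums.mean() < 0.25
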