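"""WGBS arm: coverage filtering, count-pooled region methylation, the
Hyper log-ratio, differential testing, dip calling against a per-base
brute force, and the best-fit methylation-expression model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epichrom.genome import GenomicInterval
from epichrom.methylation import (
    CpGMethylationTrack,
    best_fit_expression_model,
    call_methyl_dips,
    concordance_index,
    diff_region_methylation,
    filter_cpgs,
    hyper,
    pooled_mask_ml,
    summative_methylation,
    windowed_methylation,
)


def _track(pos, numC_g, numT_g, numC_t=None, numT_t=None, chrom="chr1"):
    numC_t = numC_g if numC_t is None else numC_t
    numT_t = numT_g if numT_t is None else numT_t
    return CpGMethylationTrack(
        chrom=np.array([chrom] * len(pos), dtype=object),
        pos=np.array(pos),
        numC={"GLOM": np.atleast_2d(numC_g), "TI": np.atleast_2d(numC_t)},
        numT={"GLOM": np.atleast_2d(numT_g), "TI": np.atleast_2d(numT_t)},
    )


class TestCoverageFilter:
    def test_coverage_exactly_five_is_removed(self):
        t = _track([10, 20], np.array([[3], [4]]), np.array([[2], [4]]))
        kept = filter_cpgs(t, min_coverage=5)  # site 0 has coverage 5
        assert kept.pos.tolist() == [20]

    def test_coverage_six_in_all_samples_is_kept(self):
        t = _track([10], np.array([[3, 3]]), np.array([[3, 3]]))
        assert filter_cpgs(t, 5).n_sites() == 1

    def test_vacuous_filter_is_identity(self, rng):
        c = rng.integers(1, 10, size=(20, 3))
        t = _track(np.arange(20) * 10, c, c)
        assert filter_cpgs(t, 0).n_sites() == 20


class TestSummativeMethylation:
    def test_direct_sum_two_cpgs(self):
        t = _track([10, 20], np.array([[3], [1]]), np.array([[1], [3]]))
        ml = summative_methylation(t, GenomicInterval("chr1", 0, 100), "GLOM")
        assert ml == pytest.approx(4 / 8)

    def test_fully_methylated(self):
        t = _track([10], np.array([[7]]), np.array([[0]]))
        assert summative_methylation(t, GenomicInterval("chr1", 0, 100), "GLOM") == 1.0

    def test_zero_coverage_returns_nan_not_zero(self):
        t = _track([10], np.array([[0]]), np.array([[0]]))
        assert math.isnan(summative_methylation(t, GenomicInterval("chr1", 0, 100), "GLOM"))

    def test_matches_flat_loop_oracle(self, rng):
        numC = rng.integers(0, 20, size=(10, 4))
        numT = rng.integers(0, 20, size=(10, 4))
        t = _track(np.arange(10) * 7, numC, numT)
        region = GenomicInterval("chr1", 5, 50)
        # naive accumulation
        tot_c = tot = 0
        for i, p in enumerate(t.pos):
            if 5 <= p < 50:
                for j in range(4):
                    tot_c += numC[i, j]
                    tot += numC[i, j] + numT[i, j]
        assert summative_methylation(t, region, "GLOM") == pytest.approx(
            tot_c / tot, abs=1e-12
        )

    def test_union_of_disjoint_regions_pools_counts(self, rng):
        numC = rng.integers(0, 20, size=(20, 2))
        numT = rng.integers(0, 20, size=(20, 2))
        t = _track(np.arange(20) * 10, numC, numT)
        a = GenomicInterval("chr1", 0, 50)
        b = GenomicInterval("chr1", 100, 150)
        pooled = pooled_mask_ml(t, [a, b], "GLOM")
        ca = numC[:5].sum() + numC[10:15].sum()
        tot = ca + numT[:5].sum() + numT[10:15].sum()
        assert pooled == pytest.approx(ca / tot, abs=1e-12)


class TestHyper:
    def test_equal_inputs_give_zero(self):
        assert hyper(0.5, 0.5, 0.001) == 0.0

    def test_hand_evaluation(self):
        assert hyper(0.8, 0.2, 0.001) == pytest.approx(
            math.log2(0.801 / 0.201), abs=1e-12
        )

    def test_antisymmetry_over_random_pairs(self, rng):
        for _ in range(100):
            a, b = rng.random(2)
            assert hyper(a, b) == pytest.approx(-hyper(b, a), abs=1e-12)

    def test_monotone_in_both_arguments(self):
        assert hyper(0.6, 0.3) > hyper(0.5, 0.3)
        assert hyper(0.5, 0.4) > hyper(0.5, 0.5)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            hyper(0.5, 0.5, beta=0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
        beta=st.floats(1e-6, 1.0, allow_nan=False),
    )
    def test_antisymmetry_property(self, a, b, beta):
        assert hyper(a, b, beta) == pytest.approx(-hyper(b, a, beta), abs=1e-9)


class TestDipCallingProperty:
    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.one_of(st.floats(0, 1), st.none()), min_size=1, max_size=80))
    def test_dips_match_oracle_and_never_touch(self, vals):
        ml = np.array([np.nan if v is None else v for v in vals], dtype=float)
        got = call_methyl_dips(ml, "chr1", window=10, max_ml=0.4, min_len_bp=50)
        assert got == _dip_oracle(ml, 10, 0.4, 50, "chr1")
        for a, b in zip(got, got[1:]):
            assert b.start > a.end and len(a) >= 50


class TestDifferentialMethylation:
    def test_identical_constant_groups(self):
        res = diff_region_methylation(
            np.array([[0.3, 0.3, 0.3]]), np.array([[0.3, 0.3, 0.3]])
        )
        assert res.loc[0, "t_stat"] == 0.0 and res.loc[0, "p_value"] == 1.0

    def test_separated_groups_reject(self, rng):
        a = 0.1 + rng.normal(0, 1e-3, size=(1, 4))
        b = 0.9 + rng.normal(0, 1e-3, size=(1, 4))
        res = diff_region_methylation(a, b)
        assert res.loc[0, "p_value"] < 1e-6

    def test_bonferroni_and_bh_apply_over_rows(self, rng):
        a = rng.normal(0.5, 0.05, size=(50, 4))
        b = rng.normal(0.5, 0.05, size=(50, 4))
        bh = diff_region_methylation(a, b, "BH")
        bonf = diff_region_methylation(a, b, "bonferroni")
        assert (bonf["p_adjusted"] >= bh["p_value"]).all()
        assert np.allclose(
            bonf["p_adjusted"], np.minimum(bonf["p_value"] * 50, 1.0)
        )

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError):
            diff_region_methylation(np.ones((1, 2)), np.ones((1, 2)), "holm")


def _dip_oracle(ml, window, max_ml, min_len, chrom):
    """Per-base sliding-scan brute force: expand bins to bases, scan runs."""
    low = np.repeat(np.isfinite(ml) & (ml <= max_ml), window)
    out, i = [], 0
    while i < len(low):
        if low[i]:
            j = i
            while j < len(low) and low[j]:
                j += 1
            if j - i >= min_len:
                out.append(GenomicInterval(chrom, i, j))
            i = j
        else:
            i += 1
    return out


class TestDipCalling:
    def test_hundred_bp_low_run_is_one_dip(self):
        ml = np.array([0.9] * 5 + [0.3] * 10 + [0.9] * 5)
        dips = call_methyl_dips(ml, "chr1", window=10)
        assert dips == [GenomicInterval("chr1", 50, 150)]

    def test_all_above_threshold_gives_no_dips(self):
        assert call_methyl_dips(np.full(50, 0.5), "chr1") == []

    def test_forty_bp_run_below_minimum_dropped(self):
        ml = np.array([0.9] * 5 + [0.3] * 4 + [0.9] * 5)
        assert call_methyl_dips(ml, "chr1", window=10) == []

    def test_nan_bins_break_runs(self):
        ml = np.array([0.3] * 4 + [np.nan] + [0.3] * 4)
        assert call_methyl_dips(ml, "chr1", window=10) == []

    def test_matches_sliding_scan_oracle_on_random_tracks(self, rng):
        for _ in range(100):
            ml = rng.random(rng.integers(5, 120))
            ml[rng.random(len(ml)) < 0.1] = np.nan
            got = call_methyl_dips(ml, "chrX", window=10, max_ml=0.4, min_len_bp=50)
            assert got == _dip_oracle(ml, 10, 0.4, 50, "chrX")
            for a, b in zip(got, got[1:]):  # dips maximal, never touching
                assert b.start > a.end

    def test_windowed_methylation_pools_counts_per_bin(self):
        t = _track([0, 5, 10], np.array([[1], [1], [8]]), np.array([[3], [3], [2]]))
        ml = windowed_methylation(t, "GLOM", "chr1", 20, window=10)
        assert ml[0] == pytest.approx(2 / 8)
        assert ml[1] == pytest.approx(8 / 10)


class TestConcordanceIndex:
    def test_perfect_concordance(self, rng):
        x = rng.permutation(20).astype(float)
        assert concordance_index(x, x) == 1.0

    def test_perfect_discordance(self, rng):
        x = rng.permutation(20).astype(float)
        assert concordance_index(x, -x) == 0.0

    def test_all_tied_observed_is_half(self):
        assert concordance_index(np.arange(5.0), np.ones(5)) == 0.5

    def test_matches_pair_counting_brute_force(self, rng):
        pred = rng.integers(0, 5, size=20).astype(float)
        obs = rng.integers(0, 5, size=20).astype(float)
        num = den = 0.0
        for i in range(20):
            for j in range(i + 1, 20):
                dp = np.sign(pred[i] - pred[j])
                do = np.sign(obs[i] - obs[j])
                num += 1.0 if dp * do > 0 else (0.5 if dp * do == 0 else 0.0)
                den += 1
        assert concordance_index(pred, obs) == pytest.approx(num / den, abs=1e-12)

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        from lifelines.utils import concordance_index as ll_ci

        pred = rng.normal(size=40)
        obs = rng.normal(size=40)
        assert concordance_index(pred, obs) == pytest.approx(
            ll_ci(obs, pred), abs=1e-12
        )


class TestBestFitModel:
    def test_noiseless_promoter_causal_recovers_all_with_c_one(self, rng):
        n = 40
        meth = pd.DataFrame(
            {
                "promoter": rng.normal(size=n),
                "cpg_island": rng.normal(scale=1e-3, size=n),
                "exon": rng.normal(scale=1e-3, size=n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        expr = -2.0 * meth["promoter"]
        res = best_fit_expression_model(meth, expr)
        assert (res.selected == "promoter").all()
        assert res.concordance == 1.0
        assert res.category_r["promoter"] == pytest.approx(-1.0)

    def test_independent_expression_gives_half_concordance(self, rng):
        # single usable category: predictions are a fixed linear map, so
        # independence of expression pins the c-index near one half
        n = 200
        meth = pd.DataFrame(
            {"promoter": rng.normal(size=n), "exon": np.zeros(n)},
            index=[f"g{i}" for i in range(n)],
        )
        expr = pd.Series(rng.normal(size=n), index=meth.index)
        res = best_fit_expression_model(meth, expr)
        assert abs(res.concordance - 0.5) < 0.08

    def test_per_gene_selection_biases_null_concordance_upward(self, rng):
        # with several candidate categories the per-gene residual
        # minimization is in-sample model selection: the null c-index sits
        # above one half, not at it
        n = 200
        meth = pd.DataFrame(
            {c: rng.normal(size=n) for c in ("promoter", "cpg_island", "exon")},
            index=[f"g{i}" for i in range(n)],
        )
        expr = pd.Series(rng.normal(size=n), index=meth.index)
        res = best_fit_expression_model(meth, expr)
        assert res.concordance >= 0.5

    def test_constant_column_excluded(self, rng):
        n = 30
        meth = pd.DataFrame(
            {"promoter": rng.normal(size=n), "exon": np.zeros(n)},
            index=[f"g{i}" for i in range(n)],
        )
        expr = -meth["promoter"]
        res = best_fit_expression_model(meth, expr)
        assert "exon" not in res.category_r

    def test_too_few_genes_rejected(self):
        meth = pd.DataFrame({"a": [0.1, 0.2], "b": [0.3, 0.4]})
        with pytest.raises(ValueError):
            best_fit_expression_model(meth, pd.Series([1.0, 2.0]))
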