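"""Cell-state analyses: pseudobulk, Wilcoxon DE, logistic-regression DA
against a statsmodels oracle, new-peak rules, gene open-chromatin AUC,
signature building, and deconvolution."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from epichrom.cellstate import (
    CellByFeatureMatrix,
    build_signature,
    da_peaks_lr,
    de_genes_wilcoxon,
    deconvolve,
    find_new_peaks,
    gene_open_chromatin_auc,
    pseudobulk,
    SignatureMatrix,
    _lr_statistic,
)
from epichrom.genome import GeneModel, GenomicInterval


def _mat(counts, labels, intervals=None):
    counts = np.asarray(counts)
    return CellByFeatureMatrix(
        sp.csr_matrix(counts),
        [f"f{i}" for i in range(counts.shape[0])],
        [f"c{j}" for j in range(counts.shape[1])],
        np.array(labels),
        intervals,
    )


class TestPseudobulk:
    def test_sum_and_fraction(self):
        m = _mat([[1, 0]], ["A", "A"])
        sums, fracs = pseudobulk(m)
        assert sums.loc["f0", "A"] == 1
        assert fracs.loc["f0", "A"] == 0.5

    def test_empty_type_rejected(self):
        m = _mat([[1, 0]], ["A", "A"])
        with pytest.raises(ValueError):
            pseudobulk(m, ["A", "B"])

    def test_unlabeled_cells_rejected(self):
        m = _mat([[1, 0]], ["A", ""])
        with pytest.raises(ValueError):
            pseudobulk(m)

    def test_matches_dense_loop_oracle(self, rng):
        counts = rng.integers(0, 4, size=(6, 20))
        labels = rng.choice(["A", "B"], 20)
        sums, fracs = pseudobulk(_mat(counts, labels))
        for t in ("A", "B"):
            idx = np.flatnonzero(labels == t)
            for i in range(6):
                assert sums.iloc[i][t] == counts[i, idx].sum()
                assert fracs.iloc[i][t] == pytest.approx(
                    (counts[i, idx] > 0).mean()
                )


class TestWilcoxonDE:
    def test_identical_groups_yield_no_de(self, rng):
        counts = np.tile(rng.integers(0, 6, size=(10, 1)), (1, 40))
        m = _mat(counts, ["A"] * 20 + ["B"] * 20)
        de = de_genes_wilcoxon(m, "A", "B")
        assert not de["significant"].any()

    def test_complete_separation_is_de_with_positive_fc(self):
        counts = np.zeros((2, 100), dtype=int)
        counts[0, :50] = 5  # expressed only in group A
        counts[1, :] = 3  # constant housekeeping so libraries are nonzero
        m = _mat(counts, ["A"] * 50 + ["B"] * 50)
        de = de_genes_wilcoxon(m, "A", "B")
        assert de.loc["f0", "significant"]
        assert de.loc["f0", "avg_log2FC"] > 0

    def test_group_swap_negates_log2fc_and_keeps_p(self, rng):
        counts = rng.poisson(2.0, size=(15, 80))
        counts[:3, :40] += rng.poisson(3.0, size=(3, 40))
        m = _mat(counts, ["A"] * 40 + ["B"] * 40)
        ab = de_genes_wilcoxon(m, "A", "B")
        ba = de_genes_wilcoxon(m, "B", "A")
        assert np.allclose(ab["avg_log2FC"], -ba["avg_log2FC"], atol=1e-12)
        assert np.allclose(ab["p"], ba["p"], atol=1e-12)

    def test_silent_genes_are_not_tested(self):
        counts = np.zeros((2, 20), dtype=int)
        counts[1] = 4
        m = _mat(counts, ["A"] * 10 + ["B"] * 10)
        de = de_genes_wilcoxon(m, "A", "B")
        assert "f0" not in de.index

    def test_fold_change_filter_applies_when_requested(self, rng):
        counts = rng.poisson(5.0, size=(8, 200))
        m = _mat(counts, ["A"] * 100 + ["B"] * 100)
        de = de_genes_wilcoxon(m, "A", "B", min_abs_log2fc=0.25)
        weak = de[np.abs(de["avg_log2FC"]) <= 0.25]
        assert not weak["significant"].any()

    def test_small_groups_rejected(self):
        m = _mat(np.ones((2, 4), dtype=int), ["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            de_genes_wilcoxon(m, "A", "B")


class TestLogisticRegressionDA:
    def test_lr_statistic_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm

        n_a, n_b = 70, 90
        for k_a, k_b in [(30, 30), (50, 10), (1, 60), (0, 45), (70, 3)]:
            got = _lr_statistic(np.array([k_a]), n_a, np.array([k_b]), n_b)[0]
            y = np.r_[np.ones(n_a), np.zeros(n_b)]
            x = np.r_[np.ones(k_a), np.zeros(n_a - k_a), np.ones(k_b), np.zeros(n_b - k_b)]
            full = sm.Logit(y, sm.add_constant(x)).fit(disp=0, method="newton")
            null = sm.Logit(y, np.ones((n_a + n_b, 1))).fit(disp=0)
            want = 2 * (full.llf - null.llf)
            assert got == pytest.approx(want, abs=1e-5)

    def test_equal_fractions_not_da(self, rng):
        acc = np.zeros((1, 200), dtype=int)
        acc[0, ::2] = 1  # same 50% rate in both groups
        m = _mat(acc, ["adaptive"] * 100 + ["reference"] * 100)
        (res,) = da_peaks_lr(m, "adaptive", "reference")
        assert not res.is_da and res.p > 0.5

    def test_strong_difference_is_da_toward_group_a(self, rng):
        acc = np.zeros((1, 400), dtype=int)
        acc[0, :180] = 1  # 90% of group A
        acc[0, 200:210] = 1  # 5% of group B
        m = _mat(acc, ["adaptive"] * 200 + ["reference"] * 200)
        (res,) = da_peaks_lr(m, "adaptive", "reference")
        assert res.is_da and res.avg_log2fc > 0

    def test_inaccessible_peaks_skipped(self):
        acc = np.zeros((2, 20), dtype=int)
        acc[1, :5] = 1
        m = _mat(acc, ["adaptive"] * 10 + ["reference"] * 10)
        res = da_peaks_lr(m, "adaptive", "reference")
        assert [r.peak for r in res] == ["f1"]


class TestNewPeaks:
    def _da(self, is_da, log2fc, frac_a, frac_b):
        from epichrom.cellstate import DAResult

        return DAResult("p", None, frac_a, frac_b, log2fc, 0.0, 0.0, is_da)

    def test_da_with_rare_comparator_is_new_peak(self):
        (r,) = find_new_peaks([self._da(True, 2.0, 0.5, 0.01)])
        assert r.is_new_peak and r.new_peak_owner == "adaptive"

    def test_comparator_at_five_percent_is_not_new(self):
        (r,) = find_new_peaks([self._da(True, 2.0, 0.5, 0.05)])
        assert not r.is_new_peak

    def test_non_da_never_new(self):
        (r,) = find_new_peaks([self._da(False, 2.0, 0.5, 0.0)])
        assert not r.is_new_peak

    def test_downward_peak_owned_by_reference(self):
        (r,) = find_new_peaks([self._da(True, -2.0, 0.0, 0.5)])
        assert r.is_new_peak and r.new_peak_owner == "reference"


class TestGeneOpenChromatinAUC:
    def _gene(self, tss=10000):
        return GeneModel(
            "g", "G", "+", GenomicInterval("chr1", tss, tss + 2000, "+"),
            [GenomicInterval("chr1", tss, tss + 2000, "+")],
        )

    def test_five_kb_cutoff(self):
        intervals = [
            GenomicInterval("chr1", 9900, 10100),  # overlaps TSS
            GenomicInterval("chr1", 15800, 16200),  # beyond 5 kb
        ]
        acc = np.array([[1, 1, 0, 0], [1, 1, 1, 1]])
        m = _mat(acc, ["A", "A", "B", "B"], intervals)
        auc = gene_open_chromatin_auc(m, self._gene(), 5000)
        assert auc["A"] == pytest.approx(1.0)
        assert auc["B"] == pytest.approx(0.0)

    def test_no_qualifying_peaks_gives_zero(self):
        m = _mat(np.ones((1, 4), dtype=int), ["A"] * 4, [GenomicInterval("chr2", 0, 10)])
        auc = gene_open_chromatin_auc(m, self._gene())
        assert (auc == 0).all()

    def test_matches_bruteforce_sum(self, rng):
        tss = 10000
        starts = rng.integers(3000, 18000, size=15)
        intervals = [GenomicInterval("chr1", int(s), int(s) + 300) for s in starts]
        acc = rng.integers(0, 2, size=(15, 30))
        labels = ["A"] * 15 + ["B"] * 15
        m = _mat(acc, labels, intervals)
        auc = gene_open_chromatin_auc(m, self._gene(), 5000)
        for t, cols in (("A", range(15)), ("B", range(15, 30))):
            want = 0.0
            for i, iv in enumerate(intervals):
                inside = iv.start >= tss - 5000 and iv.end <= tss + 5000
                if inside or iv.contains_point(tss):
                    want += np.mean([acc[i, c] > 0 for c in cols])
            assert auc[t] == pytest.approx(want)


class TestSignature:
    def _tables(self, n_per_type):
        return {
            t: pd.DataFrame(index=[f"{t}_g{i}" for i in range(n)])
            for t, n in n_per_type.items()
        }

    def test_ten_percent_of_200_degs_yields_20_markers(self):
        tables = self._tables({"A": 200, "B": 200})
        genes = {g for t in tables.values() for g in t.index}
        profiles = pd.DataFrame(1.0, index=sorted(genes), columns=["A", "B"])
        sig = build_signature(tables, genes, profiles)
        assert len(sig.markers["A"]) == 20

    def test_type_with_150_degs_is_excluded(self):
        tables = self._tables({"A": 200, "B": 150})
        genes = {g for t in tables.values() for g in t.index}
        profiles = pd.DataFrame(1.0, index=sorted(genes), columns=["A", "B"])
        sig = build_signature(tables, genes, profiles)
        assert "B" not in sig.cell_types

    def test_configured_type_removed(self):
        tables = self._tables({"A": 200, "B": 200})
        genes = {g for t in tables.values() for g in t.index}
        profiles = pd.DataFrame(1.0, index=sorted(genes), columns=["A", "B"])
        sig = build_signature(tables, genes, profiles, drop_types=("B",))
        assert sig.cell_types == ["A"]

    def test_all_types_filtered_is_an_error(self):
        tables = self._tables({"A": 50})
        with pytest.raises(ValueError):
            build_signature(tables, set(), pd.DataFrame())

    def test_markers_without_promoter_peaks_dropped(self):
        tables = self._tables({"A": 300})
        with_peaks = set(list(tables["A"].index)[:25])
        profiles = pd.DataFrame(1.0, index=sorted(tables["A"].index), columns=["A"])
        sig = build_signature(tables, with_peaks, profiles)
        # top 30 intersected with the 25 promoter-peak genes
        assert set(sig.markers["A"]) <= with_peaks


class TestDeconvolution:
    def _sig(self, rng, n_types=3, n_markers=60):
        profiles = pd.DataFrame(
            rng.uniform(0.1, 5.0, size=(n_markers, n_types)),
            index=[f"g{i}" for i in range(n_markers)],
            columns=[f"T{k}" for k in range(n_types)],
        )
        return SignatureMatrix(profiles)

    def test_exact_two_way_mixture(self, rng):
        sig = self._sig(rng, 2)
        bulk = 0.5 * sig.profiles["T0"] + 0.5 * sig.profiles["T1"]
        est = deconvolve(sig, bulk)
        assert np.allclose(est, [0.5, 0.5], atol=1e-9)

    def test_pure_type(self, rng):
        sig = self._sig(rng)
        est = deconvolve(sig, sig.profiles["T0"])
        assert est["T0"] == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_tolerance(self, rng):
        sig = self._sig(rng)
        w = np.array([0.6, 0.3, 0.1])
        for _ in range(20):
            bulk = pd.Series(
                sig.profiles.to_numpy() @ w * (1 + rng.normal(0, 0.05, 60)),
                index=sig.profiles.index,
            )
            est = deconvolve(sig, bulk)
            assert np.abs(est.to_numpy() - w).max() < 0.05

    def test_proportions_on_simplex(self, rng):
        sig = self._sig(rng)
        bulk = pd.Series(rng.uniform(0, 3, 60), index=sig.profiles.index)
        est = deconvolve(sig, bulk)
        assert est.sum() == pytest.approx(1.0) and (est >= 0).all()

    def test_missing_markers_rejected(self, rng):
        sig = self._sig(rng)
        with pytest.raises(ValueError):
            deconvolve(sig, sig.profiles["T0"].iloc[:10])
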