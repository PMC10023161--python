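"""Peak-calling statistics and the filter cascade against first-principles oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipforge.annotation import Annotation, TranscriptModel
from clipforge.binning import BinCountMatrix, make_bins
from clipforge.peaks import (
    EnrichedRegion,
    PeakCallingError,
    SignificantBins,
    bh_adjust,
    call_significant_bins,
    gene_upper_quartile_filter,
    igg_transcript_filter,
    input_cpm_filter,
    merge_significant_bins,
    peak_enrichment_test,
    select_enriched_regions,
)
from clipforge.ztnb import ZtnbFit, sample_ztnb


def bh_stepup_oracle(p):
    """Direct step-up definition of BH-adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_stay_equal(self):
        adj = bh_adjust([0.04] * 7)
        assert np.unique(adj).size == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(PeakCallingError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 1000))
            p = rng.uniform(size=n)
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)


def yates_chi2_oracle(a, b, c, d):
    """Yates-corrected chi-square from the textbook formula."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den
    return stats.chi2.sf(chi2, df=1)


class TestEnrichmentTest:
    def test_equal_proportions_fe_one(self):
        log2fe, p, _ = peak_enrichment_test(10, 10**6, 10, 10**6)
        assert log2fe == pytest.approx(0.0)

    def test_fisher_branch_small_counts(self):
        log2fe, p, branch = peak_enrichment_test(3, 1000, 3, 1000)
        assert branch == "fisher"
        assert p == pytest.approx(1.0)

    def test_chi2_branch_matches_first_principles(self):
        log2fe, p, branch = peak_enrichment_test(400, 10**6, 25, 10**6)
        assert branch == "chi2"
        assert log2fe == pytest.approx(4.0)
        assert p == pytest.approx(
            yates_chi2_oracle(400, 10**6 - 400, 25, 10**6 - 25), rel=1e-9
        )

    def test_zero_input_pseudocount_keeps_fe_finite(self):
        log2fe, p, _ = peak_enrichment_test(50, 10**4, 0, 10**4)
        assert math.isfinite(log2fe)
        assert log2fe == pytest.approx(math.log2(50))

    def test_zero_totals_rejected(self):
        with pytest.raises(PeakCallingError):
            peak_enrichment_test(0, 0, 1, 10)

    def test_branch_agreement_on_large_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            a, c = rng.integers(50, 500, 2)
            n1, n2 = rng.integers(5000, 20000, 2)
            table = [[int(a), int(n1 - a)], [int(c), int(n2 - c)]]
            p_chi = stats.chi2_contingency(table, correction=True)[1]
            p_f = stats.fisher_exact(table)[1]
            assert abs(p_chi - p_f) <= 0.02


def null_matrix(n_bins=400, seed=0, mu=5.0, size=2.0):
    rng = np.random.default_rng(seed)
    grid = make_bins({"chr1": n_bins * 200}, 200)
    mat = BinCountMatrix(grid)
    col = sample_ztnb(rng, mu, size, n_bins)
    mat.add_sample("IP1", col, int(col.sum()))
    return mat, col


class TestCallSignificantBins:
    def test_extreme_outlier_is_called(self):
        mat, col = null_matrix(seed=3)
        col = col.copy()
        col[17] = int(col.mean() * 100)
        mat.counts[:, 0] = col
        sig = call_significant_bins(mat, "IP1")
        assert 17 in sig.indices

    def test_zero_bins_never_significant(self):
        mat, col = null_matrix(seed=4)
        mat.counts[:100, 0] = 0
        sig = call_significant_bins(mat, "IP1")
        assert (sig.indices >= 100).all()

    def test_all_zero_column_rejected(self):
        grid = make_bins({"chr1": 2000}, 200)
        mat = BinCountMatrix(grid)
        mat.add_sample("IP1", np.zeros(10, dtype=int), 0)
        with pytest.raises(PeakCallingError):
            call_significant_bins(mat, "IP1")


class TestQuartileFilter:
    def _setup(self, ip_fpm_value):
        grid = make_bins({"chr1": 800}, 200)
        mat = BinCountMatrix(grid)
        mat.add_sample("Input", np.array([0, 0, 0, 100]), 10**6)
        ip = np.zeros(4, dtype=int)
        ip[1] = ip_fpm_value
        mat.add_sample("IP1", ip, 10**6)
        gene = TranscriptModel(
            gene_id="g1", transcript_id="g1.t", chrom="chr1", strand="+",
            biotype="protein_coding", exons=[(0, 800)], cds=[(100, 700)],
        )
        sig = SignificantBins(
            sample="IP1", indices=np.array([1]), pvalues=np.array([1e-6]),
            padj=np.array([1e-5]),
            fit=ZtnbFit(1, 1, 0, True), alpha=0.05,
        )
        return mat, Annotation([gene]), sig

    def test_bin_below_q3_dropped(self):
        mat, ann, sig = self._setup(ip_fpm_value=10)
        out = gene_upper_quartile_filter(sig, mat, ann)  # Q3 = 25
        assert out.indices.size == 0

    def test_bin_at_q3_kept(self):
        mat, ann, sig = self._setup(ip_fpm_value=25)
        out = gene_upper_quartile_filter(sig, mat, ann)
        assert out.indices.tolist() == [1]

    def test_intergenic_bin_kept(self):
        mat, ann, sig = self._setup(ip_fpm_value=1)
        empty_ann = Annotation(
            [TranscriptModel(
                gene_id="far", transcript_id="far.t", chrom="chr2",
                strand="+", biotype="protein_coding", exons=[(0, 100)],
            )]
        )
        out = gene_upper_quartile_filter(sig, mat, empty_ann)
        assert out.indices.tolist() == [1]

    def test_input_comparator_mode(self):
        mat, ann, sig = self._setup(ip_fpm_value=1000)
        out = gene_upper_quartile_filter(sig, mat, ann, comparator="input")
        # the bin's own Input FPM (0) is below Q3=25: dropped in this mode
        assert out.indices.size == 0


class TestMerge:
    def test_adjacent_bins_from_different_samples_merge(self):
        grid = make_bins({"chr1": 2000}, 200)
        out = merge_significant_bins([np.array([0]), np.array([1])], grid)
        assert out == [("chr1", 0, 400)]

    def test_gap_splits(self):
        grid = make_bins({"chr1": 2000}, 200)
        out = merge_significant_bins([np.array([0, 3])], grid)
        assert out == [("chr1", 0, 200), ("chr1", 600, 800)]

    def test_empty(self):
        grid = make_bins({"chr1": 2000}, 200)
        assert merge_significant_bins([np.array([], dtype=int)], grid) == []

    def test_chromosome_boundary_not_merged(self):
        grid = make_bins({"chr1": 400, "chr2": 400}, 200)
        out = merge_significant_bins([np.array([1, 2])], grid)
        assert out == [("chr1", 200, 400), ("chr2", 0, 200)]


def region(log2fe1, log2fe2, fdr1, fdr2, **kw):
    base = dict(
        chrom="chr1", start=0, end=200, summit=100, counts={},
        log2fe_ip1=log2fe1, log2fe_ip2=log2fe2, p_ip1=0.0, p_ip2=0.0,
        fdr_ip1=fdr1, fdr_ip2=fdr2,
    )
    base.update(kw)
    return EnrichedRegion(**base)


class TestSelection:
    def test_threshold_rule(self):
        r = region(2.5, 2.1, 0.01, 0.03)
        assert select_enriched_regions([r]) == [r]

    def test_both_replicates_required(self):
        assert select_enriched_regions([region(2.5, 1.9, 0.01, 0.01)]) == []

    def test_strict_fdr_boundary(self):
        assert select_enriched_regions([region(3.0, 3.0, 0.05, 0.01)]) == []


class TestIggFilter:
    def test_igg_region_elsewhere_in_transcript_removes_peak(self, toy_annotation):
        r = region(3, 3, 0.01, 0.01, chrom="chr1", start=1100, end=1300)
        n = igg_transcript_filter([r], [("chr1", 3000, 3200)], toy_annotation)
        assert n == 1 and r.igg_filtered and not r.selected

    def test_intergenic_igg_region_removes_nothing(self, toy_annotation):
        r = region(3, 3, 0.01, 0.01, chrom="chr1", start=1100, end=1300)
        r.passes_thresholds = True
        n = igg_transcript_filter([r], [("chr1", 9500, 9600)], toy_annotation)
        assert n == 0 and r.selected

    def test_empty_igg_set_is_identity(self, toy_annotation):
        r = region(3, 3, 0.01, 0.01, chrom="chr1", start=1100, end=1300)
        assert igg_transcript_filter([r], [], toy_annotation) == 0


class TestCpmFilter:
    def cpm_table(self, inp, ip1, ip2):
        return pd.DataFrame(
            {"gene_id": ["gA"], "Input_cpm": [inp], "IP1_cpm": [ip1],
             "IP2_cpm": [ip2]}
        )

    def test_kept_when_only_one_ip_below(self):
        r = region(3, 3, 0.01, 0.01, host_gene="gA")
        assert input_cpm_filter([r], self.cpm_table(10, 8, 12)) == 0

    def test_removed_when_input_exceeds_both(self):
        r = region(3, 3, 0.01, 0.01, host_gene="gA")
        assert input_cpm_filter([r], self.cpm_table(10, 8, 9)) == 1
        assert r.cpm_filtered

    def test_equality_kept(self):
        r = region(3, 3, 0.01, 0.01, host_gene="gA")
        assert input_cpm_filter([r], self.cpm_table(10, 10, 10)) == 0

    def test_missing_gene_kept_with_warning(self):
        r = region(3, 3, 0.01, 0.01, host_gene="unknown")
        assert input_cpm_filter([r], self.cpm_table(10, 1, 1)) == 0


class TestEndToEndRecovery:
    def test_selected_regions_recover_strong_planted_peaks(self, wt_run):
        from clipforge.simulate import evaluate_recovery

        res = evaluate_recovery(
            [r.interval() for r in wt_run["selected"]], wt_run["truth"], 8.0
        )
        assert res["sensitivity"] >= 0.9
        assert res["precision"] >= 0.9

    def test_monotonicity_of_fold_enrichment(self, wt_run):
        """Higher planted E gives higher measured log2FE on the same truth."""
        from clipforge.peaks import RegionCounter

        counter = RegionCounter(wt_run["fragments"])
        truth = wt_run["truth"]
        by_level = {}
        for p in truth.wt_active_peaks(1.0):
            fe, _, _ = peak_enrichment_test(
                counter.count("IP1", p.chrom, p.start, p.end),
                counter.totals["IP1"],
                counter.count("Input", p.chrom, p.start, p.end),
                counter.totals["Input"],
            )
            by_level.setdefault(p.enrichment, []).append(fe)
        levels = sorted(by_level)
        means = [np.mean(by_level[l]) for l in levels]
        assert all(a < b for a, b in zip(means, means[1:]))
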