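"""Beta values, region aggregation, and the binned chi-square test."""

import numpy as np
import pandas as pd
import pytest

from gbm_tfnet.genomic import GenomicInterval
from gbm_tfnet.methylation import (
    beta_from_counts,
    bin_betas,
    binned_chi2_test,
    c_rich_regions,
    meth_expr_correlation,
    motif_windows,
    read_methylation_table,
    region_median_beta,
    write_methylation_table,
    RegionMethylation,
)
from gbm_tfnet.motifs import MotifHit


def meth_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample", "methylated", "total"])


class TestBetaFromCounts:
    def test_simple_ratio(self):
        df = meth_frame([("chr1", 10, "+", "s1", 7, 10)])
        assert beta_from_counts(df)["beta"].iloc[0] == pytest.approx(0.7)

    def test_low_coverage_dropped(self):
        df = meth_frame([("chr1", 10, "+", "s1", 5, 9)])
        assert beta_from_counts(df).empty

    def test_zero_methylated_gives_zero_beta(self):
        df = meth_frame([("chr1", 10, "+", "s1", 0, 10)])
        assert beta_from_counts(df)["beta"].iloc[0] == 0.0

    def test_methylated_above_total_rejected(self):
        df = meth_frame([("chr1", 10, "+", "s1", 11, 10)])
        with pytest.raises(ValueError):
            beta_from_counts(df)

    def test_raising_cutoff_never_retains_more(self):
        rng = np.random.default_rng(0)
        rows = [
            ("chr1", int(p), "+", "s1", int(m), int(t))
            for p, t in zip(rng.integers(1, 1000, 200), rng.integers(0, 40, 200))
            for m in [rng.integers(0, t + 1)]
        ]
        df = meth_frame(rows)
        sizes = [len(beta_from_counts(df, min_coverage=c)) for c in (0, 5, 10, 20)]
        assert sizes == sorted(sizes, reverse=True)


class TestRegionMedian:
    def test_median_of_three(self):
        df = meth_frame(
            [("chr1", p, "+", "s1", m, 10) for p, m in [(5, 1), (6, 2), (7, 9)]]
        )
        betas = beta_from_counts(df)
        [rm] = region_median_beta(betas, [GenomicInterval("chr1", 0, 100)])
        assert rm.medians["s1"] == pytest.approx(0.2)

    def test_single_cytosine(self):
        betas = beta_from_counts(meth_frame([("chr1", 5, "+", "s1", 4, 10)]))
        [rm] = region_median_beta(betas, [GenomicInterval("chr1", 0, 100)])
        assert rm.medians["s1"] == pytest.approx(0.4)

    def test_matches_numpy_median_on_random_case(self):
        rng = np.random.default_rng(1)
        rows = [
            ("chr1", int(p), "+", "s1", int(rng.integers(0, 21)), 20)
            for p in rng.choice(np.arange(200), size=50, replace=False)
        ]
        betas = beta_from_counts(meth_frame(rows))
        [rm] = region_median_beta(betas, [GenomicInterval("chr1", 0, 200)])
        assert rm.medians["s1"] == pytest.approx(float(np.median(betas["beta"])))

    def test_region_without_coverage_omitted(self):
        betas = beta_from_counts(meth_frame([("chr1", 5, "+", "s1", 4, 10)]))
        out = region_median_beta(betas, [GenomicInterval("chr2", 0, 100)])
        assert out == []


class TestMotifWindows:
    def _hit(self, start, end):
        return MotifHit(GenomicInterval("chr1", start, end, "+", "TF"), "TF", 5.0, 1e-5)

    def test_ten_bp_motif_gives_fifty_bp_window(self):
        [w] = motif_windows([self._hit(100, 110)], flank_bp=20)
        assert (w.start, w.end, w.width) == (80, 130, 50)

    def test_clipped_at_chromosome_start(self):
        [w] = motif_windows([self._hit(5, 15)], flank_bp=20)
        assert (w.start, w.end) == (0, 35)

    def test_width_formula_unclipped(self):
        rng = np.random.default_rng(2)
        hits = [self._hit(int(s), int(s) + 11) for s in rng.integers(100, 10000, 30)]
        for w in motif_windows(hits, flank_bp=20):
            assert w.width == 11 + 40


class TestBinning:
    def test_boundaries_closed_right(self):
        counts = bin_betas(np.array([0.0, 0.2, 0.20000001, 0.6, 0.60000001, 1.0]))
        assert counts.tolist() == [2, 2, 2]  # 0.2 is hypo, 0.6 is medium


def region_betas(by_group, chrom="chr1", start=0, end=100):
    return [(GenomicInterval(chrom, start, end), by_group)]


class TestBinnedChi2:
    def test_identical_groups_statistic_zero_p_one(self):
        betas = np.array([0.1] * 10 + [0.5] * 10 + [0.9] * 10)
        [res] = binned_chi2_test(region_betas({"A": betas, "B": betas.copy()}))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_table_after_empty_bin_dropping(self):
        """[[10,0,0],[0,0,10]]: middle bin empty, 2x2 chi-square = 20."""
        a = np.full(10, 0.1)  # all hypo
        b = np.full(10, 0.9)  # all hyper
        [res] = binned_chi2_test(region_betas({"A": a, "B": b}))
        assert res.testable
        assert res.statistic == pytest.approx(20.0)

    def test_single_occupied_bin_untestable(self):
        a = np.full(5, 0.1)
        b = np.full(5, 0.15)
        [res] = binned_chi2_test(region_betas({"A": a, "B": b}))
        assert not res.testable and res.p_value is None

    def test_group_without_cytosines_untestable(self):
        [res] = binned_chi2_test(
            region_betas({"A": np.array([0.1, 0.9]), "B": np.array([])})
        )
        assert not res.testable

    def test_invariant_under_group_label_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
        [r1] = binned_chi2_test(region_betas({"A": a, "B": b}))
        [r2] = binned_chi2_test(region_betas({"A": b, "B": a}))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_fdr_only_over_testable_regions(self):
        rng = np.random.default_rng(4)
        regions = []
        for i in range(5):
            regions.append(
                (
                    GenomicInterval("chr1", i * 100, i * 100 + 50),
                    {"A": rng.uniform(0, 1, 30), "B": rng.uniform(0, 1, 30)},
                )
            )
        regions.append((GenomicInterval("chr1", 900, 950), {"A": np.full(5, 0.1), "B": np.full(5, 0.1)}))
        results = binned_chi2_test(regions)
        testable = [r for r in results if r.testable]
        assert all(r.adj_p is not None for r in testable)
        assert all(r.adj_p is None for r in results if not r.testable)


class TestCRichRegions:
    def test_at_only_window_empty(self):
        seq = {"chr1": "ATATATATATATATAT"}
        assert c_rich_regions(seq, [GenomicInterval("chr1", 0, 16)]) == []

    def test_all_c_window_spanned_by_one_region(self):
        seq = {"chr1": "CCCCCC"}
        [r] = c_rich_regions(seq, [GenomicInterval("chr1", 0, 6)], 0.8, 4)
        assert (r.start, r.end) == (0, 6)

    def test_g_counts_as_cytosine_on_other_strand(self):
        seq = {"chr1": "ATAT" + "GGGGGG" + "ATAT"}
        [r] = c_rich_regions(seq, [GenomicInterval("chr1", 0, 14)], 1.0, 4)
        assert (r.start, r.end) == (4, 10)

    def test_output_regions_satisfy_density_length_and_maximality(self):
        rng = np.random.default_rng(5)
        seq = {"chr1": "".join(rng.choice(list("ACGT"), size=60))}
        windows = [GenomicInterval("chr1", 0, 60)]
        found = c_rich_regions(seq, windows, 0.6, 5)
        s = seq["chr1"]

        def density(i, j):
            return sum(c in "CG" for c in s[i:j]) / (j - i)

        for r in found:
            assert r.width >= 5 and density(r.start, r.end) >= 0.6
        # maximality: no strictly larger qualifying interval contains a result
        for r in found:
            for a in range(0, r.start + 1):
                for b in range(r.end, len(s) + 1):
                    if (b - a) > r.width:
                        assert density(a, b) < 0.6, ((a, b), (r.start, r.end))


class TestMethExprCorrelation:
    def _medians(self, values):
        region = GenomicInterval("chr1", 0, 100, ".", "geneA")
        return [RegionMethylation(region, {}, values)]

    def _expr(self, values):
        return pd.DataFrame([values], index=["geneA"], columns=list(values))

    def test_perfect_positive(self):
        med = {f"s{i}": v for i, v in enumerate([0.1, 0.2, 0.3, 0.4])}
        expr = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4]], index=["geneA"], columns=list(med)
        )
        df = meth_expr_correlation(self._medians(med), expr)
        assert df["r"].iloc[0] == pytest.approx(1.0)

    def test_perfect_negative(self):
        med = {f"s{i}": v for i, v in enumerate([0.1, 0.2, 0.3, 0.4])}
        expr = pd.DataFrame(
            [[-0.1 + 1, -0.2 + 1, -0.3 + 1, -0.4 + 1]], index=["geneA"], columns=list(med)
        )
        df = meth_expr_correlation(self._medians(med), expr)
        assert df["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([0.1, 0.3, 0.2, 0.8, 0.6])
        y = np.array([2.0, 1.0, 3.0, 9.0, 4.0])
        med = {f"s{i}": float(v) for i, v in enumerate(x)}
        expr = pd.DataFrame([y], index=["geneA"], columns=list(med))
        df = meth_expr_correlation(self._medians(med), expr)
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert df["r"].iloc[0] == pytest.approx(expected)

    def test_fewer_than_three_samples_flagged(self):
        med = {"s0": 0.1, "s1": 0.2}
        expr = pd.DataFrame([[1.0, 2.0]], index=["geneA"], columns=["s0", "s1"])
        df = meth_expr_correlation(self._medians(med), expr)
        assert not df["testable"].iloc[0]

    def test_zero_variance_flagged(self):
        med = {f"s{i}": 0.5 for i in range(5)}
        expr = pd.DataFrame([range(5)], index=["geneA"], columns=list(med))
        df = meth_expr_correlation(self._medians(med), expr)
        assert not df["testable"].iloc[0]


class TestTableIO:
    def test_one_based_round_trip(self, tmp_path):
        df = meth_frame([("chr1", 9, "+", "s1", 3, 12), ("chr2", 0, "-", "s2", 0, 15)])
        path = tmp_path / "meth.tsv"
        write_methylation_table(df, path)
        raw = path.read_text().splitlines()
        assert raw[0].split("\t")[1] == "10"  # written 1-based
        back = read_methylation_table(path)
        pd.testing.assert_frame_equal(back, df)

    def test_invalid_counts_rejected(self, tmp_path):
        path = tmp_path / "meth.tsv"
        path.write_text("chr1\t10\t+\ts1\t9\t5\n")
        with pytest.raises(ValueError):
            read_methylation_table(path)
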