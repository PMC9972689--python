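"""PWM scoring, exact p-values, genome scanning, and the hit filters."""

import itertools

import numpy as np
import pytest

from gbm_tfnet.genomic import GenomicInterval
from gbm_tfnet.motifs import (
    BASES,
    MotifHit,
    MotifModel,
    ScoreDistribution,
    count_unambiguous_bases,
    log_odds_score,
    observed_background,
    open_chromatin_filter,
    read_meme,
    reproducible_hits,
    reverse_complement,
    scan_genome,
    score_pvalue,
    write_meme,
)

UNIFORM = [0.25, 0.25, 0.25, 0.25]


def consensus_matrix(consensus: str, major=0.91, minor=0.03) -> np.ndarray:
    m = np.full((len(consensus), 4), minor)
    for j, b in enumerate(consensus):
        m[j, BASES.index(b)] = major
    return m


class TestLogOdds:
    def test_uniform_matrix_scores_zero(self):
        mat = np.full((1, 4), 0.25)
        for b in BASES:
            assert log_odds_score(mat, b, UNIFORM) == pytest.approx(0.0)

    def test_twofold_enrichment_scores_one_bit(self):
        mat = np.array([[0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]])
        assert log_odds_score(mat, "A", UNIFORM) == pytest.approx(1.0)

    def test_matches_per_position_sum_on_all_windows(self):
        rng = np.random.default_rng(11)
        mat = rng.dirichlet(np.ones(4), size=5)
        bg = rng.dirichlet(np.ones(4) * 5)
        for window in itertools.product(BASES, repeat=5):
            w = "".join(window)
            expected = sum(
                np.log2(mat[j, BASES.index(b)] / bg[BASES.index(b)])
                for j, b in enumerate(w)
            )
            assert log_odds_score(mat, w, bg) == pytest.approx(expected)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            log_odds_score(np.full((3, 4), 0.25), "AC", UNIFORM)


class TestScorePvalue:
    def test_top_score_closed_form(self):
        rng = np.random.default_rng(5)
        mat = rng.dirichlet(np.ones(4) * 0.5, size=6)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        dist = ScoreDistribution(mat, bg)
        top = int(dist.int_matrix.max(axis=1).sum())
        expected = float(np.prod([bg[np.argmax(row)] for row in dist.int_matrix]))
        assert dist.pvalue_int(top) == pytest.approx(expected, rel=1e-12)

    def test_below_minimum_score_gives_one(self):
        mat = np.full((4, 4), 0.25)
        assert score_pvalue(mat, UNIFORM, -100.0) == 1.0

    @pytest.mark.parametrize("L", [4, 6, 8])
    def test_dp_matches_exhaustive_enumeration(self, L):
        """The DP tail must equal the probability-weighted tail over all 4^L
        windows, on the same discretized score grid."""
        rng = np.random.default_rng(100 + L)
        mat = rng.dirichlet(np.ones(4), size=L)
        bg = rng.dirichlet(np.ones(4) * 8)
        dist = ScoreDistribution(mat, bg)
        scores, weights = [], []
        for window in itertools.product(range(4), repeat=L):
            scores.append(sum(int(dist.int_matrix[j, b]) for j, b in enumerate(window)))
            weights.append(float(np.prod([bg[b] for b in window])))
        scores, weights = np.array(scores), np.array(weights)
        for s in np.unique(scores):
            empirical = weights[scores >= s].sum()
            assert dist.pvalue_int(int(s)) == pytest.approx(empirical, abs=1e-9)

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(2)
        mat = rng.dirichlet(np.ones(4), size=7)
        dist = ScoreDistribution(mat, UNIFORM)
        grid = range(dist.min_total - 5, dist.max_total + 5)
        pvals = [dist.pvalue_int(s) for s in grid]
        assert all(p1 >= p2 for p1, p2 in zip(pvals, pvals[1:]))


class TestScanGenome:
    def test_planted_consensus_found_once_on_plus_strand(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("AT"), size=500))  # AT background: no chance hits
        seq = seq[:200] + "TGAGTCA" + seq[207:]
        motif = MotifModel("AP1", consensus_matrix("TGAGTCA"))
        hits = scan_genome({"chr1": seq}, [motif], background=UNIFORM)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].interval.start, plus[0].interval.end) == (200, 207)

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(BASES), size=400))
        seq = seq[:100] + "TGAGTCA" + seq[107:]
        motif = MotifModel("AP1", consensus_matrix("TGAGTCA"))
        fwd = scan_genome({"c": seq}, [motif], background=UNIFORM)
        rev = scan_genome({"c": reverse_complement(seq)}, [motif], background=UNIFORM)
        n = len(seq)
        mirrored = {
            (n - h.interval.end, n - h.interval.start, "-" if h.strand == "+" else "+")
            for h in fwd
        }
        got = {(h.interval.start, h.interval.end, h.strand) for h in rev}
        assert got == mirrored

    def test_mitochondrial_chromosome_excluded(self):
        motif = MotifModel("AP1", consensus_matrix("TGAGTCA"))
        genome = {"chrM": "AA" + "TGAGTCA" + "TT" * 20, "chr1": "AT" * 100}
        hits = scan_genome(genome, [motif], background=UNIFORM)
        assert all(h.interval.chrom != "chrM" for h in hits)

    def test_windows_with_n_skipped(self):
        motif = MotifModel("AP1", consensus_matrix("TGAGTCA"))
        genome = {"chr1": "TT" * 30 + "TGANTCA" + "TT" * 30}
        assert scan_genome(genome, [motif], background=UNIFORM) == []

    def test_empty_genome_rejected(self):
        motif = MotifModel("AP1", consensus_matrix("TGAGTCA"))
        with pytest.raises(ValueError, match="empty"):
            scan_genome({"chrM": "ACGT" * 10}, [motif])

    def test_planted_recall_is_complete_on_synthetic_genome(self, small_config, small_genome):
        hits = scan_genome(small_genome.sequences, small_genome.motifs)
        keys = {h.key() for h in hits}
        assert small_genome.truth.planted_hits, "generator planted nothing"
        missing = [
            (tf, iv)
            for tf, iv in small_genome.truth.planted_hits
            if (iv.chrom, iv.start, iv.end, iv.strand, tf) not in keys
        ]
        assert missing == []


def _hit(chrom, start, tf="TF1", strand="+", p=0.001, sample=None):
    return MotifHit(
        GenomicInterval(chrom, start, start + 7, strand, tf), tf, 10.0, p, source_sample=sample
    )


class TestOpenChromatinFilter:
    def test_hit_outside_peaks_removed(self):
        peaks = [GenomicInterval("chr1", 1000, 1200)]
        assert open_chromatin_filter([_hit("chr1", 10)], peaks) == []

    def test_single_hit_identity_adjustment(self):
        peaks = [GenomicInterval("chr1", 0, 100)]
        [kept] = open_chromatin_filter([_hit("chr1", 10, p=0.04)], peaks)
        assert kept.adj_p == pytest.approx(0.04)

    def test_by_adjustment_hand_case(self):
        """p = (0.001, 0.01, 0.04), m=3: BY = BH * (1 + 1/2 + 1/3)."""
        peaks = [GenomicInterval("chr1", 0, 1000)]
        hits = [
            _hit("chr1", 10, p=0.001),
            _hit("chr1", 100, p=0.01),
            _hit("chr1", 200, p=0.04),
        ]
        kept = open_chromatin_filter(hits, peaks, adj_alpha=0.05)
        adj = sorted(h.adj_p for h in kept)
        assert adj == pytest.approx([0.0055, 0.0275], rel=1e-9)  # 0.0733 removed

    def test_commutes_with_reproducibility_filter(self):
        peaks = [GenomicInterval("chr1", 0, 500)]
        shared = [_hit("chr1", 10, p=0.001), _hit("chr1", 700, p=0.001)]
        extra = [_hit("chr1", 50, tf="TF2", p=0.002)]
        by_sample = {"s1": shared + extra, "s2": shared}
        oc_then_rep = reproducible_hits(
            {s: open_chromatin_filter(h, peaks) for s, h in by_sample.items()}, ["s1", "s2"]
        )
        rep_then_oc = open_chromatin_filter(
            reproducible_hits(by_sample, ["s1", "s2"]), peaks
        )
        assert {h.key() for h in oc_then_rep} == {h.key() for h in rep_then_oc}


class TestReproducibleHits:
    def test_hit_in_both_samples_kept(self):
        by_sample = {"a": [_hit("chr1", 10)], "b": [_hit("chr1", 10)]}
        assert len(reproducible_hits(by_sample, ["a", "b"])) == 1

    def test_hit_in_one_sample_dropped(self):
        by_sample = {"a": [_hit("chr1", 10)], "b": []}
        assert reproducible_hits(by_sample, ["a", "b"]) == []

    def test_opposite_strand_not_reproducible(self):
        by_sample = {
            "a": [_hit("chr1", 10, strand="+")],
            "b": [_hit("chr1", 10, strand="-")],
        }
        assert reproducible_hits(by_sample, ["a", "b"]) == []

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            reproducible_hits({"a": [], "b": []}, ["a", "zzz"])


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        models = [
            MotifModel(f"TF{i}_0_A", rng.dirichlet(np.ones(4), size=8)) for i in range(3)
        ]
        path = tmp_path / "motifs.meme"
        write_meme(models, path)
        back = read_meme(path)
        assert [m.tf_name for m in back] == [m.tf_name for m in models]
        for a, b in zip(models, back):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=2e-6)


class TestConsensusParsing:
    def test_ap1_consensus_has_one_unambiguous_cytosine(self):
        assert count_unambiguous_bases("dvTGAGTCAYh", "C") == 1

    def test_ambiguity_codes_do_not_count(self):
        # Y matches C or T, h matches A/C/T: neither is an unambiguous C
        assert count_unambiguous_bases("YCh", "C") == 1

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            count_unambiguous_bases("ACX", "C")


def test_observed_background_is_complement_symmetric():
    bg = observed_background({"c": "AACCCGTT" * 10})
    assert bg[0] == pytest.approx(bg[3])
    assert bg[1] == pytest.approx(bg[2])
    assert bg.sum() == pytest.approx(1.0)
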