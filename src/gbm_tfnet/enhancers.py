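"""Active-enhancer definition and hypergeometric motif enrichment.

Enhancers are H3K27ac peaks away from transcription start sites: peaks found
in only one tumor sample are discarded (recurrence filter), and peaks
overlapping any TSS-proximal window are removed.  Per-TF enrichment inside
enhancers is an upper-tail hypergeometric test on the 2x2 sampling scheme
(this TF vs all TFs) x (in enhancers vs genome-wide), BH-corrected across
TFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genomic import (
    GenomicInterval,
    TSSRecord,
    build_trees,
    merge_intervals,
    overlaps_any,
    subtract,
)
from .motifs import MotifHit


def define_enhancers(
    h3k27ac_peaks: Sequence[GenomicInterval],
    tss_records: Sequence[TSSRecord],
    tss_exclusion_bp: int = 3000,
) -> list[GenomicInterval]:
    """H3K27ac peaks with no overlap of any TSS +/- tss_exclusion_bp window."""
    exclusion = [
        GenomicInterval(
            t.chrom, max(0, t.tss - tss_exclusion_bp), t.tss + tss_exclusion_bp
        )
        for t in tss_records
    ]
    return subtract(h3k27ac_peaks, exclusion)


def recurrence_filter(
    peaks_by_sample: Mapping[str, Sequence[GenomicInterval]],
    min_samples: int = 2,
) -> list[GenomicInterval]:
    """Merged peak regions supported by >= min_samples distinct samples.

    All per-sample peaks are pooled and merged single-linkage on >= 1 bp
    overlap; a merged region is retained iff its member peaks come from at
    least `min_samples` distinct samples.
    """
    if len(peaks_by_sample) < 2:
        raise ValueError("need peaks from >= 2 samples")
    pooled = [iv for ivs in peaks_by_sample.values() for iv in ivs]
    if not pooled:
        return []
    merged = merge_intervals(pooled)
    trees = build_trees(merged)
    support: dict[GenomicInterval, set[str]] = {m: set() for m in merged}
    for sample, ivs in peaks_by_sample.items():
        for iv in ivs:
            tree = trees.get(iv.chrom)
            if tree is None:
                continue
            for node in tree.overlap(iv.start, iv.end):
                support[node.data].add(sample)
    return sorted(m for m, samples in support.items() if len(samples) >= min_samples)


@dataclass
class EnrichmentResult:
    tf_name: str
    k_enh: int  # this TF's occurrences in enhancers
    K_gen: int  # this TF's occurrences genome-wide
    n_enh_total: int  # all TFs' occurrences in enhancers
    N_total: int  # all TFs' occurrences genome-wide
    p_value: float
    adj_p: float | None = None


def hypergeometric_enrichment(
    counts_enh: Mapping[str, int],
    counts_genome: Mapping[str, int],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric P(X >= k_enh) per TF, BH-adjusted across TFs.

    X ~ Hypergeometric(population N_total, successes K_gen, draws n_enh_total):
    drawing the enhancer-resident motif occurrences from the genome-wide pool.
    """
    N_total = int(sum(counts_genome.values()))
    n_enh_total = int(sum(counts_enh.values()))
    results = []
    for tf in sorted(counts_genome):
        K = int(counts_genome[tf])
        k = int(counts_enh.get(tf, 0))
        if k > K:
            raise ValueError(f"{tf}: enhancer count {k} exceeds genome-wide count {K}")
        if k > n_enh_total:
            raise ValueError(f"{tf}: enhancer count {k} exceeds enhancer total")
        p = float(hypergeom.sf(k - 1, N_total, K, n_enh_total))
        results.append(EnrichmentResult(tf, k, K, n_enh_total, N_total, min(p, 1.0)))
    if results:
        _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.adj_p = float(a)
    return results


def hit_counts(
    hits: Sequence[MotifHit], enhancers: Sequence[GenomicInterval]
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-TF occurrence counts inside enhancers and genome-wide."""
    flags = overlaps_any([h.interval for h in hits], enhancers)
    counts_genome: dict[str, int] = {}
    counts_enh: dict[str, int] = {}
    for h, inside in zip(hits, flags):
        counts_genome[h.tf_name] = counts_genome.get(h.tf_name, 0) + 1
        if inside:
            counts_enh[h.tf_name] = counts_enh.get(h.tf_name, 0) + 1
    return counts_enh, counts_genome


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view mirroring an occurrences-in-enhancers enrichment table."""
    return pd.DataFrame(
        {
            "tf_name": [r.tf_name for r in results],
            "occurrences_in_enhancers": [r.k_enh for r in results],
            "occurrences_in_genome": [r.K_gen for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
        }
    )
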