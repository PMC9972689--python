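"""Beta-value methylation analysis: coverage filtering, region aggregation,
and the binned chi-square differential-methylation test.

A cytosine's beta value is methylated/total reads; only cytosines covered by
at least 10 reads are trusted.  Regions (promoters, or motif hits extended by
+/- 20 bp flanks) are compared between groups by binning the pooled
cytosine-level betas into hypo- [0, 0.2], medium- (0.2, 0.6] and
hyper-methylated (0.6, 1.0] classes and applying a classical chi-square test
to the groups x bins table, with BH FDR across regions (significant if
adjusted p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, pearsonr
from statsmodels.stats.multitest import multipletests

from .genomic import GenomicInterval, build_trees
from .motifs import MotifHit

#: right edges of the hypo / medium bins; betas are binned closed-right
BIN_EDGES = (0.2, 0.6)
BIN_LABELS = ("hypo", "medium", "hyper")

METH_COLUMNS = ["chrom", "pos", "strand", "sample", "methylated", "total"]


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read the per-cytosine table (tab-separated, 1-based positions).

    Columns: chrom, pos (1-based), strand, sample, methylated, total.
    Positions are converted to the internal 0-based convention.
    """
    df = pd.read_csv(path, sep="\t", names=METH_COLUMNS, dtype={"chrom": str, "sample": str})
    if (df["methylated"] > df["total"]).any():
        raise ValueError("methylated read count exceeds total")
    if (df["pos"] < 1).any():
        raise ValueError("1-based positions must be >= 1")
    df["pos"] = df["pos"] - 1
    return df


def write_methylation_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["pos"] = out["pos"] + 1  # back to the 1-based file dialect
    out[METH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def beta_from_counts(table: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Per-cytosine beta values; cytosines under min_coverage are dropped."""
    if (table["methylated"] > table["total"]).any():
        raise ValueError("methylated read count exceeds total")
    kept = table[table["total"] >= min_coverage].copy()
    kept["beta"] = kept["methylated"] / kept["total"]
    return kept


@dataclass
class RegionMethylation:
    region: GenomicInterval
    betas: dict[str, np.ndarray]  # sample -> covered-cytosine betas
    medians: dict[str, float]  # sample -> median beta


def assign_regions(
    betas: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> dict[GenomicInterval, pd.DataFrame]:
    """Split the beta table by containing region (a cytosine can hit several)."""
    trees = build_trees(regions)
    assignments: dict[GenomicInterval, list[int]] = {r: [] for r in regions}
    chroms = betas["chrom"].to_numpy()
    poss = betas["pos"].to_numpy()
    for i in range(len(betas)):
        tree = trees.get(chroms[i])
        if tree is None:
            continue
        for node in tree.overlap(poss[i], poss[i] + 1):
            assignments[node.data].append(i)
    return {r: betas.iloc[idx] for r, idx in assignments.items() if idx}


def region_median_beta(
    betas: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> list[RegionMethylation]:
    """Per region and per sample, the median beta over covered cytosines.

    Regions with no covered cytosine in a sample simply omit that sample.
    """
    out = []
    for region, sub in assign_regions(betas, regions).items():
        per_sample = {
            s: g["beta"].to_numpy() for s, g in sub.groupby("sample", sort=True)
        }
        medians = {s: float(np.median(v)) for s, v in per_sample.items()}
        out.append(RegionMethylation(region, per_sample, medians))
    return out


def motif_windows(hits: Sequence[MotifHit], flank_bp: int = 20) -> list[GenomicInterval]:
    """Each motif hit extended flank_bp on both sides (clipped at 0).

    A 10 bp motif with 20 bp flanks gives the canonical 50 bp window.
    """
    out = []
    for h in hits:
        iv = h.interval
        out.append(
            GenomicInterval(
                iv.chrom, max(0, iv.start - flank_bp), iv.end + flank_bp, iv.strand, iv.label
            )
        )
    return out


def bin_betas(betas: np.ndarray) -> np.ndarray:
    """Counts per methylation bin; edges are closed on the right, so a beta
    of exactly 0.2 is hypo- and 0.6 medium-methylated."""
    idx = np.digitize(betas, BIN_EDGES, right=True)
    return np.bincount(idx, minlength=3)


@dataclass
class BinnedChi2Result:
    region: GenomicInterval
    statistic: float | None
    p_value: float | None
    adj_p: float | None
    testable: bool
    bin_counts: dict[str, np.ndarray]  # group -> 3 bin counts


def binned_chi2_test(
    region_betas: Sequence[tuple[GenomicInterval, Mapping[str, np.ndarray]]],
    alpha: float = 0.05,
) -> list[BinnedChi2Result]:
    """Chi-square on the groups x bins table per region, BH across regions.

    Input: per region, the pooled cytosine-level betas of each group.  Bins
    with zero total count are dropped before computing the classical
    (uncorrected) chi-square statistic; regions left with fewer than two
    non-empty bins, or with any group contributing no cytosines, are flagged
    untestable and excluded from the FDR family.
    """
    results: list[BinnedChi2Result] = []
    for region, by_group in region_betas:
        groups = sorted(by_group)
        if len(groups) < 2:
            raise ValueError(f"region {region}: need >= 2 groups")
        counts = {g: bin_betas(np.asarray(by_group[g], float)) for g in groups}
        table = np.array([counts[g] for g in groups])
        keep_cols = table.sum(axis=0) > 0
        trimmed = table[:, keep_cols]
        if trimmed.shape[1] < 2 or (trimmed.sum(axis=1) == 0).any():
            results.append(BinnedChi2Result(region, None, None, None, False, counts))
            continue
        stat, p, _, _ = chi2_contingency(trimmed, correction=False)
        results.append(BinnedChi2Result(region, float(stat), float(p), None, True, counts))
    testable = [r for r in results if r.testable]
    if testable:
        _, adj, _, _ = multipletests([r.p_value for r in testable], method="fdr_bh")
        for r, a in zip(testable, adj):
            r.adj_p = float(a)
    return results


def chi2_frame(results: Sequence[BinnedChi2Result]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.region.chrom for r in results],
            "start": [r.region.start for r in results],
            "end": [r.region.end for r in results],
            "label": [r.region.label for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
            "testable": [r.testable for r in results],
        }
    )


def c_rich_regions(
    sequence: Mapping[str, str],
    windows: Sequence[GenomicInterval],
    min_c_density: float = 0.5,
    min_len: int = 5,
) -> list[GenomicInterval]:
    """Maximal sub-intervals of each window rich in cytosines.

    Cytosine density counts a C on either strand, i.e. C or G letters on the
    reference.  A sub-interval qualifies when its density >= min_c_density
    and its length >= min_len; only sub-intervals not contained in a longer
    qualifying one are returned.  Windows are short (tens of bp), so the
    search is a direct enumeration.
    """
    out = []
    for w in windows:
        seq = sequence[w.chrom][w.start : w.end].upper()
        is_c = np.array([c in "CG" for c in seq], dtype=int)
        cum = np.concatenate([[0], np.cumsum(is_c)])
        n = len(seq)
        candidates = []
        for i in range(n):
            for j in range(i + min_len, n + 1):
                if (cum[j] - cum[i]) / (j - i) >= min_c_density:
                    candidates.append((i, j))
        maximal = [
            (i, j)
            for (i, j) in candidates
            if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in candidates)
        ]
        for i, j in sorted(maximal):
            out.append(GenomicInterval(w.chrom, w.start + i, w.start + j, ".", w.label))
    return out


def meth_expr_correlation(
    region_medians: Sequence[RegionMethylation],
    expression: "pd.DataFrame | None" = None,
    gene_of_region: Mapping[GenomicInterval, str] | None = None,
    expr_matrix=None,
) -> pd.DataFrame:
    """Pearson correlation of promoter median beta vs expression, per gene.

    `expression` is a genes x samples DataFrame (or pass an ExpressionMatrix
    via `expr_matrix`).  Regions map to genes through `gene_of_region`, or by
    their interval label when omitted.  Genes with < 3 matched samples or
    zero variance on either side are flagged and excluded from the BH family.
    """
    if expr_matrix is not None:
        expression = pd.DataFrame(
            expr_matrix.values, index=expr_matrix.genes, columns=expr_matrix.samples
        )
    if expression is None:
        raise ValueError("expression data required")
    rows = []
    for rm in region_medians:
        gene = (
            gene_of_region[rm.region]
            if gene_of_region is not None
            else rm.region.label
        )
        if gene not in expression.index:
            continue
        samples = [s for s in rm.medians if s in expression.columns]
        if len(samples) < 3:
            rows.append((gene, np.nan, np.nan, len(samples), False))
            continue
        x = np.array([rm.medians[s] for s in samples])
        y = expression.loc[gene, samples].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((gene, np.nan, np.nan, len(samples), False))
            continue
        r, p = pearsonr(x, y)
        rows.append((gene, float(r), float(p), len(samples), True))
    df = pd.DataFrame(rows, columns=["gene", "r", "p_value", "n", "testable"])
    df["adj_p"] = np.nan
    ok = df["testable"]
    if ok.any():
        _, adj, _, _ = multipletests(df.loc[ok, "p_value"], method="fdr_bh")
        df.loc[ok, "adj_p"] = adj
    return df
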