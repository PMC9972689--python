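"""Grade-specific gene selection by repeated balanced subsampling.

With hundreds of patients per tumor grade, a single differential-expression
test is dominated by the largest group and by outliers.  The procedure here
instead draws many balanced subsamples (by default 200 draws of 20 vs 20),
runs a per-gene two-sample t-test on log2(FPKM + 1) within each draw,
BH-adjusts within the draw, and summarizes each gene by the *mean* of its
draw-wise adjusted p-values.  Direction comes from a simple log2 fold change
of group means; a gene is called overexpressed in a group when its mean
adjusted p is below alpha and the fold change points toward that group.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Named, order-independent child RNG stream derived from one seed.

    Every stochastic component draws from its own named stream so adding a
    component never perturbs the draws of another.
    """
    ints = [seed & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table (FPKM-like) with group labels."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample lists")
        if (self.values < 0).any():
            raise ValueError("negative abundances")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def submatrix(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = [self.samples.index(s) for s in sample_ids]
        return self.values[:, idx]

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.genes.index(gene_id)]

    def write(self, path: str | Path, labels_path: str | Path | None = None) -> None:
        pd.DataFrame(self.values, index=self.genes, columns=self.samples).to_csv(
            path, sep="\t", index_label="gene_id"
        )
        if labels_path is not None:
            pd.DataFrame(
                {"sample": self.samples, "group": [self.group_of[s] for s in self.samples]}
            ).to_csv(labels_path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, labels_path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", dtype=str)
        group_of = dict(zip(labels["sample"], labels["group"]))
        return cls(list(df.index), list(df.columns), df.to_numpy(float), group_of)


def _ttest_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance (Student) two-sample t-test per row; zero variance -> p=1."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~np.isfinite(t)] = 1.0  # zero within-draw variance
    return p


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~np.isfinite(t)] = 1.0
    return p


def subsampled_de(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    n_iter: int = 200,
    n_per_group: int = 20,
    seed: int = 0,
    welch: bool = False,
) -> pd.Series:
    """Mean of draw-wise BH-adjusted t-test p-values, per gene.

    Each of `n_iter` draws samples `n_per_group` sample ids uniformly without
    replacement from each group (ids sorted canonically first, so input file
    order is irrelevant), tests each gene on log2(value + 1), and adjusts
    p-values across genes within the draw.
    """
    ids_a = sorted(expr.samples_in(group_a))
    ids_b = sorted(expr.samples_in(group_b))
    if len(ids_a) < n_per_group or len(ids_b) < n_per_group:
        raise ValueError(
            f"groups have {len(ids_a)}/{len(ids_b)} samples; need {n_per_group} each"
        )
    log_vals = np.log2(expr.values + 1.0)
    col_of = {s: i for i, s in enumerate(expr.samples)}
    test = _welch_pvalues if welch else _ttest_pvalues
    acc = np.zeros(len(expr.genes))
    for it in range(n_iter):
        rng = substream(seed, "subsample", it)
        pick_a = rng.choice(len(ids_a), size=n_per_group, replace=False)
        pick_b = rng.choice(len(ids_b), size=n_per_group, replace=False)
        cols_a = [col_of[ids_a[i]] for i in pick_a]
        cols_b = [col_of[ids_b[i]] for i in pick_b]
        p = test(log_vals[:, cols_a], log_vals[:, cols_b])
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        acc += adj
    return pd.Series(acc / n_iter, index=expr.genes, name="mean_adj_p")


def direction_logfc(expr: ExpressionMatrix, group_a: str, group_b: str) -> pd.Series:
    """log2((mean_a + 1) / (mean_b + 1)) over all samples of each group."""
    a = expr.submatrix(expr.samples_in(group_a)).mean(axis=1)
    b = expr.submatrix(expr.samples_in(group_b)).mean(axis=1)
    return pd.Series(np.log2((a + 1.0) / (b + 1.0)), index=expr.genes, name="logfc")


@dataclass
class DESelectionResult:
    table: pd.DataFrame  # gene, mean_adj_p, logfc, selected_for
    group_a: str
    group_b: str

    def selected(self, group: str) -> set[str]:
        return set(self.table.index[self.table["selected_for"] == group])


def select_overexpressed(
    mean_adj_p: pd.Series,
    logfc: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
    whitelist: set[str] | None = None,
) -> DESelectionResult:
    """Assign each significant gene to the group it is overexpressed in.

    mean_adj_p < alpha and logfc > 0 -> group_a; logfc < 0 -> group_b;
    logfc == 0 stays unassigned.  An optional whitelist (e.g. protein-coding
    gene ids) restricts eligibility.
    """
    if not mean_adj_p.index.equals(logfc.index):
        logfc = logfc.reindex(mean_adj_p.index)
    selected = np.full(len(mean_adj_p), "", dtype=object)
    sig = mean_adj_p.to_numpy() < alpha
    if whitelist is not None:
        sig &= np.array([g in whitelist for g in mean_adj_p.index])
    lf = logfc.to_numpy()
    selected[sig & (lf > 0)] = group_a
    selected[sig & (lf < 0)] = group_b
    table = pd.DataFrame(
        {"mean_adj_p": mean_adj_p, "logfc": logfc, "selected_for": selected}
    )
    table.index.name = "gene"
    return DESelectionResult(table, group_a, group_b)
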