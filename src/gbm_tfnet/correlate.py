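"""TF-to-target correlation layer of the regulatory network.

Each putative target gene is scored by the Pearson correlation between the
TF's abundance (its mRNA, or a matched protein measurement) and the target's
expression across samples; two-sided p-values come from the exact
t-transform with n-2 degrees of freedom and are BH-adjusted per TF across
its targets.  A positive, significant correlation supports the TF-target
edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deg import ExpressionMatrix


@dataclass
class CorrelationRecord:
    source: str
    target: str
    r: float
    p_value: float
    adj_p: float | None
    n: int
    testable: bool = True


def _correlate_vector(
    source_name: str,
    source_values: np.ndarray,
    expr: ExpressionMatrix,
    sample_ids: Sequence[str],
    targets: Sequence[str],
) -> list[CorrelationRecord]:
    if len(sample_ids) < 3:
        raise ValueError(f"need >= 3 matched samples, got {len(sample_ids)}")
    target_matrix = expr.submatrix(sample_ids)
    row_of = {g: i for i, g in enumerate(expr.genes)}
    records = []
    for tgt in targets:
        if tgt not in row_of:
            raise KeyError(f"target gene {tgt!r} not in expression matrix")
        y = target_matrix[row_of[tgt]]
        n = len(sample_ids)
        if np.std(source_values) == 0 or np.std(y) == 0:
            records.append(CorrelationRecord(source_name, tgt, np.nan, np.nan, None, n, False))
            continue
        r = float(np.corrcoef(source_values, y)[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        records.append(CorrelationRecord(source_name, tgt, r, p, None, n, True))
    testable = [rec for rec in records if rec.testable]
    if testable:
        _, adj, _, _ = multipletests([rec.p_value for rec in testable], method="fdr_bh")
        for rec, a in zip(testable, adj):
            rec.adj_p = float(a)
    return records


def tf_target_correlation(
    expr: ExpressionMatrix, tf_gene: str, targets: Sequence[str]
) -> list[CorrelationRecord]:
    """Pearson r between the TF's mRNA and each target, across all samples."""
    if tf_gene not in expr.genes:
        raise KeyError(f"TF gene {tf_gene!r} not in expression matrix")
    return _correlate_vector(
        tf_gene, expr.gene_row(tf_gene), expr, list(expr.samples), list(targets)
    )


def protein_target_correlation(
    protein_levels: Mapping[str, float],
    expr: ExpressionMatrix,
    targets: Sequence[str],
    source_name: str = "protein",
) -> list[CorrelationRecord]:
    """Same contract with a protein measurement as the source vector.

    Only samples present in both the protein table and the expression matrix
    are used; fewer than 3 matched samples is an error.
    """
    matched = [s for s in expr.samples if s in protein_levels]
    if len(matched) < 3:
        raise ValueError(f"only {len(matched)} matched samples; need >= 3")
    values = np.array([protein_levels[s] for s in matched], float)
    return _correlate_vector(source_name, values, expr, matched, list(targets))


def correlation_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [r.source for r in records],
            "target": [r.target for r in records],
            "r": [r.r for r in records],
            "p_value": [r.p_value for r in records],
            "adj_p": [r.adj_p for r in records],
            "n": [r.n for r in records],
            "testable": [r.testable for r in records],
        }
    )
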