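"""Promoter TFBS tabulation: generic vs grade-specific motifs, family rollup.

A TF predicted to bind a promoter counts once per (TF, gene) regardless of
how many individual motif hits fall inside — "one TFBS per promoter".  A TF
is *generic* when it hits promoters of overexpressed genes of both grades,
and *grade-specific* when only one.  Raw counts are made comparable across
gene sets of different size by dividing by the number of differentially
expressed genes in the set (occurrences per DE gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genomic import GenomicInterval, intersect
from .motifs import MotifHit

GENERIC = "generic"


def promoter_hit_table(
    hits: Sequence[MotifHit], promoters: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Unique (tf_name, gene_id) pairs with >= 1 hit inside the gene's promoter.

    Promoter intervals carry their gene id in `label`.  A hit spanning the
    promoters of two genes yields one row per gene.
    """
    hit_ivs = [h.interval for h in hits]
    tf_of = {h.interval: h.tf_name for h in hits}
    pairs = set()
    for hit_iv, prom in intersect(hit_ivs, promoters):
        if not prom.label:
            raise ValueError(f"promoter {prom} has no gene id label")
        pairs.add((tf_of[hit_iv], prom.label))
    df = pd.DataFrame(sorted(pairs), columns=["tf_name", "gene_id"])
    return df


@dataclass
class TFBSClassification:
    tf_name: str
    status: str  # "generic" | "specific_to_<group>"
    raw_a: int
    raw_b: int
    norm_a: float | None = None
    norm_b: float | None = None


def classify_tfbs(
    table: pd.DataFrame,
    set_a: set[str],
    set_b: set[str],
    label_a: str = "A",
    label_b: str = "B",
) -> list[TFBSClassification]:
    """Per-TF promoter counts in each gene set, with generic/specific status.

    TFs hitting no gene of either set are absent from the output.
    """
    if set_a & set_b:
        raise ValueError("gene sets must be disjoint")
    out = []
    for tf, sub in table.groupby("tf_name", sort=True):
        genes = set(sub["gene_id"])
        raw_a, raw_b = len(genes & set_a), len(genes & set_b)
        if raw_a == 0 and raw_b == 0:
            continue
        if raw_a > 0 and raw_b > 0:
            status = GENERIC
        elif raw_a > 0:
            status = f"specific_to_{label_a}"
        else:
            status = f"specific_to_{label_b}"
        out.append(TFBSClassification(tf, status, raw_a, raw_b))
    return out


def normalized_occurrences(
    classification: Sequence[TFBSClassification], n_de_a: int, n_de_b: int
) -> list[TFBSClassification]:
    """Scale raw per-set counts to occurrences per DE gene (raw / |set|)."""
    if n_de_a <= 0 or n_de_b <= 0:
        raise ValueError("DE gene counts must be positive")
    return [
        TFBSClassification(
            c.tf_name, c.status, c.raw_a, c.raw_b, c.raw_a / n_de_a, c.raw_b / n_de_b
        )
        for c in classification
    ]


def family_rollup(
    classification: Sequence[TFBSClassification],
    family_of: Mapping[str, str],
) -> pd.DataFrame:
    """TF-family presence per gene set; families unique to one set flagged.

    A family is present in a set iff any member TF has raw_count > 0 there.
    """
    rows: dict[str, dict] = {}
    for c in classification:
        fam = family_of.get(c.tf_name, "")
        if not fam:
            warnings.warn(f"TF {c.tf_name} has no family annotation; using UNKNOWN")
            fam = "UNKNOWN"
        row = rows.setdefault(fam, {"in_a": False, "in_b": False})
        row["in_a"] |= c.raw_a > 0
        row["in_b"] |= c.raw_b > 0
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "family"
    df["unique_to"] = ""
    df.loc[df["in_a"] & ~df["in_b"], "unique_to"] = "A"
    df.loc[df["in_b"] & ~df["in_a"], "unique_to"] = "B"
    return df


def classification_frame(classification: Sequence[TFBSClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tf_name": [c.tf_name for c in classification],
            "status": [c.status for c in classification],
            "raw_a": [c.raw_a for c in classification],
            "raw_b": [c.raw_b for c in classification],
            "norm_a": [c.norm_a for c in classification],
            "norm_b": [c.norm_b for c in classification],
        }
    )
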