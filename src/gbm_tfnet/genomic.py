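"""Genomic coordinate primitives and flat-file I/O.

All coordinates are 0-based half-open (BED convention) internally.  Inputs
that use 1-based positions (the per-cytosine methylation table) are converted
at the parser boundary, never downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED / annotation lines; names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic span, 0-based half-open.

    The unit of peaks, promoters, enhancers and motif hits alike.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple:
        """Coordinate identity (chrom, start, end, strand), ignoring label."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class TSSRecord:
    """One gene's transcription start site (single TSS per gene)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"TSS for {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"TSS for {self.gene_id}: negative coordinate")


def build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index intervals per chromosome for overlap queries."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    return dict(trees)


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (x in a, y in b) overlapping by >= 1 bp (half-open semantics)."""
    trees = build_trees(b)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for x in a:
        tree = trees.get(x.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(x.start, x.end)):
            pairs.append((x, hit.data))
    return pairs


def overlaps_any(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[bool]:
    """Per query interval, whether it overlaps >= 1 bp of any subject interval."""
    trees = build_trees(subject)
    out = []
    for x in query:
        tree = trees.get(x.chrom)
        out.append(bool(tree is not None and tree.overlap(x.start, x.end)))
    return out


def make_promoters(
    tss_records: Sequence[TSSRecord], upstream_bp: int, downstream_bp: int
) -> list[GenomicInterval]:
    """Strand-aware promoter window around each TSS, clipped at 0.

    On '+': [tss - upstream, tss + downstream); on '-' the window mirrors so
    that "upstream" points away from the gene body.  Symmetric windows (e.g.
    +/-1.5 kb) are therefore strand-invariant; asymmetric ones (2 kb/500 bp)
    are not.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("upstream_bp and downstream_bp must be >= 0")
    if upstream_bp == 0 and downstream_bp == 0:
        raise ValueError("promoter window cannot be empty")
    out = []
    for rec in tss_records:
        if rec.strand == "+":
            start, end = rec.tss - upstream_bp, rec.tss + downstream_bp
        else:
            start, end = rec.tss - downstream_bp, rec.tss + upstream_bp
        start = max(0, start)
        if end <= start:  # fully clipped away
            continue
        out.append(
            GenomicInterval(rec.chrom, start, end, rec.strand, label=rec.gene_id)
        )
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Single-linkage merge of intervals overlapping by >= 1 bp, per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def subtract(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intervals of `a` that overlap no interval of `b` (whole-interval removal)."""
    keep = overlaps_any(a, b)
    return [iv for iv, hit in zip(a, keep) if not hit]


# ---------------------------------------------------------------------------
# I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-BED6 (tab-separated, 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns: {line!r}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate: {line!r}") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid coordinates [{start},{end}): {line!r}"
                )
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise BedParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            out.append(GenomicInterval(chrom, start, end, strand, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Tab-separated gene annotation: gene_id, chrom, tss (0-based), strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns: {line!r}")
            out.append(TSSRecord(fields[0], fields[1], int(fields[2]), fields[3]))
    return out


def write_tss_table(records: Iterable[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
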