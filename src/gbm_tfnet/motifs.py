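"""PWM motif models, exact p-value scanning, and occupancy-style filtering.

The scanner mirrors the classic FIMO contract: log2 odds scores against a
0-order background, an exact score distribution obtained by dynamic
programming on a discretized score grid, hits on both strands at p < 1e-4,
and the mitochondrial chromosome excluded.  Downstream filters keep only
hits inside open-chromatin peaks whose Benjamini-Yekutieli-adjusted p-value
is below 0.05, and only hits reproduced at identical coordinates in every
required sample (e.g. two cell lines).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from statsmodels.stats.multitest import multipletests

from .genomic import GenomicInterval, build_trees

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes -> set of bases matched.  Lower-case codes (used by
#: HOCOMOCO consensus strings for low-information positions) map identically.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

MITO_NAMES = frozenset({"chrm", "chrmt", "m", "mt"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_unambiguous_bases(consensus: str, base: str) -> int:
    """Count consensus positions that unambiguously specify `base`.

    E.g. the AP-1 consensus "dvTGAGTCAYh" contains exactly one position that
    can only be a cytosine.
    """
    base = base.upper()
    n = 0
    for letter in consensus:
        matched = IUPAC_CODES.get(letter.upper())
        if matched is None:
            raise ValueError(f"not an IUPAC nucleotide code: {letter!r}")
        if matched == frozenset(base):
            n += 1
    return n


@dataclass(frozen=True)
class MotifModel:
    """A TF's position probability matrix plus metadata.

    `matrix` holds per-position probabilities over ACGT (shape L x 4).  A
    pseudocount is added per cell and rows renormalized before any scoring,
    so zero entries never produce -inf log-odds.
    """

    tf_name: str
    matrix: np.ndarray
    family: str = ""
    consensus: str = ""
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"motif {self.tf_name}: matrix must be L x 4 with L >= 1")
        if (m < 0).any():
            raise ValueError(f"motif {self.tf_name}: negative probabilities")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def probabilities(self) -> np.ndarray:
        """Row-normalized probabilities after pseudocount regularization."""
        m = self.matrix + self.pseudocount
        return m / m.sum(axis=1, keepdims=True)

    def information_bits(self, background: Sequence[float] | None = None) -> float:
        """Total information content (bits) relative to the background."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = self.probabilities()
        return float((p * np.log2(p / bg)).sum())


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence on a genome."""

    interval: GenomicInterval
    tf_name: str
    score: float
    p_value: float
    adj_p: float | None = None
    source_sample: str | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand

    def key(self) -> tuple:
        """Coordinate identity used by the reproducibility filter."""
        return (*self.interval.key(), self.tf_name)


def log_odds_score(
    matrix: np.ndarray | MotifModel,
    window: str,
    background: Sequence[float],
) -> float:
    """Sum over positions of log2(P_motif(base) / P_background(base)), in bits.

    Raises on windows whose length differs from the motif length or that
    contain non-ACGT letters (the scanner simply skips such windows).
    """
    probs = matrix.probabilities() if isinstance(matrix, MotifModel) else np.asarray(matrix, float)
    if len(window) != probs.shape[0]:
        raise ValueError(f"window length {len(window)} != motif length {probs.shape[0]}")
    bg = np.asarray(background, float)
    total = 0.0
    for j, letter in enumerate(window.upper()):
        idx = _BASE_INDEX.get(letter)
        if idx is None:
            raise ValueError(f"non-ACGT letter {letter!r} in window")
        total += float(np.log2(probs[j, idx] / bg[idx]))
    return total


class ScoreDistribution:
    """Exact distribution of PWM scores under a 0-order background.

    Scores are discretized onto a fixed grid (`eps` bits per unit); the full
    distribution of the integer total score is then computed by dynamic
    programming over positions.  The discretization error (<= L*eps/2 bits)
    is far below the granularity relevant at the p < 1e-4 threshold.
    """

    def __init__(
        self,
        matrix: np.ndarray | MotifModel,
        background: Sequence[float],
        eps: float = 1e-3,
    ) -> None:
        probs = matrix.probabilities() if isinstance(matrix, MotifModel) else np.asarray(matrix, float)
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
        self.eps = float(eps)
        self.background = bg
        lom = np.log2(probs / bg)
        self.int_matrix = np.rint(lom / eps).astype(np.int64)  # L x 4
        row_min = self.int_matrix.min(axis=1)
        self.min_total = int(row_min.sum())
        shifted = self.int_matrix - row_min[:, None]
        span = int(shifted.max(axis=1).sum())
        dist = np.zeros(span + 1)
        dist[0] = 1.0
        used = 0
        for j in range(shifted.shape[0]):
            new = np.zeros(span + 1)
            for b in range(4):
                s = int(shifted[j, b])
                new[s : s + used + 1] += dist[: used + 1] * bg[b]
            dist = new
            used += int(shifted[j].max())
        # tail[k] = P(total integer score >= min_total + k)
        self.tail = np.cumsum(dist[::-1])[::-1]
        self.max_total = self.min_total + span

    def pvalue_int(self, int_score: int) -> float:
        """P(random background window scores >= int_score), on the grid."""
        k = int_score - self.min_total
        if k <= 0:
            return 1.0
        if k > self.max_total - self.min_total:
            return float(self.tail[-1]) if int_score <= self.max_total else 0.0
        return float(self.tail[k])

    def pvalue(self, score_bits: float) -> float:
        """P-value of a score in bits; the score is snapped to the grid."""
        return self.pvalue_int(int(np.rint(score_bits / self.eps)))

    def threshold_int(self, p_threshold: float) -> int:
        """Smallest integer score whose tail probability is < p_threshold."""
        below = np.nonzero(self.tail < p_threshold)[0]
        if below.size == 0:
            return self.max_total + 1  # no window can pass
        return self.min_total + int(below[0])


def score_pvalue(
    matrix: np.ndarray | MotifModel,
    background: Sequence[float],
    score_bits: float,
    eps: float = 1e-3,
) -> float:
    """One-shot exact p-value for a log-odds score (see ScoreDistribution)."""
    return ScoreDistribution(matrix, background, eps=eps).pvalue(score_bits)


def observed_background(genome: Mapping[str, str]) -> np.ndarray:
    """Strand-symmetrized mononucleotide composition of the given sequences."""
    counts = np.zeros(4)
    for seq in genome.values():
        codes = _encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("empty genome: no ACGT letters found")
    at = (counts[0] + counts[3]) / 2.0
    cg = (counts[1] + counts[2]) / 2.0
    bg = np.array([at, cg, cg, at])
    return bg / bg.sum()


_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_mitochondrial(chrom: str) -> bool:
    return chrom.lower() in MITO_NAMES


def _scan_one_strand(
    codes: np.ndarray,
    int_matrix: np.ndarray,
    n_invalid: np.ndarray,
    threshold: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and integer scores of windows scoring >= threshold (no Ns)."""
    L = int_matrix.shape[0]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    # 5th column scores N as 0; N-containing windows are masked out below.
    lut = np.concatenate([int_matrix, np.zeros((L, 1), dtype=np.int64)], axis=1)
    scores = np.zeros(n_win, dtype=np.int64)
    for j in range(L):
        scores += lut[j, codes[j : j + n_win]]
    valid = (n_invalid[L:] - n_invalid[:-L]) == 0
    keep = np.nonzero(valid & (scores >= threshold))[0]
    return keep, scores[keep]


def scan_genome(
    genome: Mapping[str, str],
    motif_models: Sequence[MotifModel],
    p_threshold: float = 1e-4,
    background: Sequence[float] | None = None,
    eps: float = 1e-3,
    source_sample: str | None = None,
) -> list[MotifHit]:
    """Scan every chromosome on both strands, independently per motif.

    Emits every window with exact p-value < `p_threshold`.  Mitochondrial
    chromosomes (chrM/chrMT/M/MT, any case) are excluded; windows containing
    N are skipped.  Reverse-strand hits are reported in forward coordinates.
    """
    nuclear = {c: s for c, s in genome.items() if not is_mitochondrial(c)}
    if not nuclear or all(len(s) == 0 for s in nuclear.values()):
        raise ValueError("empty genome")
    bg = observed_background(nuclear) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()

    encoded = {c: _encode(s) for c, s in nuclear.items()}
    invalid_cum = {c: np.concatenate([[0], np.cumsum(codes == 4)]) for c, codes in encoded.items()}

    hits: list[MotifHit] = []
    for model in motif_models:
        dist_fwd = ScoreDistribution(model, bg, eps=eps)
        # reverse-complement matrix; its score distribution equals the forward
        # one only under a complement-symmetric background, so recompute
        dist_rev = ScoreDistribution(model.probabilities()[::-1, ::-1], bg, eps=eps)
        per_strand = (("+", dist_fwd.int_matrix, dist_fwd), ("-", dist_rev.int_matrix, dist_rev))
        for chrom in sorted(nuclear):
            codes = encoded[chrom]
            n_invalid = invalid_cum[chrom]
            for strand, int_matrix, dist in per_strand:
                thr = dist.threshold_int(p_threshold)
                offs, scores = _scan_one_strand(codes, int_matrix, n_invalid, thr)
                for off, sc in zip(offs.tolist(), scores.tolist()):
                    hits.append(
                        MotifHit(
                            interval=GenomicInterval(
                                chrom, off, off + model.length, strand, label=model.tf_name
                            ),
                            tf_name=model.tf_name,
                            score=sc * dist.eps,
                            p_value=dist.pvalue_int(sc),
                            source_sample=source_sample,
                        )
                    )
    hits.sort(key=lambda h: (h.tf_name, h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def open_chromatin_filter(
    hits: Sequence[MotifHit],
    peaks: Sequence[GenomicInterval],
    adj_alpha: float = 0.05,
) -> list[MotifHit]:
    """Keep hits inside open chromatin whose BY-adjusted p-value is < adj_alpha.

    A hit must overlap >= 1 bp of a peak; the Benjamini-Yekutieli adjustment
    is then computed per motif over its in-peak hits.  This is the occupancy
    stand-in for a fragment-count binding model: peak overlap carries the
    accessibility evidence, the adjusted scan p-value the motif evidence.
    """
    trees = build_trees(peaks)
    in_peak = [
        h
        for h in hits
        if (t := trees.get(h.interval.chrom)) is not None
        and t.overlap(h.interval.start, h.interval.end)
    ]
    out: list[MotifHit] = []
    by_tf: dict[str, list[MotifHit]] = {}
    for h in in_peak:
        by_tf.setdefault(h.tf_name, []).append(h)
    for tf in sorted(by_tf):
        tf_hits = by_tf[tf]
        pvals = np.array([h.p_value for h in tf_hits])
        _, adj, _, _ = multipletests(pvals, method="fdr_by")
        for h, a in zip(tf_hits, adj):
            if a < adj_alpha:
                out.append(replace(h, adj_p=float(a)))
    out.sort(key=lambda h: (h.tf_name, h.interval.chrom, h.interval.start, h.interval.strand))
    return out


def reproducible_hits(
    hits_by_sample: Mapping[str, Sequence[MotifHit]],
    required_samples: Sequence[str],
) -> list[MotifHit]:
    """Hits whose (chrom, start, end, strand, tf) recur in every required sample."""
    if len(required_samples) < 2:
        raise ValueError("need >= 2 required samples")
    for s in required_samples:
        if s not in hits_by_sample:
            raise KeyError(f"unknown sample id {s!r}")
    key_sets = [frozenset(h.key() for h in hits_by_sample[s]) for s in required_samples]
    common = frozenset.intersection(*key_sets)
    first = required_samples[0]
    kept = [h for h in hits_by_sample[first] if h.key() in common]
    kept.sort(key=lambda h: (h.tf_name, h.interval.chrom, h.interval.start, h.interval.strand))
    return kept


# ---------------------------------------------------------------------------
# MEME-minimal I/O and the motif metadata table


def write_meme(
    motif_models: Sequence[MotifModel],
    path: str | Path,
    background: Sequence[float] | None = None,
) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg)) + "\n\n")
        for m in motif_models:
            fh.write(f"MOTIF {m.tf_name}\n")
            # large nsites: parsers that quantize probabilities into integer
            # counts then lose at most 5e-7 per cell
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} nsites= 1000000 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(
    path: str | Path,
    metadata: pd.DataFrame | None = None,
    pseudocount: float = 0.01,
) -> list[MotifModel]:
    """Read MEME minimal format; optional metadata supplies family/consensus."""
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    meta = metadata.set_index("tf_name") if metadata is not None else None
    models = []
    for m in record:
        mat = np.array([[m.pwm[b][i] for b in BASES] for i in range(m.length)], float)
        family, consensus = "", ""
        if meta is not None and m.name in meta.index:
            family = str(meta.at[m.name, "family"])
            consensus = str(meta.at[m.name, "consensus"])
        models.append(
            MotifModel(m.name, mat, family=family, consensus=consensus, pseudocount=pseudocount)
        )
    return models


def write_motif_metadata(motif_models: Sequence[MotifModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "tf_name": [m.tf_name for m in motif_models],
            "family": [m.family for m in motif_models],
            "quality": [m.tf_name.rsplit("_", 1)[-1] for m in motif_models],
            "consensus": [m.consensus for m in motif_models],
        }
    ).to_csv(path, sep="\t", index=False)


def read_motif_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Tabular (BED6+) view of hits for writing."""
    return pd.DataFrame(
        {
            "chrom": [h.interval.chrom for h in hits],
            "start": [h.interval.start for h in hits],
            "end": [h.interval.end for h in hits],
            "tf_name": [h.tf_name for h in hits],
            "score": [h.score for h in hits],
            "strand": [h.strand for h in hits],
            "p_value": [h.p_value for h in hits],
            "adj_p": [h.adj_p if h.adj_p is not None else np.nan for h in hits],
        }
    )
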