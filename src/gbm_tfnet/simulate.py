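"""Deterministic synthetic data with known planted truth.

Generates everything the pipeline consumes — a small genome, TF motifs,
open-chromatin and H3K27ac peak sets, an expression matrix with grade
labels, and a per-cytosine methylation table — so every stage can be tested
against a recorded ground truth without any download.

Layout of each nuclear chromosome: a gene zone (TSS placed on a regular
grid with jitter) followed by a gene-free distal zone holding enhancers.
Open-chromatin peaks are 200 bp windows (the Tn5-centered convention) at a
subset of promoters plus distal sites; enhancers are wider H3K27ac regions
in the distal zone, which are also accessible.  Motif instances are planted
as exact consensus strings (uniformly on either strand) so recovery is
unambiguous.  Three motifs have designated roles: motif 1 (c-Jun-like bZIP)
is planted in promoters of grade-IV overexpressed genes and inside a set of
enhancers, motif 3 in promoters of grade-II overexpressed genes, and motif
2 is planted at an elevated rate inside enhancers.

All randomness flows from a single seed through named substreams, so adding
one generator never perturbs another, and every generator is bit-for-bit
reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .deg import ExpressionMatrix, substream
from .genomic import (
    GenomicInterval,
    TSSRecord,
    write_bed,
    write_fasta,
    write_tss_table,
)
from .motifs import BASES, MotifModel, reverse_complement, write_meme, write_motif_metadata

FAMILIES = ("bZIP", "ETS", "SOX", "ZF")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults matching its design.

    Group sizes, effect sizes and rates define the simulated study
    conditions: two tumor grades with 40 expression samples each, 10% of
    genes differentially expressed at a 2.0 log2-scale shift, methylation
    cohorts of 4 (GII) and 10 (GIV) samples, and ~1 planted motif instance
    per two accessible kilobases.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_motifs: int = 8
    motif_length_bp: int = 10
    n_genes: int = 2000
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"GII": 40, "GIV": 40}
    )
    planted_de_fraction: float = 0.10
    de_effect_size: float = 2.0
    planted_motif_rate: float = 0.5  # expected planted instances / accessible kb
    meth_diff_fraction: float = 0.10
    background_gc: float = 0.41
    # ---- secondary knobs -------------------------------------------------
    gene_spacing_bp: int = 5000
    peak_width_bp: int = 200  # Tn5-centered open-chromatin window
    promoter_peak_fraction: float = 0.6
    n_distal_peaks_per_chrom: int = 100
    n_enhancers_per_chrom: int = 40
    enhancer_width_bp: int = 1000
    atac_samples: tuple[str, ...] = ("LN18", "LN229")
    sample_specific_peak_fraction: float = 0.05
    h3k27ac_samples: tuple[str, ...] = tuple(
        [f"DA{i}" for i in range(1, 9)] + [f"GBM{i}" for i in range(1, 11)]
    )
    n_tf_enhancer_sites: int = 94  # c-Jun-like motif instances inside enhancers
    enhancer_motif_rate_boost: float = 4.0  # extra planting for the enriched motif
    expr_sigma: float = 1.0
    regulon_coupling: float = 0.5  # latent-factor loading of TF1 targets
    meth_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"GII": 4, "GIV": 10}
    )
    mean_coverage: float = 20.0
    low_coverage_fraction: float = 0.05
    low_coverage_mean: float = 5.0
    cytosine_density: float = 0.2
    meth_high: float = 0.8  # differential windows: high-group methylation probability
    meth_low: float = 0.1  # differential windows: low-group methylation probability

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "n_motifs",
            "motif_length_bp",
            "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "planted_de_fraction",
            "meth_diff_fraction",
            "background_gc",
            "promoter_peak_fraction",
            "low_coverage_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length_bp < self.motif_length_bp:
            raise ValueError("chrom_length_bp must be >= motif_length_bp")
        if len(self.n_samples_per_group) < 2:
            raise ValueError("need >= 2 expression groups")
        for g, n in self.n_samples_per_group.items():
            if n < 1:
                raise ValueError(f"group {g}: need >= 1 sample")

    @property
    def groups(self) -> list[str]:
        return sorted(self.n_samples_per_group)


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating the data."""

    de_gene_ids: dict[str, set[str]] = field(default_factory=dict)
    planted_hits: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    differential_meth_windows: set[str] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "de_gene_ids": {g: sorted(s) for g, s in self.de_gene_ids.items()},
            "planted_hits": [
                [tf, iv.chrom, iv.start, iv.end, iv.strand]
                for tf, iv in self.planted_hits
            ],
            "differential_meth_windows": sorted(self.differential_meth_windows),
        }


def region_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


# ---------------------------------------------------------------------------
# gene ids and the planted DE split (shared by genome and expression)


def gene_ids(config: SimConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, config.n_genes + 1)]


def tf_gene_of_motif(config: SimConfig, motif_index: int) -> str:
    """The gene encoding each simulated TF: the first n_motifs gene ids."""
    if motif_index >= min(config.n_motifs, config.n_genes):
        raise ValueError("motif index out of range")
    return gene_ids(config)[motif_index]


def planted_de_sets(config: SimConfig) -> dict[str, set[str]]:
    """Planted DE gene ids per group, disjoint, deterministic from the seed.

    The designated GIV-specific TF's own gene is always grade-IV
    overexpressed (and the GII-specific TF's gene grade-II overexpressed),
    mirroring a TF that drives — and is itself part of — its regulon.
    """
    ids = gene_ids(config)
    n_de = int(round(config.planted_de_fraction * config.n_genes))
    groups = config.groups
    if n_de < 1:
        warnings.warn("planted_de_fraction * n_genes < 1: no genes planted")
        return {g: set() for g in groups}
    rng = substream(config.seed, "de-split")
    chosen = rng.choice(len(ids), size=n_de, replace=False)
    per_group: dict[str, set[str]] = {g: set() for g in groups}
    for j, idx in enumerate(sorted(chosen.tolist())):
        per_group[groups[j % len(groups)]].add(ids[idx])
    if config.n_motifs >= 1 and "GIV" in per_group:
        _force_membership(per_group, tf_gene_of_motif(config, 0), "GIV")
    if config.n_motifs >= 3 and "GII" in per_group:
        _force_membership(per_group, tf_gene_of_motif(config, 2), "GII")
    return per_group


def _force_membership(per_group: dict[str, set[str]], gene: str, group: str) -> None:
    for g, s in per_group.items():
        s.discard(gene)
    per_group[group].add(gene)


# ---------------------------------------------------------------------------
# motifs


def generate_motifs(config: SimConfig) -> list[MotifModel]:
    """Random high-information motifs; motif 1 is AP-1-flavored (TGAGTCA core)."""
    rng = substream(config.seed, "motifs")
    L = config.motif_length_bp
    models = []
    for m in range(config.n_motifs):
        if m == 0:
            core = "TGAGTCA"[:L]
            extra = "".join(rng.choice(list(BASES), size=max(0, L - len(core))))
            consensus = (core + extra)[:L]
            name = f"JUNL_0_A"
        else:
            consensus = "".join(rng.choice(list(BASES), size=L))
            name = f"TF{m + 1:02d}_0_A"
        matrix = np.full((L, 4), 0.03)
        for j, b in enumerate(consensus):
            matrix[j] = 0.03
            matrix[j, BASES.index(b)] = 0.91
        models.append(
            MotifModel(
                name,
                matrix,
                family=FAMILIES[m % len(FAMILIES)],
                consensus=consensus,
            )
        )
    return models


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeSim:
    """Genome-side simulation outputs."""

    sequences: dict[str, str]
    motifs: list[MotifModel]
    tss: list[TSSRecord]
    base_peaks: list[GenomicInterval]  # accessible chromatin (union design)
    atac_peaks_by_sample: dict[str, list[GenomicInterval]]
    h3k27ac_by_sample: dict[str, list[GenomicInterval]]
    enhancer_regions: list[GenomicInterval]  # recurrent by construction
    truth: PlantedTruth


def _place_genes(config: SimConfig) -> list[TSSRecord]:
    rng = substream(config.seed, "genes")
    ids = gene_ids(config)
    margin = 2000
    zone_end = int(0.6 * config.chrom_length_bp)
    spacing = config.gene_spacing_bp
    records = []
    gi = 0
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = margin
        while pos + spacing < zone_end and gi < len(ids):
            tss = pos + int(rng.integers(0, min(1000, spacing // 2)))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(TSSRecord(ids[gi], chrom, tss, strand))
            gi += 1
            pos += spacing
    return records


def generate_genome(config: SimConfig) -> GenomeSim:
    """Genome sequences with planted consensus instances, plus peak sets.

    Returns one sequence per nuclear chromosome (chr1..chrN) and a
    mitochondrial chromosome (chrM) of the same stated length, all at the
    requested GC composition.  Planted motif instances are recorded in the
    truth; every one lies inside an accessible-chromatin interval.  chrM
    carries one unrecorded instance of each motif so the exclusion logic is
    exercisable.
    """
    if config.chrom_length_bp < config.motif_length_bp:
        raise ValueError("chrom_length_bp must be >= motif_length_bp")
    motifs = generate_motifs(config)
    tss = _place_genes(config)
    de_sets = planted_de_sets(config)
    L = config.motif_length_bp
    gc = config.background_gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    chrom_names = [f"chr{c}" for c in range(1, config.n_chromosomes + 1)] + ["chrM"]
    seqs: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        rng = substream(config.seed, "sequence", chrom)
        seqs[chrom] = rng.choice(np.frombuffer(BASES.encode(), dtype=np.uint8),
                                 size=config.chrom_length_bp, p=base_p)

    tss_by_gene = {t.gene_id: t for t in tss}

    # --- open-chromatin design: promoter peaks + distal peaks + enhancers
    rng_peaks = substream(config.seed, "peaks")
    half = config.peak_width_bp // 2
    promoter_peaks: list[GenomicInterval] = []
    de_placed = {g for s in de_sets.values() for g in s if g in tss_by_gene}
    for t in tss:
        has_peak = t.gene_id in de_placed or rng_peaks.random() < config.promoter_peak_fraction
        if has_peak and t.tss - half >= 0:
            promoter_peaks.append(
                GenomicInterval(t.chrom, t.tss - half, t.tss + half, ".", t.gene_id)
            )
    distal_start = int(0.65 * config.chrom_length_bp)
    distal_end = config.chrom_length_bp - 2000
    distal_peaks: list[GenomicInterval] = []
    enhancers: list[GenomicInterval] = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        span = distal_end - distal_start
        n_slots = config.n_distal_peaks_per_chrom + config.n_enhancers_per_chrom
        slot = span // max(1, n_slots)
        positions = [distal_start + i * slot for i in range(n_slots)]
        enh_slots = set(
            rng_peaks.choice(n_slots, size=min(config.n_enhancers_per_chrom, n_slots), replace=False).tolist()
        )
        for i, pos in enumerate(positions):
            if i in enh_slots:
                end = min(pos + config.enhancer_width_bp, config.chrom_length_bp)
                enhancers.append(GenomicInterval(chrom, pos, end, ".", f"enh_{chrom}_{i}"))
            else:
                end = min(pos + config.peak_width_bp, config.chrom_length_bp)
                distal_peaks.append(GenomicInterval(chrom, pos, end, ".", ""))
    base_peaks = sorted(promoter_peaks + distal_peaks + enhancers)

    # --- plant motif instances (consensus strings, uniform strand)
    truth = PlantedTruth(de_gene_ids={g: set(s) for g, s in de_sets.items()})
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def try_plant(motif: MotifModel, chrom: str, start: int, rng: np.random.Generator,
                  record: bool = True) -> bool:
        end = start + L
        if start < 0 or end > config.chrom_length_bp:
            return False
        for a, b in occupied[chrom]:
            if start < b and a < end:
                return False
        strand = "+" if rng.random() < 0.5 else "-"
        planted = motif.consensus if strand == "+" else reverse_complement(motif.consensus)
        seqs[chrom][start:end] = np.frombuffer(planted.encode(), dtype=np.uint8)
        occupied[chrom].append((start, end))
        if record:
            truth.planted_hits.append(
                (motif.tf_name, GenomicInterval(chrom, start, end, strand, motif.tf_name))
            )
        return True

    # grade-specific promoter plantings: motif 1 -> GIV promoters, motif 3 -> GII
    specials = []
    if config.n_motifs >= 1 and "GIV" in de_sets:
        specials.append((0, "GIV"))
    if config.n_motifs >= 3 and "GII" in de_sets:
        specials.append((2, "GII"))
    special_indices = {m for m, _ in specials}
    peak_of_gene = {p.label: p for p in promoter_peaks}
    for m, group in specials:
        rng = substream(config.seed, "plant-promoter", m)
        for gene in sorted(de_sets[group]):
            peak = peak_of_gene.get(gene)
            if peak is None:
                continue
            for _ in range(20):
                start = int(rng.integers(peak.start, max(peak.start + 1, peak.end - L)))
                if try_plant(motifs[m], peak.chrom, start, rng):
                    break

    # c-Jun-like instances inside enhancers (the methylation windows)
    if config.n_motifs >= 1 and enhancers:
        rng = substream(config.seed, "plant-enhancer-jun")
        widths = np.array([e.width for e in enhancers], float)
        for _ in range(config.n_tf_enhancer_sites):
            for _ in range(20):
                e = enhancers[int(rng.choice(len(enhancers), p=widths / widths.sum()))]
                start = int(rng.integers(e.start, e.end - L))
                if try_plant(motifs[0], e.chrom, start, rng):
                    break

    # enhancer-enriched motif 2
    if config.n_motifs >= 2 and enhancers:
        rng = substream(config.seed, "plant-enhancer-boost")
        enh_kb = sum(e.width for e in enhancers) / 1000.0
        n_extra = int(rng.poisson(config.planted_motif_rate * config.enhancer_motif_rate_boost * enh_kb))
        widths = np.array([e.width for e in enhancers], float)
        for _ in range(n_extra):
            for _ in range(20):
                e = enhancers[int(rng.choice(len(enhancers), p=widths / widths.sum()))]
                start = int(rng.integers(e.start, e.end - L))
                if try_plant(motifs[1], e.chrom, start, rng):
                    break

    # uniform background planting over accessible chromatin (all other motifs)
    acc_kb = sum(p.width for p in base_peaks) / 1000.0
    peak_widths = np.array([p.width for p in base_peaks], float)
    for m, motif in enumerate(motifs):
        if m in special_indices:
            continue
        rng = substream(config.seed, "plant-uniform", m)
        n_plant = int(rng.poisson(config.planted_motif_rate * acc_kb))
        for _ in range(n_plant):
            for _ in range(20):
                p = base_peaks[int(rng.choice(len(base_peaks), p=peak_widths / peak_widths.sum()))]
                if p.width <= L:
                    continue
                start = int(rng.integers(p.start, p.end - L))
                if try_plant(motif, p.chrom, start, rng):
                    break

    # one unrecorded instance of each motif on chrM
    rng = substream(config.seed, "plant-chrm")
    for m, motif in enumerate(motifs):
        start = int(rng.integers(0, config.chrom_length_bp - L))
        try_plant(motif, "chrM", start, rng, record=False)

    sequences = {c: seqs[c].tobytes().decode("ascii") for c in chrom_names}

    # --- per-sample ATAC peaks: shared base + a few sample-specific extras
    atac: dict[str, list[GenomicInterval]] = {}
    for sample in config.atac_samples:
        rng = substream(config.seed, "atac", sample)
        own: list[GenomicInterval] = []
        n_extra = int(config.sample_specific_peak_fraction * len(base_peaks))
        for _ in range(n_extra):
            chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
            start = int(rng.integers(0, config.chrom_length_bp - config.peak_width_bp))
            own.append(GenomicInterval(chrom, start, start + config.peak_width_bp, ".", f"{sample}_only"))
        atac[sample] = sorted(base_peaks + own)

    # --- per-sample H3K27ac: enhancers recur in >= 2 samples by design,
    # promoters carry the mark too (removed later by the TSS exclusion)
    h3k: dict[str, list[GenomicInterval]] = {s: [] for s in config.h3k27ac_samples}
    rng = substream(config.seed, "h3k27ac")
    n_h3k = len(config.h3k27ac_samples)
    for e in enhancers:
        k = int(rng.integers(2, n_h3k + 1))
        carriers = rng.choice(n_h3k, size=k, replace=False)
        for ci in carriers:
            jitter_s = int(rng.integers(-100, 101))
            jitter_e = int(rng.integers(-100, 101))
            start = max(0, e.start + jitter_s)
            end = max(start + 1, min(e.end + jitter_e, config.chrom_length_bp))
            h3k[config.h3k27ac_samples[ci]].append(GenomicInterval(e.chrom, start, end, ".", e.label))
    # singleton noise peaks (removed by the recurrence filter)
    for sample in config.h3k27ac_samples:
        rng_s = substream(config.seed, "h3k27ac-noise", sample)
        for _ in range(5):
            chrom = f"chr{int(rng_s.integers(1, config.n_chromosomes + 1))}"
            start = int(rng_s.integers(distal_start, distal_end - 500))
            h3k[sample].append(GenomicInterval(chrom, start, start + 500, ".", "noise"))
    # promoter H3K27ac at active promoters, in all samples
    for t in tss[:: max(1, len(tss) // 40) ]:
        iv = GenomicInterval(t.chrom, max(0, t.tss - 500), t.tss + 500, ".", f"prom_{t.gene_id}")
        for sample in config.h3k27ac_samples:
            h3k[sample].append(iv)
    h3k = {s: sorted(ivs) for s, ivs in h3k.items()}

    return GenomeSim(
        sequences=sequences,
        motifs=motifs,
        tss=tss,
        base_peaks=base_peaks,
        atac_peaks_by_sample=atac,
        h3k27ac_by_sample=h3k,
        enhancer_regions=enhancers,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression


def generate_expression(config: SimConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Log-normal FPKM-like abundances with planted grade-specific DE genes.

    Planted genes get a de_effect_size shift of their log2 mean in exactly
    one group.  Grade-IV planted genes additionally load on a latent
    per-sample factor shared with the designated TF's own gene, so TF-target
    correlation is positive within groups as well as across them.
    """
    de_sets = planted_de_sets(config)
    truth = PlantedTruth(de_gene_ids={g: set(s) for g, s in de_sets.items()})
    ids = gene_ids(config)
    groups = config.groups
    samples = []
    group_of = {}
    for g in groups:
        for i in range(1, config.n_samples_per_group[g] + 1):
            s = f"{g}_{i:02d}"
            samples.append(s)
            group_of[s] = g

    rng = substream(config.seed, "expression")
    n_g, n_s = len(ids), len(samples)
    baseline = rng.uniform(2.0, 8.0, size=n_g)
    noise = rng.normal(0.0, config.expr_sigma, size=(n_g, n_s))
    latent = rng.normal(0.0, 1.0, size=n_s)  # per-sample regulon factor

    gene_index = {g: i for i, g in enumerate(ids)}
    # regulon coupling mixes the latent factor into the *noise* of grade-IV
    # planted genes (unit variance preserved), before any mean shift
    coupled = set(de_sets.get("GIV", set()))
    if coupled and config.regulon_coupling > 0:
        lam = config.regulon_coupling
        for gene in coupled:
            i = gene_index[gene]
            noise[i] = noise[i] * np.sqrt(1 - lam**2) + lam * latent * config.expr_sigma

    log2x = baseline[:, None] + noise
    group_idx = {g: np.array([group_of[s] == g for s in samples]) for g in groups}
    for g in groups:
        for gene in de_sets[g]:
            log2x[gene_index[gene], group_idx[g]] += config.de_effect_size * config.expr_sigma
    values = np.power(2.0, log2x)
    return ExpressionMatrix(ids, samples, values, group_of), truth


# ---------------------------------------------------------------------------
# methylation


def meth_sample_names(config: SimConfig) -> dict[str, list[str]]:
    return {
        g: [f"{g}_M{i:02d}" for i in range(1, n + 1)]
        for g, n in sorted(config.meth_samples_per_group.items())
    }


def generate_methylation(
    regions: Sequence[GenomicInterval],
    config: SimConfig,
    diff_fraction: float | None = None,
    prob_override: float | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Per-cytosine read counts for each methylation sample over the regions.

    A `diff_fraction` of regions gets group-differential cytosine
    methylation (mean beta `meth_high` in one randomly chosen group vs
    `meth_low` in the others); remaining regions share a common mean.
    Per-cytosine probabilities are Beta-distributed around the region mean
    so betas populate the hypo/medium/hyper bins.  Coverage is Poisson
    around `mean_coverage`, with a `low_coverage_fraction` of cytosines
    drawn around `low_coverage_mean` instead so the >= 10-read filter has
    something to remove.  The returned table uses internal 0-based
    positions; `write_methylation_table` emits the 1-based file dialect.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    frac = config.meth_diff_fraction if diff_fraction is None else diff_fraction
    samples_by_group = meth_sample_names(config)
    groups = sorted(samples_by_group)
    rng = substream(config.seed, "methylation")
    n_diff = int(round(frac * len(regions)))
    diff_idx = set(rng.choice(len(regions), size=n_diff, replace=False).tolist()) if n_diff else set()
    truth = PlantedTruth()
    rows: list[tuple] = []
    for ri, region in enumerate(regions):
        n_cyt = max(1, int(round(region.width * config.cytosine_density)))
        positions = np.sort(rng.choice(region.width, size=min(n_cyt, region.width), replace=False))
        if ri in diff_idx and prob_override is None:
            high_group = groups[int(rng.integers(0, len(groups)))]
            mean_of = {g: (config.meth_high if g == high_group else config.meth_low) for g in groups}
            truth.differential_meth_windows.add(region_id(region))
        else:
            shared = float(rng.uniform(0.2, 0.8)) if prob_override is None else float(prob_override)
            mean_of = {g: shared for g in groups}
        for off in positions.tolist():
            pos = region.start + off
            # the methylation probability is constant within a region for
            # each group; cytosine betas then vary only through binomial
            # read sampling, and group bin counts are independent
            p_of = {g: float(min(1.0, max(0.0, mean_of[g]))) for g in groups}
            for g in groups:
                for s in samples_by_group[g]:
                    mean_cov = (
                        config.low_coverage_mean
                        if rng.random() < config.low_coverage_fraction
                        else config.mean_coverage
                    )
                    total = int(rng.poisson(mean_cov))
                    meth = int(rng.binomial(total, p_of[g])) if total else 0
                    rows.append((region.chrom, pos, region.strand, s, meth, total))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample", "methylated", "total"])
    return table, truth


def meth_group_of(config: SimConfig) -> dict[str, str]:
    return {s: g for g, ss in meth_sample_names(config).items() for s in ss}


# ---------------------------------------------------------------------------
# writing everything to disk


def write_simulation(
    outdir: str | Path,
    genome_sim: GenomeSim,
    expr: ExpressionMatrix,
    meth_table: pd.DataFrame | None = None,
    truth: PlantedTruth | None = None,
) -> None:
    """Write FASTA, BED, TSV and JSON artifacts of a simulation."""
    from .methylation import write_methylation_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome_sim.sequences, out / "genome.fa")
    write_meme(genome_sim.motifs, out / "motifs.meme")
    write_motif_metadata(genome_sim.motifs, out / "motif_metadata.tsv")
    write_tss_table(genome_sim.tss, out / "genes.tsv")
    write_bed(genome_sim.base_peaks, out / "accessible.bed")
    for sample, peaks in genome_sim.atac_peaks_by_sample.items():
        write_bed(peaks, out / f"atac_{sample}.bed")
    for sample, peaks in genome_sim.h3k27ac_by_sample.items():
        write_bed(peaks, out / f"h3k27ac_{sample}.bed")
    write_bed([iv for _, iv in genome_sim.truth.planted_hits], out / "planted_hits.bed")
    expr.write(out / "expression.tsv", out / "groups.tsv")
    if meth_table is not None:
        write_methylation_table(meth_table, out / "methylation.tsv")
    merged = truth if truth is not None else genome_sim.truth
    with open(out / "truth.json", "w") as fh:
        json.dump(merged.to_json(), fh, indent=1, sort_keys=True)
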