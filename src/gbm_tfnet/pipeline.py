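"""End-to-end orchestration: scan -> DE -> promoter TFBS -> enhancers ->
methylation -> correlation, with every stage's table written to disk.

The pipeline runs either on user-supplied files (YAML config naming the
inputs) or fully self-contained on the synthetic generator (`simulate`),
in which case the generated inputs and the planted truth are written next
to the results.  Given a fixed config and seed the run is idempotent: no
timestamps enter any artifact, so output checksums are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlate import correlation_frame, tf_target_correlation
from .deg import ExpressionMatrix, direction_logfc, select_overexpressed, subsampled_de
from .enhancers import (
    define_enhancers,
    enrichment_frame,
    hit_counts,
    hypergeometric_enrichment,
    recurrence_filter,
)
from .genomic import (
    GenomicInterval,
    TSSRecord,
    build_trees,
    make_promoters,
    read_bed,
    read_fasta,
    read_tss_table,
    write_bed,
)
from .methylation import (
    assign_regions,
    beta_from_counts,
    binned_chi2_test,
    chi2_frame,
    motif_windows,
    read_methylation_table,
    write_methylation_table,
)
from .motifs import (
    MotifModel,
    hits_to_frame,
    open_chromatin_filter,
    read_meme,
    read_motif_metadata,
    reproducible_hits,
    scan_genome,
)
from .promoter_tfbs import (
    classification_frame,
    classify_tfbs,
    family_rollup,
    normalized_occurrences,
    promoter_hit_table,
)
from .simulate import (
    SimConfig,
    generate_expression,
    generate_genome,
    generate_methylation,
    meth_group_of,
    tf_gene_of_motif,
    write_simulation,
)


@dataclass
class AnalysisOptions:
    """Tunables of the analysis stages (scan threshold, window sizes, FDR)."""

    p_threshold: float = 1e-4
    adj_alpha: float = 0.05
    n_iter: int = 200
    n_per_group: int = 20
    de_alpha: float = 0.01
    promoter_upstream: int = 1500
    promoter_downstream: int = 1500
    tss_exclusion_bp: int = 3000
    min_recurrent_samples: int = 2
    flank_bp: int = 20
    min_coverage: int = 10
    meth_alpha: float = 0.05


@dataclass
class PipelineData:
    """In-memory inputs of one pipeline run, however they were obtained."""

    sequences: dict[str, str]
    motifs: list[MotifModel]
    tss: list[TSSRecord]
    atac_peaks_by_sample: dict[str, list[GenomicInterval]]
    h3k27ac_by_sample: dict[str, list[GenomicInterval]]
    expr: ExpressionMatrix
    group_a: str
    group_b: str
    focal_tf: str  # TF whose enhancer motifs anchor the methylation stage
    focal_tf_gene: str  # the gene encoding it, for correlation
    # either a ready methylation table + labels, or a generator callback
    meth_table: pd.DataFrame | None = None
    meth_groups: dict[str, str] | None = None
    meth_generator: Callable[[list[GenomicInterval]], tuple[pd.DataFrame, object]] | None = None


def pooled_group_betas(
    betas: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    group_of: Mapping[str, str],
) -> list[tuple[GenomicInterval, dict[str, np.ndarray]]]:
    """Per region, cytosine-level betas pooled across samples within group."""
    out = []
    for region, sub in assign_regions(betas, regions).items():
        by_group: dict[str, list[float]] = {}
        for s, g in sub.groupby("sample", sort=True):
            by_group.setdefault(group_of[s], []).extend(g["beta"].tolist())
        if len(by_group) >= 2:
            out.append((region, {g: np.array(v) for g, v in by_group.items()}))
    return out


def run_stages(
    data: PipelineData, outdir: str | Path, opts: AnalysisOptions, seed: int
) -> dict:
    """Execute every analysis stage on `data`, writing tables under `outdir`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- motif scan + occupancy + reproducibility -------------------------
    hits = scan_genome(data.sequences, data.motifs, p_threshold=opts.p_threshold)
    hits_by_sample = {
        s: open_chromatin_filter(hits, peaks, adj_alpha=opts.adj_alpha)
        for s, peaks in data.atac_peaks_by_sample.items()
    }
    rep_hits = reproducible_hits(hits_by_sample, sorted(hits_by_sample))
    hits_to_frame(rep_hits).to_csv(out / "tfbs_reproducible.tsv", sep="\t", index=False)

    # ---- grade-specific gene selection ------------------------------------
    group_a, group_b = data.group_a, data.group_b
    mean_adj_p = subsampled_de(
        data.expr, group_a, group_b, n_iter=opts.n_iter, n_per_group=opts.n_per_group, seed=seed
    )
    logfc = direction_logfc(data.expr, group_a, group_b)
    selection = select_overexpressed(mean_adj_p, logfc, group_a, group_b, alpha=opts.de_alpha)
    selection.table.to_csv(out / "de_selection.tsv", sep="\t")
    set_a, set_b = selection.selected(group_a), selection.selected(group_b)

    # ---- promoter TFBS classification -------------------------------------
    promoters = make_promoters(data.tss, opts.promoter_upstream, opts.promoter_downstream)
    prom_table = promoter_hit_table(rep_hits, promoters)
    classification = classify_tfbs(prom_table, set_a, set_b, group_a, group_b)
    if set_a and set_b:
        classification = normalized_occurrences(classification, len(set_a), len(set_b))
    class_df = classification_frame(classification)
    class_df.to_csv(out / "tfbs_classification.tsv", sep="\t", index=False)
    family_of = {m.tf_name: m.family for m in data.motifs}
    families = family_rollup(classification, family_of)
    families.to_csv(out / "tf_families.tsv", sep="\t")

    # ---- enhancers + enrichment -------------------------------------------
    recurrent = recurrence_filter(data.h3k27ac_by_sample, opts.min_recurrent_samples)
    enhancers = define_enhancers(recurrent, data.tss, opts.tss_exclusion_bp)
    write_bed(enhancers, out / "enhancers.bed")
    counts_enh, counts_genome = hit_counts(rep_hits, enhancers)
    enrichment = hypergeometric_enrichment(counts_enh, counts_genome)
    enrichment_frame(enrichment).to_csv(out / "enhancer_enrichment.tsv", sep="\t", index=False)

    # ---- methylation around the focal TF's motifs in enhancers ------------
    enh_trees = build_trees(enhancers)
    focal_in_enh = [
        h
        for h in rep_hits
        if h.tf_name == data.focal_tf
        and (t := enh_trees.get(h.interval.chrom)) is not None
        and t.overlap(h.interval.start, h.interval.end)
    ]
    windows = motif_windows(focal_in_enh, flank_bp=opts.flank_bp)
    summary_meth = {"n_windows": len(windows), "n_significant": 0}
    if windows and (data.meth_table is not None or data.meth_generator is not None):
        if data.meth_generator is not None:
            meth_table, _ = data.meth_generator(windows)
            groups_of = data.meth_groups
            write_methylation_table(meth_table, out / "methylation.tsv")
        else:
            meth_table, groups_of = data.meth_table, data.meth_groups
        betas = beta_from_counts(meth_table, min_coverage=opts.min_coverage)
        pooled = pooled_group_betas(betas, windows, groups_of)
        chi2 = binned_chi2_test(pooled, alpha=opts.meth_alpha)
        chi2_frame(chi2).to_csv(out / "meth_chi2.tsv", sep="\t", index=False)
        sig = [r for r in chi2 if r.testable and r.adj_p is not None and r.adj_p < opts.meth_alpha]
        summary_meth = {"n_windows": len(windows), "n_significant": len(sig)}

    # ---- TF-target correlation --------------------------------------------
    targets = sorted(
        set(prom_table.loc[prom_table["tf_name"] == data.focal_tf, "gene_id"])
        & set_a - {data.focal_tf_gene}
    )
    targets = [t for t in targets if t in data.expr.genes]
    corr_df = pd.DataFrame()
    if targets and data.focal_tf_gene in data.expr.genes:
        records = tf_target_correlation(data.expr, data.focal_tf_gene, targets)
        corr_df = correlation_frame(records)
        corr_df.to_csv(out / "tf_target_correlation.tsv", sep="\t", index=False)

    summary = {
        "seed": seed,
        "version": __version__,
        "n_scan_hits": len(hits),
        "n_hits_open_chromatin": {s: len(v) for s, v in sorted(hits_by_sample.items())},
        "n_reproducible_hits": len(rep_hits),
        "n_overexpressed": {group_a: len(set_a), group_b: len(set_b)},
        "n_promoter_tf_gene_pairs": int(len(prom_table)),
        "n_grade_specific_tfbs": {
            group_a: int((class_df["status"] == f"specific_to_{group_a}").sum()),
            group_b: int((class_df["status"] == f"specific_to_{group_b}").sum()),
        },
        "n_generic_tfbs": int((class_df["status"] == "generic").sum()),
        "n_enhancers": len(enhancers),
        "n_motif_instances_in_enhancers": int(sum(counts_enh.values())),
        "n_focal_tf_sites_in_enhancers": len(focal_in_enh),
        "methylation": summary_meth,
        "n_correlated_targets": int(len(corr_df)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"gbm-tfnet {__version__}\nseed: {seed}\n")
        fh.write("stages: scan, de, promoters, enhancers, methylation, correlate\n")
    return summary


def run_simulated_pipeline(
    seed: int,
    outdir: str | Path,
    sim_config: SimConfig | None = None,
    options: AnalysisOptions | None = None,
) -> dict:
    """Generate synthetic inputs and run every stage on them."""
    cfg = sim_config if sim_config is not None else SimConfig(seed=seed)
    if sim_config is None:
        cfg.seed = seed
    gsim = generate_genome(cfg)
    expr, _ = generate_expression(cfg)
    meth_truth_holder: list = []

    def _gen_meth(windows):
        table, truth = generate_methylation(windows, cfg)
        meth_truth_holder.append(truth)
        return table, truth

    data = PipelineData(
        sequences=gsim.sequences,
        motifs=gsim.motifs,
        tss=gsim.tss,
        atac_peaks_by_sample=gsim.atac_peaks_by_sample,
        h3k27ac_by_sample=gsim.h3k27ac_by_sample,
        expr=expr,
        group_a="GIV",
        group_b="GII",
        focal_tf=gsim.motifs[0].tf_name,
        focal_tf_gene=tf_gene_of_motif(cfg, 0),
        meth_groups=meth_group_of(cfg),
        meth_generator=_gen_meth,
    )
    summary = run_stages(data, outdir, options or AnalysisOptions(), cfg.seed)
    write_simulation(Path(outdir) / "inputs", gsim, expr, truth=gsim.truth)
    if meth_truth_holder:
        with open(Path(outdir) / "inputs" / "truth_methylation.json", "w") as fh:
            json.dump(meth_truth_holder[0].to_json(), fh, indent=1, sort_keys=True)
    return summary


def load_pipeline_data(cfg: Mapping) -> PipelineData:
    """Assemble PipelineData from a YAML config naming input files."""
    required = ["genome", "motifs", "genes", "expression", "groups", "atac", "h3k27ac"]
    missing = []
    for key in required:
        if key not in cfg:
            missing.append(key)
            continue
        paths = cfg[key].values() if isinstance(cfg[key], Mapping) else [cfg[key]]
        missing.extend(str(p) for p in paths if not Path(p).exists())
    if missing:
        raise FileNotFoundError("missing pipeline inputs: " + ", ".join(map(str, missing)))
    metadata = None
    if "motif_metadata" in cfg:
        metadata = read_motif_metadata(cfg["motif_metadata"])
    motifs = read_meme(cfg["motifs"], metadata=metadata)
    expr = ExpressionMatrix.read(cfg["expression"], cfg["groups"])
    meth_table = meth_groups = None
    if "methylation" in cfg:
        meth_table = read_methylation_table(cfg["methylation"])
        labels = pd.read_csv(cfg["meth_groups"], sep="\t", dtype=str)
        meth_groups = dict(zip(labels["sample"], labels["group"]))
    focal_tf = cfg.get("focal_tf", motifs[0].tf_name)
    return PipelineData(
        sequences=read_fasta(cfg["genome"]),
        motifs=motifs,
        tss=read_tss_table(cfg["genes"]),
        atac_peaks_by_sample={s: read_bed(p) for s, p in cfg["atac"].items()},
        h3k27ac_by_sample={s: read_bed(p) for s, p in cfg["h3k27ac"].items()},
        expr=expr,
        group_a=cfg.get("group_a", "GIV"),
        group_b=cfg.get("group_b", "GII"),
        focal_tf=focal_tf,
        focal_tf_gene=cfg.get("focal_tf_gene", focal_tf),
        meth_table=meth_table,
        meth_groups=meth_groups,
    )


def run_pipeline(config_path: str | Path) -> dict:
    """Run from a YAML config; `simulate: true` uses the generator instead."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    outdir = cfg.get("outdir", "gbm_tfnet_results")
    seed = int(cfg.get("seed", 0))
    opts = AnalysisOptions(**(cfg.get("analysis", {}) or {}))
    if cfg.get("simulate", False):
        sim = SimConfig(seed=seed, **(cfg.get("sim", {}) or {}))
        return run_simulated_pipeline(seed, outdir, sim_config=sim, options=opts)
    data = load_pipeline_data(cfg)
    return run_stages(data, outdir, opts, seed)


def checksum_tree(root: str | Path) -> str:
    """SHA256 over the sorted relative paths and contents of a directory."""
    h = hashlib.sha256()
    root = Path(root)
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(root)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
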