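# Methods

This note documents the models implemented in `gbm-tfnet`, the parameter
defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic-data tests demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention). The only
1-based input dialect — the per-cytosine methylation table — is converted
at the parser boundary. Promoters are strand-aware windows around a single
TSS per gene: `[tss − up, tss + down)` on `+`, mirrored on `−`, clipped at
zero. Symmetric windows (±1.5 kb, used for TFBS counting) are therefore
strand-invariant; the asymmetric methylation promoters (2 kb upstream /
500 bp downstream) are not. Promoters of adjacent genes may overlap and
are never merged: the counting unit is the gene.

## PWM scanning with exact p-values

A motif is an L×4 position probability matrix. Before scoring, a
pseudocount of 0.01 is added per cell and rows renormalized, so no letter
has probability zero (−∞ log-odds). A window scores
`Σ_j log2(p_j(b_j) / q(b_j))` bits against a 0-order background `q`; the
default background is the scanned genome's observed mononucleotide
composition, strand-symmetrized (`q_A = q_T`, `q_C = q_G`), so forward and
reverse-complement scans are exact mirrors. Windows containing `N` are
skipped.

P-values are exact: log-odds are discretized on a 1e-3-bit grid and the
full distribution of the integer total score under the background is
computed by dynamic programming over positions. The scanner scores windows
on the same integer grid, so reported p-values agree with exhaustive
enumeration to floating-point precision (verified for L ≤ 8 against all
4^L windows). The grid error (≤ L·5e-4 bits) is negligible relative to the
score gaps that matter at the p < 1e-4 emission threshold. Reverse-strand
hits are scored with the reverse-complemented matrix and reported in
forward coordinates; the reverse distribution is recomputed rather than
reused, so user-supplied asymmetric backgrounds remain exact.
Mitochondrial sequences (chrM/chrMT/M/MT, any case) are never scanned.

Occupancy filtering is deliberately simple: a hit must overlap ≥ 1 bp of
an open-chromatin peak, and within each motif the scan p-values of in-peak
hits are Benjamini–Yekutieli adjusted; hits with adjusted p ≥ 0.05 are
dropped. The BY family is per motif (not global) because motifs are
scanned independently. Fragment-count occupancy modeling is out of scope.
The reproducibility filter keeps a hit only if an identical
(chrom, start, end, strand, TF) tuple exists in every required sample —
strand included, a conservative reading of "same chromosomal localization".
The two filters commute.

## Resampled differential expression

For groups A and B (e.g. grade IV vs grade II), each of `n_iter = 200`
draws samples `n_per_group = 20` patients per group uniformly without
replacement (sample ids sorted canonically first, so file order is
irrelevant; each draw uses its own named RNG substream). Within a draw,
each gene gets a pooled-variance Student t-test on log2(value + 1)
(Welch available via a flag), p-values are BH-adjusted across genes, and a
gene's final statistic is the arithmetic mean of its draw-wise adjusted
p-values. Genes with zero within-draw variance get p = 1 for that draw,
keeping the mean defined. Direction is `log2((mean_A + 1)/(mean_B + 1))`
over all samples; a gene is overexpressed in A when mean adjusted p < 0.01
and the fold change is positive (exactly zero stays unassigned). An
optional gene-id whitelist stands in for a protein-coding restriction.

Under the synthetic study conditions (2000 genes, 40+40 samples, 10%
planted at a 2.0 log2-scale shift with unit noise SD), the procedure
recovers ≥ 95% of planted genes and passes < 2% of null genes — measured,
not assumed, in the acceptance checks.

## Promoter TFBS classification

A TF binding twice in one promoter counts once (one row per (TF, gene));
a hit spanning two overlapping promoters counts once per gene. A TF with
promoter hits in both overexpressed-gene sets is *generic*; in exactly one
set, *grade-specific*. Raw counts are normalized to occurrences per DE
gene (`raw / |set|`) — the simplest factor that makes sets of different
size comparable; the formula is a package choice and configurable. Family
rollup marks a family present in a set when any member TF has a positive
count there; families present in exactly one set are flagged unique.

Background caveat: at the fixed p < 1e-4 scan threshold, random sequence
yields near-consensus matches at roughly 2–5 per 10^5 windows. A planted
"grade-specific" motif can therefore acquire a chance hit in the opposite
gene set and classify as generic — on synthetic and on real genomes alike.
The planted-truth tests account for this: they verify that planted
instances never contribute to the opposite grade and that the end-to-end
classification matches an independent recount of the filtered hit set,
rather than asserting that background never collides.

## Enhancers and hypergeometric enrichment

Per-sample H3K27ac peaks are pooled and merged single-linkage on ≥ 1 bp
overlap; merged regions supported by < 2 distinct samples are discarded
(recurrence filter). Regions overlapping any TSS ± 3 kb window are then
removed — the exclusion radius is configurable; 3 kb (symmetric) is a
conventional promoter-proximal buffer. Enrichment of TF t inside
enhancers uses the 2×2 sampling scheme: population N = all motif
occurrences of all TFs (post-filter) genome-wide, successes K = TF t's
occurrences, draws n = all occurrences inside enhancers, observed k = TF
t's occurrences inside enhancers; p = P(X ≥ k) from the hypergeometric
upper tail, BH across TFs. The implementation is verified against direct
combinatorial enumeration for all populations N ≤ 12.

## Binned differential methylation

Beta = methylated/total reads per cytosine; cytosines under 10 reads are
dropped. The unit of observation for the region test is the covered
cytosine, pooled across samples within a group; per-sample medians are
retained for region summaries and methylation–expression correlation.
Pooled betas are binned into [0, 0.2], (0.2, 0.6], (0.6, 1.0] — closed on
the right, so beta = 0.2 is hypo- and 0.6 medium-methylated — and the
groups × bins table is tested with the classical (uncorrected) chi-square.
Bins with zero total are dropped first; regions left with fewer than two
occupied bins, or with a group contributing no cytosines, are flagged
untestable and excluded from the BH family (FDR across regions,
significant at adjusted p < 0.05).

Motif-centered windows extend each hit by ±20 bp (a 10 bp motif gives the
canonical 50 bp window; width follows the actual hit, so an 11 bp motif
gives 52 bp). C-rich regions are maximal sub-intervals of a window with
C-or-G density ≥ 0.5 over ≥ 5 bp (defaults are package choices, exposed in
the API); maximality means no strictly larger qualifying interval contains
the result, so overlapping maximal intervals can both be reported.

## Correlation layer

TF→target edges are scored by Pearson r between the TF's expression (or a
matched protein measurement) and each target across samples, two-sided
p-values from the exact t-transform with n−2 df, BH-adjusted per TF across
its targets (one family per analysis question). Records with < 3 matched
samples or zero variance are flagged and excluded from the family.

## Synthetic data: what it emulates, and what it does not

Each nuclear chromosome (default 2 × 1 Mb, plus a chrM decoy of the same
length carrying unrecorded motif instances) has a gene zone — TSS every
5 kb with jitter, 2000 expression genes of which ~400 fit on the genome —
and a gene-free distal zone holding enhancers (40 × 1 kb per chromosome).
Open chromatin comprises 200 bp Tn5-style windows at 60% of promoters (all
planted DE-gene promoters included), 100 distal 200 bp peaks per
chromosome, and the enhancers themselves; the two ATAC samples share this
design and add 5% sample-specific peaks each, which the reproducibility
filter removes. H3K27ac comes from 18 simulated tumors (8 + 10); each
enhancer appears in ≥ 2 of them with ±100 bp jitter, plus per-sample
singleton noise peaks and promoter marks that the TSS exclusion strips.

Motif instances are planted as exact consensus strings (strand uniform,
never overlapping another planted instance) so recovery is unambiguous;
matrices put 0.91 on the consensus base (≥ 18 bits of information at
L = 10), making planted-recall 1.0 a meaningful scanner check. Planting
roles: motif 1 (AP-1-like core TGAGTCA, bZIP) in promoters of grade-IV
planted genes and at 94 enhancer sites (mirroring the c-Jun enhancer
analysis); motif 3 in grade-II promoters; motif 2 at a 4× elevated rate in
enhancers; all others uniformly over accessible chromatin at 0.5/kb.

Expression is log-normal: per-gene baseline log2 mean U(2, 8), unit noise
SD, a +2.0 log2 shift in exactly one group for the 10% planted DE genes,
and a latent per-sample factor (loading 0.5) shared by the grade-IV
regulon so TF–target correlation holds within groups as well as between.
Methylation cohorts are 4 (GII) and 10 (GIV) samples; cytosines sit at
density 0.2/bp, coverage Poisson(20) with a 5% Poisson(5) low-coverage
admixture so the ≥ 10-read filter acts; reads are binomial with a
per-region, per-group constant probability — U(0.2, 0.8) shared by groups
under the null, 0.8 vs 0.1 in the 10% differential windows. Under this
model group bin counts are independent multinomials, and the measured
chi-square null type-I rate is within binomial error of 5%.

All randomness derives from one seed through named substreams (CRC32 of
the stream name folded into a `SeedSequence`), so generators are
bit-for-bit reproducible and adding one never perturbs another.

Not emulated: read-level artifacts (FASTQ, alignment, duplicates), linkage
and co-methylation structure, PWM-sampled (non-consensus) motif instances,
copy-number and purity effects, batch structure, and realistic
inter-sample peak variability beyond the jitter above. Passing tests
demonstrate the correctness and calibration of the statistical machinery
under these controlled conditions, not performance on real tumors.

## Problem sizes and determinism

The default simulated study (2 Mb nuclear genome, 8 motifs, 2000 genes,
80 expression samples, 14 methylation samples) runs the full pipeline in a
few seconds on one CPU; the acceptance script, which runs the pipeline
twice plus all oracle suites, completes in well under a minute. No
timestamps enter any artifact, so two runs with the same seed produce
byte-identical output trees (verified by SHA-256 over the directory).
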