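# Methods

`caprilinc` implements a genome-wide discovery pipeline for long intergenic
noncoding RNAs (lincRNAs) in goat (*Capra hircus*) transcriptomes, together
with the downstream spatial (tissue-panel) and temporal (hair-follicle
cycle) expression analyses. This note records the model behind each stage,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter when
reproducing results.

## Discovery cascade

Candidate transcript models (as assembled from RNA-seq) are classified
against the protein-coding reference annotation by position alone:

- **o** — any candidate exon shares ≥ 1 bp with any reference exon, on
  either strand. Strand is deliberately ignored: "intergenic" is a
  positional property, and a transcript overlapping a known gene on the
  antisense strand is an antisense lncRNA, not a lincRNA.
- **i** — inside a reference gene span with no exon overlap (intronic).
- **near** — no overlap, but < 500 bp from the nearest gene span.
- **u** — intergenic, ≥ 500 bp from every coding gene.

Distances are bp gaps between 1-based inclusive spans; a candidate whose
chromosome carries no reference gene is class *u* at infinite distance
(warned, not fatal).

Class-*u* candidates then pass an ordered filter cascade; survival is
inclusive at each printed threshold:

1. exon count ≥ 2 (single-exon models are unreliable assembly fragments);
2. FPKM ≥ 0.5 in at least one sample (`fpkm_mode="max"`; an `"all"` mode
   requiring every sample is provided, since per-sample assembly pipelines
   can be read either way);
3. distance to the nearest coding gene ≥ 500 bp (redundant after class-*u*
   selection but kept as an explicit, auditable stage);
4. spliced length ≥ 200 bp (the defining lncRNA length cut);
5. noncoding by the three-scorer consensus below.

The audit trail records (stage, n_in, n_removed, n_out) and chains
exactly. The stages after class-*u* commute with respect to the final
catalogue (the audit counts are order-dependent and reported as such); a
`stage_order` argument exposes this.

Multi-sample assemblies are merged before filtering: transcripts with
identical intron chains (identical exon chains for single-exon models)
collapse to the member with the longest spliced length, and same-strand
transcripts with ≥ 1 bp exonic overlap group into one gene; ids are
reassigned in deterministic genomic order.

## Coding-potential consensus

Three independent scorers stand in for the usual external classifiers,
combined by the same intersection logic:

- **ORF scorer** — longest ATG→stop open reading frame over the three
  forward frames (assembled transcripts are stranded, so reverse frames
  are not scanned). Coding iff ORF ≥ 300 nt or ORF coverage ≥ 0.5 of the
  transcript. 300 nt (100 codons) is the classical "small protein" cut.
- **Fickett TESTCODE** — the published statistic combining per-base
  positional asymmetry (max over the three phases of each base's count
  divided by min + 1) and composition, through the published lookup tables
  and weights. Coding iff score ≥ 0.95, the published coding cut.
- **Hexamer log-likelihood ratio** — mean log2 ratio of hexamer
  frequencies under coding vs noncoding training tables (all overlapping
  windows, N-windows skipped, pseudocount 1 over the 4^6 alphabet).
  Coding iff LLR > 0.

A transcript is accepted as noncoding only when **all three** scorers call
it noncoding (`rule="all_noncoding"`). The alternative reading — discard
only when all three call it coding (`rule="not_all_coding"`) — is provided
as a flag; the two differ for transcripts with split votes, and the
intersection rule is the stricter, default choice. The consensus is
monotone: making any score more coding-like can never turn a coding call
into a noncoding one.

## Tissue panel

Tissue-specificity uses per-tissue mean FPKM with an expressed threshold
of 0.5 (consistent with the discovery reliability cut; the panel itself
does not define "expressed"): a feature expressed in exactly one tissue is
labelled with that tissue, in ≥ 2 tissues `multi`, in none
`not_expressed`.

Hair-follicle (HF) high expression requires both a collective and a
per-tissue margin: HF mean ≥ 20 × the pooled mean of the other tissues'
means **and** HF mean ≥ 2.5 × every individual other tissue's mean. Zero
denominators pass; a feature silent in HF is never called.

Neighbor analysis pairs every lincRNA gene with every coding gene whose
span lies within 10 kb (boundary-inclusive, span-to-span gap). Pair
co-expression is the Pearson correlation of tissue-mean vectors
(tissue-level profiles, not per-sample values); linc–coding correlations
are compared against proximal coding–coding pairs and seeded random pairs
by two-sided asymptotic Kolmogorov–Smirnov tests. Zero-variance profiles
are dropped with a warning rather than propagating undefined correlations.

## Time course

The skin series covers five time points (May, Jun, Aug, Sep, Oct) × 3
biological replicates, spanning the early-anagen → anagen transition of
the secondary hair follicle between June and August.

**Differential expression.** For each of the 10 unordered time-point
pairs: log2FC = log2((mean_B + ε)/(mean_A + ε)) on FPKM with ε = 0.1 to
stabilize ratios at zero expression; p from a two-sample t-test on
log2(FPKM + 1); Benjamini–Hochberg correction across features within each
comparison; significant iff |log2FC| ≥ 1 and q ≤ 0.05. The pooled-variance
t is the default: under the homoscedastic Gaussian noise model on the log
scale it is exactly calibrated at three replicates, whereas Welch's
variant (available as `equal_var=False`) is noticeably conservative at
such small groups because of its estimated degrees of freedom. With zero
variance in both groups (noise-free data) the statistic is undefined; the
implementation takes the natural limit p = 0 for unequal means and p = 1
for equal means, which makes noise-free planted-truth recovery exact.

A feature significant in ≥ 1 comparison is *time-specific*; the
*transition subset* contains features significant **only** in the six
cross-block comparisons ({May, Jun} × {Aug, Sep, Oct}).

**PCA** operates on samples in log10(FPKM + 1) feature space with centered
features; explained-variance fractions sum to 1 over retained components.
**Hierarchical clustering** uses feature profiles of per-time-point means
of log10(FPKM + 1), distance 1 − Pearson r, complete linkage, and an exact
k-cluster cut (k = 5 by default) with clusters relabelled by descending
size (ties by smallest member id). The two figure-level transforms differ
on purpose: the tissue heatmap is log2(FPKM + 1) with per-tissue Z-scores,
the temporal analyses use log10 — both are configuration options.

**Enrichment** is standard over-representation: hypergeometric upper tail
P(X ≥ overlap) against a user-supplied universe, BH across terms. No GO
hierarchy handling and no proprietary multiple-testing scheme.

## qPCR

Relative quantification is 2^−ΔΔCt: technical replicates averaged first
(arithmetic Ct mean), ΔCt = Ct_target − mean(Ct of the reference assays)
— the arithmetic Ct mean equals the geometric mean of reference
quantities, the standard multi-reference normalization — then ΔΔCt
against a calibrator condition, with perfect amplification efficiency
(2.0) assumed and exposed as a parameter. A per-reference ΔCt-then-average
mode is provided; the two coincide at efficiency 2. RNA-seq concordance
converts both series to log2(value/value at the reference time point) and
reports a Pearson r per assay; an `offset` (default 1.0, i.e. FPKM + 1
abundance, matching the simulator's Ct model) keeps the inversion
identity exact, with a flagged 0.1 pseudo-value fallback for zeros at the
reference.

## Synthetic data: what it emulates, what it does not

The generator plants every structure the pipeline is designed to detect
and emits the ground truth alongside:

- a toy two-chromosome genome (2 × 4 Mb) with 80 non-overlapping coding
  genes (4–9 exons of 120–300 bp, introns 0.5–2.5 kb), inter-gene gaps
  drawn from a short/long mixture so that proximal coding–coding pairs
  exist;
- 150 candidate transcripts in a fixed class mix — 40% intergenic-far
  (≥ 500 bp), 10% intergenic-near (< 500 bp), 15% exon-overlap, 10%
  intronic, 15% single-exon, 10% short (< 200 bp) — each placed by
  rejection sampling and verified against its label by construction;
- two sequence regimes: coding-like candidates (20% of the far class)
  carry a GC-codon-biased ORF covering ~70% of the transcript; all other
  sequences are AT-rich with an 11-mer stop block (a stop codon in each
  reading frame) interleaved every ~18–30 bp, which bounds every possible
  ORF below ~45 nt *by construction* rather than by rejection;
- expression as FPKM = 2^x with x Gaussian (log-normal baseline, floor at
  FPKM 4 for planted features), tissue panel of 10 organs + HF (1 sample
  each) and the 5 × 3 time course; planted tissue-specific features (one
  positive tissue, exact zeros elsewhere), HF-high features (HF ≥ 64 FPKM
  vs others in [0.5, 2], clearing both fold rules with margin),
  cross-block DE features (±2 log2 units between May–Jun and Aug–Oct),
  five cluster templates (three down-shaped, two up-shaped, mutually
  separated in correlation distance), tissue-correlated neighbor pairs
  from a shared Gaussian latent factor (exact r = 1 at target 1; the
  log-normal transform attenuates intermediate targets, e.g. planted 0.9
  measures ≈ 0.85), and "spatiotemporal" lincRNAs that are simultaneously
  HF-high, up-template-shaped in time, and correlated with a ≤ 10 kb
  coding neighbor at an exactly constructed target r (0.95) over
  time-point means;
- noise is additive Gaussian on log2(FPKM + 1) (default sd 0.2),
  back-transformed and clamped at zero — the same transform the analysis
  uses; Ct tables are Ct = 30 − log2(FPKM + 1) with three technical
  replicates and optional Ct noise.

It does **not** emulate read-level artifacts (no FASTQ, alignment or
assembly errors), batch effects, library-size variation, count
overdispersion, ambiguous multi-mapping, or partially assembled
transcripts. Passing the noise-free identity tests therefore shows the
*logic* of every rule is implemented exactly as stated; it does not show
robustness to assembly noise, which is out of scope here.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full pipeline at the
generator defaults (150 candidates, 80 genes, 26 samples) and the
calibration studies at 2000 null features (false-positive rate), 500
features with 100 planted effects (power), 5 × 40 features (cluster
recovery), 200 pairs per side (co-expression dominance), and 12 assays
(qPCR round trip). These sizes give binomial/permutation noise well below
the decision margins while keeping a complete run in seconds.

## Known limitations

- The coding-potential scorers are deliberately desk-scale stand-ins: they
  reproduce the *consensus logic* and the classical statistics, not the
  trained models of the usual external tools; absolute sensitivities on
  real transcripts will differ.
- The fold-based HF rule and the expressed threshold are sharp cutoffs;
  features near a boundary flip under noise, which is why exactness is
  only claimed (and tested) in the noise-free regime.
- The DE test assumes homoscedastic Gaussian noise on the log scale;
  count-level overdispersion would call for a negative-binomial model
  instead.
- Correlation targets for tissue-level neighbor pairs are attained in
  expectation on the latent log scale; the FPKM-scale sample correlation
  is biased slightly toward zero for targets strictly between 0 and 1.
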