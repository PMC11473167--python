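# Methods

## Problem and model

mTECs present a broad repertoire of self-antigens; the analysis asks which
tissue-restricted antigen (TRA) genes depend on Prmt5, which on Aire, and
whether loss of expression is accompanied by failed pre-mRNA splicing. The
pipeline has five analytic stages, each usable on its own:

1. **Entropy-based TRA classification.** A gene's tissue specificity is the
   Shannon entropy of its normalized expression profile across a
   multi-tissue atlas, in bits. Entropy is computed on linear expression
   proportions, without a log transform of expression and without a
   pseudocount (`entropy.input_transform` is the place a different
   convention would plug in). The TRA threshold is strictly less than
   3.0 bits; 3 bits corresponds to uniform support over 8 tissues, so the
   rule reads "expressed in effectively fewer than eight tissues". Genes
   with an all-zero atlas row have no defined distribution; they are
   excluded from the classification universe and reported, rather than
   being assigned maximal entropy.
2. **Feature counting.** Gene models carry merged, sorted exons; introns
   are the gaps between consecutive merged exons. A read overlapping
   exactly one gene is intronic if it touches any intronic base —
   junction-spanning reads are direct evidence of a retained intron —
   exonic if it lies entirely inside the exon union, and otherwise
   unassigned (it hangs off a gene edge). Reads overlapping two or more
   genes are discarded as ambiguous rather than fractionally assigned;
   all discard classes are tallied so reads are conserved. Strand is
   ignored (unstranded protocol assumed). RPKM uses the sum of all
   assigned feature reads (exon + intron) as the library size
   (`rpkm.library_size_mode`): with intron-retaining transcripts in the
   library, "per million mapped reads" should include them.
3. **Differential expression and categorization.** Student's equal-variance
   t test (two-tailed) on log₂(RPKM + ε), ε = 0.01; the fold change is the
   ratio of linear group means with the same ε guarding a zero denominator.
   The log scale stabilizes the heavy right tail of RPKM; linear-scale
   testing is available (`log_scale=False`). Thresholds are strict
   (P < 0.05 together with FC < 0.5 or FC > 2), and no multiple-testing
   correction is applied at this per-gene stage — BH FDR enters only for
   the category-level retention comparisons. Expressed TRAs (mean control
   RPKM strictly > 0) are partitioned by the two down flags into
   TRA_Prmt5 / TRA_Aire / TRA_shared / TRA_other; summary percentages are
   rounded half away from zero to one decimal.
4. **Intron retention.** The retention index pools a genotype's replicates
   (ratio of summed intron reads to summed total reads) rather than
   averaging per-sample ratios; pooling is robust for low-count genes, and
   the mean-of-ratios alternative is kept as `retention.aggregation`.
   Single-exon genes have nothing to retain and are excluded and counted.
   Retention fold change adds ε = 1e-3 to both indices so zero-retention
   genes stay comparable; flag thresholds (> 1.5 increased, < 0.75
   decreased) are strict, giving three disjoint states. The per-gene
   panel applies a pooled-total ≥ 10 reads filter (inclusive) in the
   knockout being displayed.
5. **Diversity and statistics.** Shannon–Weaver H′ uses the natural log,
   the community-ecology default. Genotype comparisons use one-way ANOVA
   followed by Dunnett's many-to-one test against control (scipy's exact
   multivariate-t implementation, with its quasi-Monte Carlo stream
   pinned for reproducibility). Category-level retention comparisons are
   Wilcoxon signed-rank tests on per-gene (KO, control) index pairs —
   robust on a bounded, skewed ratio scale — with a paired t option; the
   family of category × contrast p values is BH-adjusted. Pearson's r
   uses the t transform with n − 2 df for its two-tailed p.

## Synthetic data generator

The generator emulates the study design: a genes × tissues atlas with
planted TRAs, gene models tiled on one synthetic chromosome, and
exon/intron counts for three genotypes × n replicates.

* **Defaults as study conditions.** 2,000 genes, 16 tissues, 25% TRAs with
  tissue breadth 1–3, four equiprobable dependence classes among TRAs,
  five-fold downregulation (`downreg_fc = 0.2`) of affected genes in the
  affected genotype(s), intron-read fraction rising 0.05 → 0.35 under
  splicing deficiency, three replicates per genotype, and per-gene
  expected depth drawn log-uniformly from 500–3,000 reads. The depth floor
  keeps every gene's retention index estimable; the study itself reports
  no library sizes, so these are desk-scale choices with comfortable
  power rather than a reconstruction.
* **Effect coupling.** For gene g in genotype G, expected total reads are
  baseline × downreg_fc if g is affected in G, split into intronic
  (μ·π) and exonic (μ·(1−π)) expectations. Splicing-deficient genes thus
  lose mature signal exactly as their intron fraction rises, building in
  the inverse retention–expression correlation the statistics then
  measure; recovery tests check the machinery, not the biology.
* **Noise model.** Counts are gamma-Poisson (negative binomial) with
  variance μ + αμ²; α defaults to 0.05, a typical between-replicate
  biological dispersion for bulk RNA-seq of sorted cells from inbred
  mice. α = 0 gives Poisson noise; `nb_dispersion=None` is a
  deterministic mode (counts = rounded expectations) for exact tests.
  Near the 1.5× retention-flag threshold, α = 0.05 puts the null
  fold-change distribution's upper tail at a few percent, so the false
  flag rate on unaffected genes sits near 5% and varies by noise
  realization — a property of the flag-by-threshold rule itself, which
  has no significance filter.
* **Silent and single-exon genes.** 5% of genes are silent in the mTEC
  compartment (exercising the expressed filter) and 10% of unaffected
  genes are single-exon (exercising the retention exclusion); both are
  drawn only from classes without knockout effects so every planted
  effect remains measurable.
* **Reads.** `simulate_read_intervals` realizes a count matrix as BED6
  intervals placed fully inside exons or introns (length-weighted choice
  of feature, 50 bp reads), so re-counting reproduces the matrix
  bit-exactly — a closed loop that tests the counting module. No
  sequence-level simulation (no FASTQ, no error model) is attempted.
* **Reproducibility.** One global seed drives named substreams ("truth",
  "atlas", "models", "counts", "reads") via `SeedSequence([seed,
  crc32(name)])`, so each generator can be re-run independently with
  bit-identical output.

What the generator does **not** emulate: mappability and GC biases,
gene-length–dependent coverage, correlated co-regulation, partial splicing
deficiency gradients, isoform structure, or single-cell heterogeneity
(the mTEC^lo compartment's known heterogeneity is collapsed into a bulk
profile). Passing recovery tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance
on real sequencing data.

## Numerical choices and degenerate inputs

* Strict inequalities at every printed threshold (entropy < 3.0,
  P < 0.05, FC < 0.5 / > 2, retention FC > 1.5 / < 0.75, mean RPKM > 0);
  the read-count filter is inclusive (≥ 10).
* Identical constant groups in the t test get p = 1 (a non-result) rather
  than NaN; genes that are constant zero on both sides are flagged
  untestable and excluded from flags.
* Undefined retention indices (zero group total, single-exon genes)
  propagate as NaN and never enter flags or tests; Wilcoxon comparisons
  with all-zero differences report p = 1.
* BH q values are computed within the family of non-NaN p values; NaNs
  pass through.
* Abutting exons merge (zero-length gaps are not introns); GTF's 1-based
  inclusive coordinates are converted to 0-based half-open at the parser
  boundary only.
* Percentages are rounded half away from zero to one decimal via decimal
  arithmetic, avoiding binary-float round-to-even artifacts.

## Pipeline and configuration

`run_pipeline` executes the stages in order from a `PipelineConfig`
(YAML-loadable, validated by explicit dataclass checks), persists every
intermediate TSV plus a `report.json`, and is bit-reproducible for a given
config and seed. Exactly one input mode applies per run: `simulate`
(default) or `files` (atlas/design TSVs plus either a counts TSV or GTF +
BED). When simulating, the report additionally carries recovery metrics
against the planted truth: macro-averaged per-class recall (balanced
accuracy) over the four TRA categories, retention-flag sensitivity on
planted splicing-deficient genes, and the false-flag rate on planted
unaffected TRAs. Figures are presentational only and add no numbers.

The test suite and the acceptance script use scaled-down instances
(150–300 genes for unit and null-calibration work, 50 genes for the BED
round trip, the full 2,000-gene default for recovery), sizes chosen so the
whole suite runs comfortably on a laptop.

## Known limitations

* The intron retention index is gene-level; no per-intron PSI, junction
  analysis or isoform quantification.
* Counting interprets pre-placed read intervals, not alignments: no
  BAM/CIGAR handling, by design.
* Dunnett comparisons assume approximately normal, equal-variance group
  values; with 3 replicates per group this is an assumption, not a
  verified property.
* The flag-by-fold-change retention rule has no significance component,
  so its false-positive rate depends directly on count depth and
  dispersion (see the noise-model note above).
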