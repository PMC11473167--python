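# trasplice

Analysis of promiscuous self-antigen expression and pre-mRNA splicing in
thymic epithelial cells.

Medullary thymic epithelial cells (mTECs) ectopically express thousands of
tissue-restricted antigens (TRAs) — genes normally confined to one or a few
peripheral tissues — to tolerize developing T cells. This expression depends
partly on the transcriptional facilitator Aire, and partly on efficient
pre-mRNA splicing supported by the arginine methyltransferase Prmt5.
`trasplice` implements the computational side of dissecting that dependence
from bulk RNA-seq of sorted mTEC populations across control, Prmt5-cKO and
Aire-KO genotypes, together with a synthetic-data generator with planted
ground truth so the whole pipeline is testable without any download.

## What it computes

* **TRA classification.** Each gene in a genes × tissues expression atlas is
  scored by the Shannon entropy of its expression distribution,
  H(g) = −Σ_t p_t log₂ p_t with p_t = x_t / Σ x_t; genes with H < 3.0 bits
  (roughly: supported by fewer than 2³ = 8 tissues) are TRAs.
* **Exon/intron counting and RPKM.** Read placements (BED6) are assigned to
  gene models (GTF): a read touching any intronic base is intronic, a read
  entirely inside the merged exon union is exonic, multi-gene reads are
  discarded as ambiguous. Expression is RPKM = 10⁹ · exon reads /
  (library size × exonic length).
* **Dependence categorization.** Per gene, each knockout is compared with
  control by an unpaired two-tailed Student's t test on log₂(RPKM + 0.01);
  a gene is downregulated when P < 0.05 and fold change < 0.5. Expressed
  TRAs are partitioned into TRA^Prmt5 (down only in Prmt5-cKO), TRA^Aire
  (down only in Aire-KO), TRA^shared (down in both) and TRA^other.
* **Intron retention.** The per-gene intron retention index is
  intron reads / (exon + intron reads), pooled over a genotype's
  replicates; a knockout/control retention fold change > 1.5 flags
  increased retention, < 0.75 decreased, over genes with ≥ 10 reads.
* **Diversity and association statistics.** Per-sample Shannon–Weaver
  diversity H′ = −Σ p_i ln p_i of the expressed TRA repertoire, one-way
  ANOVA with Dunnett many-to-one comparisons, Pearson correlation between
  retention change and expression change, and Benjamini–Hochberg FDR over
  families of category-level retention comparisons.

## Worked example

```python
from trasplice import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, out_dir="demo_run")
res = run_pipeline(cfg)
stages = res.report["stages"]
print("TRA genes (entropy < 3.0):", stages["classify"]["n_tra"])
print("expressed genes:", stages["diffexpr"]["n_expressed"])
print("category counts:", stages["categories"]["counts"])
print("retention vs expression r:",
      round(stages["stats"]["retention_vs_expression"]["r"], 3))
```

which prints:

```
TRA genes (entropy < 3.0): 500
expressed genes: 1900
category counts: {'TRA_Prmt5': 114, 'TRA_Aire': 129, 'TRA_shared': 133, 'TRA_other': 117}
retention vs expression r: -0.982
```

The default simulation plants 2,000 genes (25% TRAs, 5% silent in mTECs)
and three replicates per genotype. All 500 planted TRAs are recovered from
the atlas; the 1,900 genes with positive mean control RPKM pass the
expressed filter; the four dependence classes are recovered from the
knockout contrasts; and the Pearson r ≈ −0.98 reflects the built-in
coupling between expression loss and intron retention gain in
splicing-deficient genes. Every table is persisted as TSV under
`demo_run/`, with a machine-readable `report.json`;
`trasplice run --seed 1 --out-dir demo_run --figures` does the same from
the shell and renders scatter/heatmap/bar/PCA panels.

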