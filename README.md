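# tfdep

Identifying **cofactor-dependent transcription-factor target genes** from an
inducible factorial experiment that combines RNA-seq, ChIP-seq and
quantitative interactome proteomics.

The motivating setting is epithelial–mesenchymal transition (EMT) in breast
cancer models: an EMT transcription factor (e.g. SLUG) is induced with and
without knockdown of a chromatin cofactor (e.g. the NELF-E subunit of the
negative elongation factor complex), and the question is *which induced
genes are direct, cofactor-dependent targets*. `tfdep` implements the
integrative downstream analysis for this design — it consumes count
matrices, peak files and TMT intensity tables (alignment, quantification
and peak calling are upstream tools' jobs) and ships a fully specified
synthetic-data generator so every stage is testable without any download.

## The analysis

Given a 2×2 genotype × treatment design (`SCR`/`KD` × `Con`/`Dox`):

1. **Differential expression.** Per-contrast tables (gene, log2FC, p,
   BH-adjusted p). External tables (e.g. a DESeq2 export) are accepted
   as-is; a built-in surrogate (median-of-ratios normalization, Welch's t
   on log2 counts, Benjamini–Hochberg) makes the pipeline self-contained.
   Genes are categorized **UP** iff adj-p ≤ 0.05 and FC ≥ 1.5, **DOWN**
   symmetrically.

2. **Knockdown impact score.** For each gene,

   ```
   IS = log2FC(KD+Dox vs KD−Con) − log2FC(SCR+Dox vs SCR−Con)
   ```

   A negative IS means the knockdown attenuates activation. Genes that are
   UP in the control genotype **and** have IS ≤ −log2(1.5) (≥1.5-fold
   reduction in activation) are *impaired*.

3. **Peak co-occupancy and annotation.** Co-bound peaks are TF peaks
   sharing ≥1 bp with a cofactor peak (`bedtools intersect -u` semantics,
   0-based half-open). Peaks are annotated to the nearest TSS within 10 kb
   (midpoint distance) and classified promoter / gene body / distal.
   Condition-specific peaks are the presence/absence decomposition of two
   conditions of one factor.

4. **Target selection.** Dependent direct targets = impaired genes ∩ genes
   with a co-bound peak, sorted most-impaired first.

5. **Enrichment statistics.**
   - *Exact multi-set intersection test*: the null law of an m-way
     intersection of independent uniform fixed-size subsets of an
     N-universe, computed by iterated hypergeometric conditioning in log
     space (reduces to the hypergeometric tail for m = 2); reported as
     observed, expected = N·∏(nᵢ/N), fold and upper-tail p.
   - *Observed/expected chi-square* on the 2×2 co-bound × lost/retained
     peak table (1 df, no continuity correction, log-space tail).
   - Hypergeometric over-representation (ORA), preranked GSEA (weighted
     running-sum ES, gene-label permutations), Spearman correlation, BH.

6. **qPLEX-RIME interactome.** TMT channels are normalized to equal total
   intensity; bait-vs-IgG enrichment and induced-vs-control rewiring are
   tested per protein with a moderated t (empirical-Bayes variance
   shrinkage); calls use |log2FC| ≥ 0.5 and adj-p < 0.05.

## Worked example

Run the whole pipeline on the default synthetic study (5,000 genes, 40
planted cofactor-dependent co-bound genes, 500 proteins with 30 planted
bait interactors):

```sh
tfdep run-all --seed 7 --outdir out/
```

The summary (`out/summary.json`) reports, among others:

```
"n_up": 393, "n_down": 372,          # induced/repressed genes (UP/DOWN)
"n_impaired": 39,                    # UP genes with IS <= -log2(1.5)
"n_targets": 39,                     # impaired ∩ co-bound  -> target list
"peaks": {"n_cobound_peaks": 50, "frac_promoter_cobound": 0.8, ...},
"cobound_loss_chi2": {"oe_ratio": 4.47, "chi2": 44.36, "log10_p": -10.56},
"target_overlap_test": {"observed": 39, "expected": 0.31, "fold": 125.0},
"qplex": {"n_enriched": 30, "n_rewired_up": 10, ...},
"recovery": {"target_sensitivity": 0.975, "target_precision": 1.0, ...}
```

Reading: of 393 induced genes, 39 lose ≥1.5-fold of their activation under
knockdown; all 39 carry a TF–cofactor co-bound peak within 10 kb of their
TSS, a 125-fold enrichment over chance. Co-bound TF peaks are lost upon
knockdown 4.5× more often than expected under independence, and 80% of
co-bound peaks sit at promoters. Against the recorded ground truth this
recovers 39/40 planted targets with no false positives.

Every stage is also exposed standalone (`tfdep simulate`, `tfdep de`,
`tfdep score`, `tfdep peaks intersect|subtract|diffbind|annotate`,
`tfdep stats superexact|chisq|ora|gsea|spearman`,
`tfdep qplex normalize|enrich|contrast`) and as plain library functions.

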