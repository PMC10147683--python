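# Methods

## Study design and scope

`tfdep` operates on the downstream artifacts of an inducible factorial
experiment: a gene × sample count matrix over the four cells SCR−Con,
SCR+Dox, KD−Con, KD+Dox (scrambled control vs cofactor knockdown, each
with and without induction of the transcription factor), peak sets for the
TF and its cofactor in the control and knockdown genotypes, gene models
(TSS + strand), gene-set collections, and a protein × channel TMT
intensity matrix from a chromatin pull-down with bait and IgG channels in
both conditions. Read alignment, expression quantification, peak calling
and spectral search are deliberately out of scope; their outputs are the
package's inputs.

## Differential expression surrogate

The scoring stage consumes any per-contrast table with columns
`gene_id, log2fc, p, adj_p` — in a real analysis this would come from a
dedicated DE fit such as a negative-binomial GLM. The built-in surrogate
keeps the pipeline self-contained:

- **Size factors**: median-of-ratios over genes expressed in every sample,
  rescaled to geometric mean 1. Like all median-of-ratios estimators it is
  unbiased only while differential genes are a minority or balanced in
  direction; a strongly one-directional DE composition shifts the null
  gene ratios' median by ~0.43·CV (the null genes' median must reach the
  (0.5)/(1−f) quantile of the noise distribution at DE fraction f).
- **Contrast**: per gene, log2FC = mean log2(normalized count +
  pseudocount) difference between the two cells (pseudocount 1.0, needed
  for zeros); p from Welch's two-sample t on the per-sample log values;
  BH adjustment. When both groups have zero variance, p = 1 for equal
  means and 0 otherwise.
- No dispersion or fold-change shrinkage, by design: the package's
  contribution is the downstream integration, not DE methodology.

## Gene categorization and the impact score

UP: adj-p ≤ α (0.05) and log2FC ≥ log2(1.5); DOWN mirrored; thresholds are
applied *inclusively* everywhere and recorded in output metadata (source
conventions vary between ≤ and < at the boundary; one convention is used
throughout and exposed as configuration).

The knockdown impact score is the difference of induction responses,

IS(g) = log2FC_KD(g) − log2FC_SCR(g),

where each term contrasts induced vs uninduced within one genotype. IS is
antisymmetric under swapping the contrasts. "Impaired" genes are UP with
IS ≤ −log2(1.5) ≈ −0.585; with cutoff −∞ the filter returns exactly the UP
set. Dependent targets are impaired genes whose annotated peaks are
co-bound, ordered by ascending IS with lexicographic gene-id tie-break.
The log2FC entering IS is taken exactly as reported by the DE stage, with
no additional rescaling; genes missing from either contrast are dropped
and counted, not imputed.

## Interval logic

All coordinates are 0-based half-open; two intervals overlap iff
max(starts) < min(ends) (≥1 shared bp). Co-occupancy follows unique-report
semantics: each query interval overlapping ≥1 subject interval is reported
once with its original coordinates; the complement operation returns
queries with zero overlaps, and the two partition the query set. The
implementation is a per-chromosome sorted sweep using running maxima of
subject interval ends (O((n+m) log(n+m))); the test suite pins it to an
O(n·m) all-pairs oracle on fuzzed inputs.

Condition-specific peaks are presence/absence differences of two peak sets
of one factor — an interval-level simplification chosen because signal
tracks are out of scope; a signal-based differential binding analysis
could reclassify peaks whose occupancy changes quantitatively but not
categorically.

Annotation assigns each peak to the gene minimizing |midpoint − TSS| when
that minimum is ≤ the window (default 10,000 bp). The midpoint
`floor((start+end)/2)` is used because summit offsets are absent from
plain BED input. Exactly equidistant TSSs resolve to the lexicographically
smaller gene id. Context: promoter iff midpoint within TSS ± 3,000 bp of
any gene (the conventional "≤3 kb" promoter class, configurable); else
gene body when spans are provided; else distal. Peak-level co-occupancy is
asymmetric (query coordinates are reported), so the gene-level co-bound
set unions both query directions, making it symmetric in its arguments.

## Enrichment statistics

**Exact multi-set intersection test.** Under the null, each of the m sets
is an independent uniform random subset of fixed size nᵢ from a universe
of N elements. The law of the running intersection is obtained by
conditioning: |A₁| = n₁ with certainty, and given |A₁ ∩ … ∩ Aₖ| = i that
intersection is itself a uniform i-subset, so
|A₁ ∩ … ∩ Aₖ₊₁| | i ~ Hypergeom(N, i, n₍ₖ₊₁₎). Iterating the mixture
yields the exact m-way pmf; the upper tail is accumulated with log-space
arithmetic so p-values far below double underflow (10⁻²⁶⁰ and beyond)
retain their magnitude. Expected size is N·∏(nᵢ/N) and the fold is
observed/expected. For m = 2 this reduces exactly to the hypergeometric
upper tail (pinned to 1e−10 relative in tests); for m = 3 it is validated
against a 10⁶-draw Monte-Carlo oracle.

**Observed/expected chi-square.** Pearson chi-square on a 2×2 table with
1 df and no continuity correction (appropriate in the large-count,
extreme-significance regime this pipeline encounters); the focal-cell
observed/expected ratio quantifies, e.g., how much more often co-bound
peaks lose TF binding after knockdown than independence predicts. The tail
is computed as log P = log 2 + log Φ̄(√χ²) via the normal log-survival
function, which stays finite where a direct chi-square survival lookup
underflows.

**ORA.** Upper-tail hypergeometric on |query ∩ set| within an explicit
universe, BH across the collection. The universe is always a required
argument — enrichment folds are meaningless without it.

**Preranked GSEA.** Genes sorted by decreasing score; hits add
|score|/Σ|score over hits| (weight exponent 1), misses subtract 1/(N−k);
ES is the maximum signed deviation of the running sum. Because the sum
decreases linearly between hits, every extreme occurs immediately before
or after a hit, so ES is computed in O(k) per evaluation; permutations are
vectorised in batches. The null is gene-label permutation (random same-size
sets — the appropriate null for preranked input), with
p = (1 + #{same-sign perms, |ES| ≥ |ES_obs|}) / (1 + #same-sign perms).
A set covering the whole ranked list has no miss steps; ES is defined +1
and flagged degenerate. Desk default 10,000 permutations (configurable up
to the 10⁶ used for publication-grade p-values; the pipeline stage default
is 2,000 to keep an end-to-end run interactive). No NES normalization
across set sizes is attempted.

**Spearman.** Mid-rank correlation; two-sided p by the t approximation for
n ≥ 10 and exact enumeration of all n! rank permutations below.

**BH.** Step-up adjusted values adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j capped at 1;
NaNs propagate without counting toward m. Cross-checked against
statsmodels in the test suite.

## TMT interactome

Channels are scaled so every total equals the mean pre-normalization total
(idempotent; factors reported). Per-protein tests operate on
log2(intensity + 1): bait vs IgG within a condition (IgG pooling across
conditions is a switch, default per-condition) and induced vs control on
bait channels. The pooled within-group variance s²(d residual df) is
shrunk toward a prior: s²_mod = (d·s² + d₀·s₀²)/(d + d₀), with (d₀, s₀²)
estimated by method of moments on log s² (var log s² = ψ′(d/2) + ψ′(d₀/2),
the limma-style moment identity) when ≥10 finite variances are available,
else fixed at d₀ = 4; t has d + d₀ df. Calls: enriched iff log2FC ≥ 0.5
(inclusive) and adj-p < 0.05 (strict), depleted symmetrically.

*Known limitation*: total-intensity normalization carries composition
bias. When strongly rewired proteins inflate the induced-condition bait
totals, all null proteins acquire a small negative shift in the condition
contrast (≈ −0.2 log2 units in the default simulation), which can produce
a few spurious "depleted" calls. This is a property of the normalization
scheme itself and is left visible rather than corrected, since the
enrichment and rewiring sensitivity targets are unaffected.

## Synthetic data generator

The generator defines the reference study conditions; all defaults are
fixed once in `SimulationConfig`:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_chroms / chrom_length | 5,000 / 5 / 100 Mb | synthetic genome `chrS1..chrS5`; ~100 kb gene spacing so promoter neighbourhoods and background space are well separated |
| samples_per_cell | 3 | replicates per factorial cell |
| nb_dispersion | 0.01 | shared NB dispersion, var = μ + 0.01 μ² (CV 10%, clean cell-line replicates; chosen so the unmoderated Welch surrogate retains power a shrinkage-based DE fit would otherwise supply) |
| base_mean_log2 / base_sd_log2 | 8 / 1 | log2 baseline expression per gene |
| frac_up / frac_down, lfc_up / lfc_down | 0.08 / 0.08, +2 / −2 | planted induction-responsive genes |
| frac_dependent / attenuation_lfc | 0.10 / 1.5 | 10% of up genes (40) lose 1.5 log2 units of activation under knockdown → true IS −1.5 |
| frac_cobound | 1.0 | dependent genes carrying an overlapping TF+cofactor promoter peak pair |
| n_background_peaks / peak_width | 2,000 / 400 bp | per factor, on a 2×width slot grid ≥12 kb from every TSS (≥1 peak-width gaps guaranteed) |
| loss_cobound / loss_noncobound | 0.44 / 0.07 | TF-peak loss rates in the knockdown, co-bound vs background |
| TMT | 500 proteins, 30 enriched (lfc 2), 10 rewired (lfc 1.5), noise σ 0.3, channel scale 0.7–1.4 | 3+3 bait, 2+2 IgG channels |

Counts are gamma-Poisson draws (μ from baseline + planted effects ×
log-uniform [0.7, 1.4] library factors); each modality uses its own RNG
stream derived from the master seed, so outputs are byte-identical per
config and modalities regenerate independently.

What the generator emulates: planted condition- and genotype-dependent
fold changes, promoter co-binding at dependent genes, preferential
knockdown loss at co-bound sites, bait enrichment and condition rewiring
in the interactome. What it does not: gene-wise dispersion variation,
correlated genes, overlapping/nested gene structures, peak-width and
summit variability, signal-intensity gradients, peptide-level effects.
Passing recovery tests therefore demonstrates the integration logic is
correct under the stated statistical structure — not that the surrogate DE
or moderated tests match a specific production DE/limma fit on real data.

## Numerical and reproducibility choices

- All tails that can underflow are carried in log space (multi-set test,
  chi-square, GSEA p with +1 correction so permutation p > 0).
- All stochastic operations take explicit seeds; the pipeline funnels every
  seed through its config and writes the resolved config next to the
  outputs. Running twice on one config produces byte-identical summaries.
- Ties: IS ordering and equidistant-TSS assignment break ties by gene id;
  BH uses a stable sort.
- Degenerate inputs are errors, not silent defaults: empty universes,
  zero-total channels, sets exceeding the universe, constant vectors in
  rank correlation, <2 replicates per contrasted cell.
- Problem sizes in the acceptance checks (5,000 genes, ~2,000 peaks per
  factor, 500 proteins, 10⁶ Monte-Carlo draws, 200×10⁴ GSEA permutations)
  were chosen as the smallest sizes at which the binomial/Monte-Carlo error
  bands in those checks are meaningfully tight.
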