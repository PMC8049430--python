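# Methods

## The specificity score

For a gene measured over N ≥ 2 conditions, let TPM_t be its normalized
expression in condition t and p_t = TPM_t / Σ_u TPM_u its expression
fraction. The score is

    S = Σ_t p_t · log₂(p_t · N) = log₂ N − H(p)     [bits]

with 0·log₂ 0 := 0 and H the Shannon entropy of p in bits. S is the
Kullback–Leibler divergence of p from the uniform profile: 0 when the gene
is expressed identically everywhere, log₂ N when it is expressed in exactly
one condition. This is the orientation used by expression-specificity tools
such as BioQC's `entropySpecificity`: *low* values mean constitutive
expression, *high* values condition-specific expression. The identity
S + H(p) = log₂ N is asserted in the test suite. Scores are clamped at 0
against floating-point underflow; the analytic range [0, log₂ N] is a tested
invariant.

A gene with zero counts in every condition has no fraction profile. Its
score is undefined — reported as `NA` with class `excluded`, and carried in
a dedicated excluded-gene list — rather than 0 or NaN-propagated, because
"never observed" is categorically different from "uniformly expressed".

A convenience `normalized_specificity` divides by log₂ N to give a scale-free
score in [0, 1]; the unnormalized score in bits is primary throughout.

## TPM normalization

Gene-level counts are divided by gene length (bp) to per-base rates, and
each condition column is rescaled so its rates sum to 10⁶. Columns with zero
counts for every gene yield all-zero TPM columns with a warning instead of
an error: such columns contribute p_t = 0 to every gene and change no score,
but silently renormalizing them would fabricate observations. No other
library-size normalization (CPM, FPKM, size factors) is offered; the score
only consumes within-gene fractions, for which TPM's within-column
normalization is what matters.

## Replicate merging

Replicate samples belonging to one condition are merged by summing their
count columns. Gene-level read counts are additive over reads, so this is
exactly equivalent to merging alignment files before counting; the identity
"per-gene totals are conserved by merging" is tested exactly on integers.

## Classification

Defined scores are split at a threshold of 1 bit (parameter): S ≤ 1 is
`constitutive-like`, S > 1 is `condition-specific`. The boundary itself is
read as constitutive-like (strictly "above one" is specific). One bit is a
natural default — the divergence of a profile that concentrates half its
mass in one condition pair — and in large compendia tends to split the
genome roughly 70/30.

## Gene-set benchmarking

`geneset_scores` never drops identifiers silently: set members absent from
the table and members with undefined scores are returned as explicit lists.
Score densities use a Gaussian kernel (scipy's `gaussian_kde`) with Scott's
rule by default (Silverman or a fixed bandwidth in bits may be supplied),
evaluated on a 512-point grid spanning the data ± 3 bandwidths so the
trapezoidal integral is ≈ 1. Constant score lists raise a dedicated error
suggesting a rug-only display instead of returning a delta-like density.

Heatmap matrices are log₂(TPM + pseudocount) with a default pseudocount of 1
(so zero TPM maps to 0); rows ascend by score with ties broken by gene ID,
making ranked outputs reproducible. Column categories come from the
condition table's closed vocabulary {Metabolism, Development, Light
Response}. Rendering (colormaps, the brown-to-green score sidebar, the
category bar) is cosmetic and configurable; all tests compare the numeric
exports, never raster bytes.

`extreme_genes` selects the k lowest- and k highest-scoring genes by full
sort with the same ID tie-break; excluded genes are never selected and
fewer than 2k scored genes is an error.

## Synthetic data generator

The generator emulates the structure the analysis assumes in a real
genes × conditions compendium, not any particular organism's data:

- **constitutive** genes: one expected count in all conditions;
- **induced** genes: baseline everywhere, multiplied by `induction_fold` in
  `n_induced_conditions` randomly chosen conditions;
- **single-condition** genes: zero expected count everywhere except one
  uniformly chosen condition (these pin the analytic maximum log₂ N in
  end-to-end tests);
- **silent** genes: exactly zero counts (these exercise the exclusion path).

Counts are negative binomial — the standard overdispersed model for bulk
RNA-seq counts — with size parameter `dispersion` (variance m + m²/size) and
mean `base_mean × length_g / mean(length) × multiplier`. Scaling the mean by
gene length makes TPM normalization non-trivial: without it, TPM would be a
constant rescaling of counts and length bugs would be invisible. Gene
lengths are uniform integers on `length_range`. One top-level seed drives a
single generator stream (simplicity over partial reproducibility), so equal
seeds give bit-identical matrices.

Defaults: 97 conditions; class mix 70 / 20 / 9 / 1 percent
(constitutive / induced / single-condition / silent), echoing the roughly
70/30 low/high-score split and the ~1% unscoreable fraction observed in a
real genome-wide fungal compendium; `base_mean` 100 (a well-measured gene);
`dispersion` 10 (moderate bulk-RNA-seq overdispersion); `induction_fold` 100
in 2 of 97 conditions (a strong, narrow induction); lengths 500–5000 bp.
Recovery tests run at these settings with 5000 genes, a size chosen so the
full matrix (≈ 0.5 M negative-binomial draws) generates and scores in
seconds.

What the generator does **not** emulate: replicate-level structure, mapping
artifacts, batch effects, GC/length biases beyond the mean scaling, and
correlation between conditions. Passing recovery tests therefore shows the
scoring machinery is correct under its own assumptions — not that the score
is robust to real-data confounders.

## Recovery metrics

`recovery_metrics` reports the median score per true class (absent classes
reported as absent, not zero), the AUROC of the score as a discriminator of
induced-or-single-condition vs constitutive genes (via
`sklearn.metrics.roc_auc_score`), and the fraction of silent genes the
metric excluded, which must be exactly 1.0 for a correct pipeline. At the
default generator settings the separation is total (AUROC 1.0): a 100-fold
induction in 2 of 97 conditions lifts an induced gene's score to ≈ 3 bits
while constitutive genes sit near 0.1.

## Numerical and format choices

- Logarithms are base 2 throughout; scores are in bits.
- Entropy tables are written at 12 significant digits so a write/read
  round-trip reproduces scores to well below 1e-9; undefined scores are
  written as `NA`.
- featureCounts dialect: `#` comment lines are skipped; the six annotation
  columns `Geneid Chr Start End Strand Length` are required but only
  `Geneid` and `Length` are consumed; tab- and whitespace-delimited tables
  are both accepted; sample headers that are file paths are reduced to their
  basename with any `.bam`/`.sam`/`.cram` extension stripped, so they match
  bare run accessions in condition tables.
- Identifier translation (e.g. NCU accessions → assembly gene IDs) is an
  explicit, optional two-column map; untranslatable IDs are reported
  alongside the set, never silently dropped.
- The score histogram uses 0.25-bit bins by default (parameterized); bin
  counts sum to the scored-gene total.
- No statistical test is attached to gene-set comparisons: the benchmark
  surface is the score distributions themselves (densities, ranked
  heatmaps), and formal two-sample testing is out of scope.

## Limitations

- The score ignores absolute expression level: a gene detected at 2 TPM
  everywhere and one at 2000 TPM everywhere both score 0. Filter on
  expression first if that distinction matters.
- With few conditions (small N) the score's range [0, log₂ N] is narrow and
  sampling noise dominates; the tool refuses N < 2 and users should be
  cautious below N ≈ 10.
- TPM does not remove composition effects between conditions; a handful of
  extremely induced genes slightly deflate every other gene's fraction in
  that condition.
- No quality-control filter (e.g. on mapping rate) is applied to input
  samples; curating the input compendium is the user's responsibility.
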