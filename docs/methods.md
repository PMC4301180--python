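# Methods

## Scope and data model

The package analyzes a genes × samples matrix of linear-scale,
non-negative hybridization intensities with a design of K time points
(default 0, 1, 3, 8, 24 h; 0 h is the untreated control) and r biological
replicates per time point (r ≥ 2, default 3). Gene-level metadata —
TAP family membership, orphan status, GO terms — arrive as precomputed
annotation; the package neither computes orthology nor reasons over the
GO graph (terms are tested as annotated, without parent propagation).

## Differential-expression calling

1. **Median normalization.** Each sample column is rescaled
   multiplicatively so its median equals the grand median of all
   per-sample medians. This preserves within-sample rank order and assumes
   most genes are unchanged; a column with median 0 is rejected as a
   degenerate array. (Consequence worth knowing: if a large, sign-biased
   share of genes truly changes, the normalization itself shifts fold
   changes — the synthetic tests therefore keep planted effects either a
   small minority or sign-balanced.)
2. **Per-gene one-way ANOVA**, fixed effects, F(k−1, N−k). Computed by the
   closed-form sums-of-squares identity, vectorized across all genes.
   Degenerate inputs are defined, not dropped: a gene with zero within-
   and between-group variance reports F = 0, p = 1; zero within- with
   positive between-group variance reports p = 0.
3. **BH step-up** across genes (statsmodels); genes with adjusted
   p < α (default 0.05) enter post-hoc testing. Genes failing the gate are
   marked `not_tested` — their pairwise fields are missing, not p = 1.
4. **Tukey HSD** for all k(k−1)/2 time-point pairs with the gene's pooled
   within-group mean square. The studentized-range upper tail is evaluated
   by a Gauss–Legendre double quadrature (64 nodes over the normal-range
   integral, 48 over the chi scale factor), accurate to ≈1e−9 over the
   practical (k, df) range — orders of magnitude below the 1e−6 target —
   and fast enough to score tens of thousands of pairs per second. The
   within-gene multiplicity of the pairs is handled by Bonferroni
   (multiply by the number of pairs, cap at 1); the across-genes burden is
   already carried by the BH gate. This two-level reading of
   "Tukey with Bonferroni correction" is a design decision: the
   alternative (Bonferroni across genes) would double-count the gene-level
   correction.
5. **Fold change** is the ratio of normalized linear group means,
   mean(later)/mean(earlier). A DEG for a pair is a gene that passed the
   BH gate and whose Bonferroni-corrected Tukey p is below the pairwise α
   (default 0.05, the stricter 0.01 screen is the same code path with a
   different α). Its direction is *induced* if the fold change exceeds 1,
   *repressed* below 1; the measure-zero case of a significant pair with
   fold change exactly 1 is counted in neither direction, so
   `n_induced + n_repressed = n_deg` holds by construction in every
   summary. *Persistently induced* means induced in every control-vs-t
   comparison (and analogously for repressed).

## Enrichment

`fisher_2x2` returns exact hypergeometric tail sums and the
minimum-likelihood two-sided p (sum of all tables with the observed
margins whose point probability is at most that of the observed table,
with 1e−7 relative slack in the comparison) — numerically identical to
`scipy.stats.fisher_exact` and verified in the tests against an
exact-rational enumeration oracle. Note that on a discrete support the
two-sided p can exceed twice the smaller tail, though never by more than
the shared point mass. Term enrichment runs one test per annotated term,
BH across terms, with the direction of significant terms taken from the
smaller one-tail. The default universe is all genes of the input matrix.

Stage partitioning maps each non-control time point to early (1, 3 h),
intermediate (8 h) or late (24 h); a stage's gene set is the union of
control-vs-t DEG calls over its time points, so stages may overlap. For
the orphan stage *test*, disjoint sets are required, and each DEG is
assigned to its **earliest** significant control comparison; early
= {1, 3 h} vs later = {8, 24 h}. The stage contrast is one-sided (orphan
share higher early), the induced-vs-repressed contrast two-sided; genes
induced at one time point and repressed at another are dropped from the
direction contrast. Printed percentages use round-half-away-from-zero at
the requested precision.

## TAP-family specialization

Pooled genes of two species are tabulated per family into developmental
(GO:0032502), stimulus/stress (GO:0050896 or GO:0006950) and both;
unannotated members count toward family totals only. A *both* gene is
evidence for each side, so side counts are dev-only + both and
stim-only + both. Each family × side is tested one-sided (enrichment)
against the background of all other annotated TAP genes — two-sided tests
would conflate depletion with specialization — and a single BH correction
spans every family × side test of the run. Quality classes: (1) best side
significant after BH; (2) only the raw p significant; (3) neither — the
side with the larger member count is assigned, ties are declared
unspecialized. The classes are mutually exclusive and exhaustive for
non-empty families, and the classification is invariant to gene order and
species relabeling.

## GLM contrasts

Responses are log2 fold changes of the *called* control-vs-t DEG
comparisons of TAP-coding genes; the log scale makes induction and
repression symmetric so the sign of a mean encodes direction. Fits are
Gaussian-identity GLMs — ordinary least squares with Wald t tests on the
residual df (statsmodels behind the module surface); an intercept-only
fit of one class is exactly a one-sample t-test. Gene × comparison
responses are treated as independent (no gene-level random effect), which
matches the simplicity of the original analysis style but understates
uncertainty when the same gene contributes several comparisons; every
summary prints that caveat. Rank-deficient designs are rejected naming
the collinear columns; perfect fits are flagged and their p-values
reported at the machine floor. Classes or families with fewer than 3
responses in scope are skipped with a warning.

## Synthetic data

`generate_dataset` draws, per gene: a baseline log2 intensity
N(8, 2²); i.i.d. replicate noise N(0, 0.25²) on the log2 scale (so noise
is multiplicative on the intensity scale); a DE indicator with probability
`de_fraction` = 0.116; for DE genes a response stage
(early/intermediate/late with first-response shares 0.08/0.45/0.47
approximating the observed accumulation of DEGs over such a time course),
a first-responding time point uniform within the stage, a direction, and
a |log2 effect| ~ N(stage mean 1.5–2.0, sd 0.6) truncated at 0.25.
Effects are step functions — present from the first time point onward —
unless a gene is drawn transient (`transient_fraction`, default 0), in
which case the effect is confined to its own stage. Everything is
exponentiated at the end, so intensities are log-normal and strictly
positive.

Annotations: TAP families of configurable sizes (default 48 families,
sizes 2 + Poisson(2)) sampled without replacement; each family has a
stimulus-side bias (default a 0.60/0.36/0.04 mixture of biases
0.85/0.15/0.5, mirroring the predominance of stress-specialized
families), members carry the corresponding class term, optionally both
sides (p = 0.1) or none (p = 0.15); every gene additionally draws generic
GO terms, and DE genes carry the stress term with probability 0.3 so GO
enrichment has signal to find. Orphan flags have base rate 0.12; for
early-stage DE genes the rate is multiplied by `orphan_early_enrichment`
(default 1.7, i.e. the ≈20% vs 12% contrast; capped at 1) and the
non-early rate is lowered so the marginal stays 0.12. Orphan enrichment
is planted on the *truth* stage, so its recovery by the pipeline is a
genuine end-to-end test. All draws flow from one `numpy` Generator
seeded by `seed`: identical configurations are bit-identical.

What the generator does **not** emulate: probe-level artifacts (spatial
effects, dye bias), missing values, gene–gene correlation, and
class-coupled effect directions (TAP class biases label GO terms, not
expression effects — class-level GLM power is therefore assessed on
directly simulated responses). Passing tests show the statistics behave
as designed under this model, not that real arrays satisfy it.

## Problem sizes and numerical choices

The test and acceptance simulations use 5000-gene null panels (20 seeds),
10 000-gene panels for orphan power (50 seeds), 500-replicate GLM
recovery and 10-seed TAP-partition recovery — sizes at which binomial
error bands are a few percent while a full run stays around a minute on
one CPU. Two power figures are reported for the orphan stage test at a
planted 2× enrichment: on the truth-stage partition (~0.9), the power of
the test itself, and on the called-DEG earliest-response partition
(~0.6–0.7), which is additionally diluted by detection noise in stage
assignment — the gap is a property of stage assignment, not of the test.
Tolerances: quadrature accuracy ≈1e−9 (validated against scipy and a
10⁶-draw Monte-Carlo oracle); exact-test agreement with the rational
enumeration oracle to 1e−9 relative; BH agreement with the literal
step-up definition to 1e−12; simulation assertions use 3-standard-error
bands.

## Known limitations

- Fold-change means over DEGs only (not all genes) — the original
  tabulation convention is not recoverable from the source material.
- No mixed-effects modeling of repeated gene contributions to GLM
  responses.
- No GO-graph-aware enrichment; annotation quality directly bounds what
  the classifier can see.
- The earliest-response stage assignment is one defensible policy for
  making stage sets disjoint; alternatives (e.g. per-time-point tests
  with overlapping sets) would give different stage p-values.
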