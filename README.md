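# coldcourse

Statistical analysis of time-series cold-stress transcriptomes, built for
the classical moss (*Physcomitrella patens*) experimental design: a
whole-genome intensity microarray measured at 0 (control), 1, 3, 8 and
24 h of cold with three biological replicates per time point.

The package answers four questions about such an experiment:

1. **Which genes respond, when, and how strongly?** Per-sample median
   normalization, a per-gene one-way (K groups) ANOVA with
   Benjamini–Hochberg FDR control across genes, Tukey HSD post-hoc tests
   for every pair of time points (Bonferroni-corrected within each gene),
   and linear fold changes of group means. A gene is a DEG for a pair iff
   its BH-adjusted ANOVA p < 0.05 **and** its Bonferroni-corrected Tukey p
   for that pair < 0.05.
2. **What do the responders do?** Fisher's-exact over/under-representation
   of GO terms in DEG sets against the array universe, and a partition of
   the time course into early (1, 3 h), intermediate (8 h) and late (24 h)
   response stages.
3. **Are species-specific (orphan) genes concentrated in the early
   response?** Exact 2×2 tests of orphan share by stage, direction and
   persistence.
4. **Are transcriptional regulators specialized?** A comparative
   transcription-associated-protein (TAP) family classifier that pools two
   species, tabulates family members into *developmental*
   (GO:0032502) vs *stimulus/stress* (GO:0050896, GO:0006950) process
   classes, tests each family against the remaining TAP complement with
   one-sided Fisher tests + BH, and assigns a three-tier annotation
   quality class; Gaussian-identity GLMs (Wald *t* tests) then contrast
   mean log2 fold changes of stress- vs development-specialized regulators
   globally, per time point and per family.

A seeded synthetic-data generator reproduces the statistical structure of
such an experiment (log-normal intensities, staged step effects, biased
TAP families, orphan enrichment) so every stage is testable without any
external download.

## The statistics

For gene *g* with intensities grouped by time point, the ANOVA statistic is

    F_g = [SSB/(k−1)] / [SSW/(N−k)],  SSB = Σ_j n_j (x̄_{gj} − x̄_g)²

referred to F(k−1, N−k). For a pair of time points (a, b) the Tukey
statistic is

    q = |x̄_{ga} − x̄_{gb}| / sqrt(MSW/2 · (1/n_a + 1/n_b))

referred to the studentized range distribution Q(k, N−k), evaluated here
by a vectorized Gauss–Legendre quadrature of

    P(Q ≤ q) = ∫ f_ν(s) · k ∫ φ(z) [Φ(z) − Φ(z − q s)]^{k−1} dz ds

accurate to well below 1e−6 (and cross-checked against
`scipy.stats.studentized_range` in the tests). Fold change is the ratio of
normalized linear group means, mean(later)/mean(earlier); values < 1
denote repression. Enrichment p-values are exact hypergeometric sums with
the conventional minimum-likelihood two-sided rule.

## Worked example

```python
import coldcourse as cc

cfg = cc.SimulationConfig(n_genes=2000, seed=1)      # 5 x 3 design, 11.6% DE
data, annotation, truth = cc.generate_dataset(cfg)

res = cc.ColdTimecourseDE(data).fit()
print(res.summary())
```

```
Time-course DE analysis: 2000 genes, time points ['0', '1', '3', '8', '24'] h, control 0 h
BH gate alpha=0.05: 212 genes entered post-hoc testing
DEGs in any control comparison: 190

  pair  n_deg  n_induced  n_repressed  n_deg_2fold  ...   fc_min    fc_max  fc_mean
 0h/1h      8          4            4            5  ... 0.212788  3.250030 1.574459
 0h/3h     17          8            9           13  ... 0.217244  4.768884 1.540448
 0h/8h     91         43           48           86  ... 0.104756  9.731066 2.170683
0h/24h    181        106           75          170  ... 0.081733 10.092403 2.644930
...
```

Of 2000 simulated genes, 212 pass the gene-level FDR gate and 190 are a
DEG in at least one control comparison; the number of DEGs accumulates
over the time course (8 at 1 h, 181 at 24 h) and `n_induced + n_repressed`
equals `n_deg` in every row. Downstream:

```python
orph = cc.OrphanStageAnalysis(res, annotation).fit()
print(orph.summary())
# Orphans among all DEGs: 24/190 (13%)
# Early vs later orphan enrichment (one-sided): table [[2,16],[22,150]], p = 0.697
# Induced vs repressed orphan share (two-sided): table [[15,97],[9,69]], p = 0.826

table, planted = cc.simulate_tap_gene_table(seed=1)   # 30/15/5 planted families
print(cc.classify_all(table).summary())
# TAP family specialization (50 families, alpha=0.05):
#   developmental: 17, stimulus_or_stress: 33
#   quality classes: class 1: 31, class 2: 5, class 3: 14
```

The orphan share of this (default 1.7× enriched) simulation is 13% overall
with a non-significant early contrast at this sample size, and the TAP
classifier recovers the planted 30-stress/15-developmental/5-neutral
partition almost perfectly. The same pipeline is available from the shell:

```sh
coldcourse simulate --seed 1 --out sim/
coldcourse deg --matrix sim/matrix.tsv --design sim/design.tsv --out deg/
coldcourse orphan --deg deg/deg_table.tsv --annot sim/annotation.tsv --out orphan/
```

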