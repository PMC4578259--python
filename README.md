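# omicpersona

Quantifying the "omic personality": how individualized and temporally
stable blood omic profiles are, from longitudinal multi-omic data.

When the same people are profiled repeatedly (here: 12 individuals, 3
visits, whole blood), the interesting question is not whether samples
differ but *along which axis*: do gene expression, CpG methylation, miRNA
abundance, and clinical traits separate people from each other more than
they separate one person's visits? `omicpersona` answers this with a
pipeline of estimators plus a synthetic-data generator that plants every
effect the estimators are supposed to find, so the whole analysis is
testable end to end without restricted cohort data.

## What it computes

- **Among-individual variance partitioning** — per feature, one-way ANOVA
  with individual as factor: R² = SSB/SST, the fraction of variance among
  people. Includes the exact conversion between R² and the underlying
  intraclass correlation ρ,
  `E[SSB]/E[SST] = (n−1)(1+(k−1)ρ) / ((nk−1)−(k−1)ρ)`,
  used both to interpret the small-replicate upward bias of R² and to
  calibrate simulations. Summaries, per-gene peak-CpG selection, and
  gene-set R² comparisons (strong vs weak eQTL sets) sit on top.
- **Replicate-cluster concordance** — first 10 PCs, Ward clustering, and a
  count of individuals whose three visits form a pure clade.
- **Individual-extreme features** — one-vs-rest ANOVA per (gene,
  individual) at p < 1e-4 for transcripts; a 0.3-beta-unit deviation rule
  for methylation; hypergeometric enrichment; miRNA/CpG integration
  correlations against each person's extreme set.
- **Methylation–expression coupling** — per CpG–gene Pearson r across
  samples (fraction with |r| > 0.5, all CpGs vs peak CpGs) and the
  regression of methylation R² on transcript R².
- **Blood axis scores** — per sample, PC1 of each axis's ten blood
  informative transcripts (BITs); variance-explained decompositions for
  axes and cell counts; attribution of extreme-gene sets to axes.
- **Replicate-aware allele-specific expression (ASE)** — per heterozygous
  site, a t test of the three replicate alternate-allele fractions against
  0.5 (df = 2, two-sided 5% cutoff |t| > 4.30) with a binomial-variance
  floor for degenerate replicates; dual-alignment capture-bias summaries;
  cross-individual ANOVA with π₀ estimation; pairwise ASE-effect
  correlations between individuals.
- **Synthetic data** — a variance-components generator
  (y = μ + Σ λ·axis + b_individual + e_visit) calibrated on the pooled-R²
  scale per data type, with planted axes, extremes, CpG–transcript
  couplings, ASE effects, and alignment biases, all recorded in truth
  tables.

## Worked example

```python
from omicpersona import synthetic as sy, varpart as vp, cluster as cl, extremes as ex, ase

cfg = sy.SyntheticConfig(n_genes=2000, cpg_per_gene=(1, 8), seed=11)
cfg.axis_spec.n_correlated_genes = 40
cfg.extreme_spec.n_per_individual = 25
bundle = sy.generate_multiomic(cfg)

rows = vp.among_individual_r2(bundle.expression, bundle.design)
print(f"pooled among-individual R2 (expression): {vp.pooled_r2(rows):.3f}")
print(f"fraction of genes with R2 > 0.8: {(rows.R2 > 0.8).mean():.3f}")

scores, ve = cl.pca_scores(bundle.expression, 10)
conc = cl.cluster_concordance(cl.ward_linkage(scores), list(scores.index),
                              bundle.design, 10, ve.sum())
print(f"individuals clustering uniquely: {conc.unique_count}/12")

calls, counts = ex.loo_extremes(bundle.expression, bundle.design)
print(f"extreme transcripts called: {len(calls)} (planted: {len(bundle.truth['extreme_genes'])})")

alt, ref, _ = sy.generate_allele_counts(cfg, bundle.design)
filtered, _ = ase.filter_sites(alt)
res = ase.site_ase_table(filtered)
print(f"sites with allelic bias: {res.significant.mean():.1%} of {len(res)} tests")
```

prints

```
pooled among-individual R2 (expression): 0.746
fraction of genes with R2 > 0.8: 0.284
individuals clustering uniquely: 12/12
extreme transcripts called: 461 (planted: 300)
sites with allelic bias: 8.6% of 21768 tests
```

Reading it: about three quarters of transcript variance separates people
(the 0.67 calibration target plus the variance added by the planted
extreme genes, of which this config carries an unusually dense 25 per
individual); every individual's three visits cluster as a pure clade on
the first ten PCs; the one-vs-rest ANOVA recovers the planted extremes
along with genes whose drawn individual effects are naturally extreme; and
roughly 9% of well-covered heterozygous sites show significant allelic
imbalance at the |t| > 4.30 cutoff.

The same stages are available from the shell:

```bash
omicpersona simulate --seed 11 --out run/
omicpersona varpart --matrix run/expression.tsv --design run/design.tsv \
    --scale log2_expression --out run/varpart/
omicpersona cluster --matrix run/expression.tsv --design run/design.tsv --out run/cluster/
omicpersona ase --counts run/allele_counts_alternate.tsv \
    --counts-ref run/allele_counts_reference.tsv --out run/ase/
```

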