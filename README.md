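# modnet

Multiscale network analysis of transcriptome compendia: gene–module and
module–module association scoring with cross-dataset meta-analysis,
cross-species conservation testing, cell-type marker enrichment, cis/trans
eQTL classification (including methylation-bin pseudo-genotypes), and
causal key-driver identification with Shapley-based regulator ranking.

The package is written for systems biologists who want to run this style
of analysis — the kind used to dissect plant drought response across
large expression compendia — on their own data, and to validate every
stage against synthetic data with planted ground truth before trusting it
on real cohorts.

## The statistics at the core

**Gene–module association (G-MAD).** For a seed gene *g* in dataset *d*,
every other gene's statistic is the Fisher-z Pearson correlation with
*g*. A module *M* (an ontology term or co-expression module, |M| = m) is
tested competitively against the background with a correlation-adjusted
two-sample z:

    z = (mean_in − mean_out) / (sd_pooled · sqrt(VIF/m + 1/m₂)),
    VIF = 1 + (m − 1)·ρ̄

where ρ̄ is the mean pairwise inter-gene correlation of the module's
genes in that dataset. Without the VIF the test is badly anticonservative
on correlated gene sets (measured in this package: a 0.36 type-I rate at
nominal α = 0.05 when ρ̄ = 0.2). Per dataset, Benjamini–Hochberg-significant
tests are quantized to tri-valued **binding scores** bᵈ ∈ {−1, 0, +1} by
enrichment direction, and the meta-analytic

    GMAS = Σ_d w_d·b_d / Σ_d w_d,   w_d = sqrt(n_d / VIF_d)

is the gene–module association score in [−1, 1].

**Module–module association (M-MAD).** A target module's per-gene signed
z profile is itself tested against every other module (overlapping genes
removed from the candidate), cross-module p-values are condensed to
{1, 0, −1} under a Bonferroni threshold α/K, and the condensed scores are
meta-analyzed with the same weights into MMAS. Thresholding |MMAS| yields
the module association network.

**Downstream layers.** Conservation between species uses reciprocal-best
ortholog filtering (E < 1e−5, identity > 60%), exact hypergeometric
overlap tests, and one-sided two-sample Kolmogorov–Smirnov comparisons of
MMAS distributions. Cell-type specificity is Fisher's exact enrichment of
marker sets in modules under a family-wide FDR. eQTLs are per-variant
linear regressions classified *cis* (≤ 1 Mb from the gene body) or
*trans* (≥ 5 Mb or another chromosome), with raw-p and BH thresholds
respectively. Key drivers are nodes of a TF-rooted causal DAG whose
downstream neighborhood is hypergeometrically enriched for co-functional
genes; regulators are ranked by exact Shapley attribution (full subset
enumeration, interventional background) across a cross-validated learner
zoo, summarized as top-k prevalence per regulator.

Every layer is exercisable on synthetic compendia with planted truth
(`modnet.synthetic`), so recovery, calibration and determinism are all
testable without downloading anything.

## Worked example

`analysis/` contains the numbered study scripts. On the default study
conditions (10 datasets × 100 samples, 2000 genes, 20 modules, seed 17):

```text
$ python analysis/02_gene_module_scan.py
GMAS matrix: 2000 genes x 20 modules, 40000 testable cells
planted sign recovery: 100.0% of 30
top of the M00 column:
 gene  gmas  n_datasets
G0000   1.0          10

$ python analysis/03_module_network.py
module network at |MMAS| >= 0.3: 8 directed edges
planted couplings: 4; precision 1.00, recall 1.00
target candidate      mmas  sign
   M00       M01  1.000000     1
   M02       M03 -1.000000    -1
```

All 30 planted gene–module associations are recovered with the correct
sign (a GMAS of 1.0 means every one of the 10 cohorts produced a
significant, same-direction binding score), and the module network at the
default |MMAS| ≥ 0.3 cut contains exactly the four planted couplings in
both directions with their planted signs. `04`–`07` continue through
conservation (conserved modules overlap across species at p ≈ 1e−41,
scrambled ones at p ≈ 1), marker enrichment, the eQTL scan, and regulator
ranking, where the planted driver gene tops the prevalence table at 100%.

The orchestrated pipeline is also available as a CLI:

```bash
modnet simulate --seed 3 --out fixtures/
modnet run --config run.yaml
```

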