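# Methods

This note documents the models, defaults, numerical choices and known
limitations of the package. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Gene–module association scoring

The gene-level statistic is the Fisher z-transform of the Pearson
correlation between each gene and the seed gene, with |r| capped at
1 − 1e−12 before `atanh` so collinear fixtures stay finite. The seed gene
is excluded from both the module and the background when it is a module
member, preventing self-association leakage.

The competitive test standardizes the difference of mean statistics
between module and background genes. Its variance term multiplies the
module side by VIF = 1 + (m − 1)ρ̄, where ρ̄ is the mean of all
m(m − 1)/2 pairwise Pearson correlations among the module's genes in the
dataset at hand. The motivating fact, asserted by the acceptance suite:
under a null with ρ̄ = 0.2 modules, the uncorrected test rejects at
roughly seven times the nominal rate, while the corrected test stays
inside the binomial 99% interval around α. The correction is exact in
the limit where the correlation among gene-level statistics equals the
expression correlation of the underlying genes, which holds approximately
for correlation-based statistics under the null. With ρ̄ = 0 the test
reduces to the unadjusted two-sample z-test, and its p-values agree with
gene-label permutation p-values to within ±0.02 (measured over 50 random
instances at 10⁴ permutations).

The normal tail is used rather than a t tail: the background always has
hundreds of genes in intended use, so the degrees of freedom are large;
the permutation agreement above is the empirical justification.

**Quantization and meta-analysis.** Per dataset, p-values over the whole
gene × module family are Benjamini–Hochberg adjusted (the paper-style
"multiple testing adjustments" made concrete; the family choice is per
dataset because datasets are the unit of meta-analysis). Significant
cells (strict `adj_p < α`, α = 0.05 default) become binding scores ±1 by
direction, otherwise 0. The meta-analytic weight is
w_d = sqrt(n_d / VIF_d): sqrt-n is the standard z-based meta-analysis
weight, and dividing by sqrt(VIF) discounts datasets whose module
correlation inflates the effective noise — together an effective-sample-
size weight. The formula is recorded in the output metadata
(`GmasMatrix.weight_formula`) so alternatives can be compared. Cells with
no contributing dataset are NaN ("absent"), never 0: a zero is evidence
of tested non-association, absence is lack of evidence.

## Module–module association

The target module's per-gene signed z-scores (not the quantized binding
scores) form the profile; candidate modules are tested against it with
the same correlation-adjusted test. Genes shared between target and
candidate are removed from the candidate so trivial overlap cannot drive
the score; the target's own genes remain in the background, where at
realistic scale (tens of member genes among thousands) their influence on
the pooled standard deviation is negligible. Cross-module p-values are
condensed to {1, 0, −1} at the Bonferroni threshold α/K with K = the
number of candidate modules tested for that target in that dataset — the
smallest defensible family. MMAS reuses the G-MAD meta-analysis weights.

MMAS is directional (row = target, column = candidate). The two
directions need not agree numerically; on the default synthetic
conditions the directional matrix and its symmetrized mean differ by at
most 0.2 (asserted empirically). Symmetrization is an explicit opt-in
(`MmasMatrix.symmetrized()`), off by default.

The module network keeps edges with |MMAS| ≥ 0.3 by default. No
published cut exists for this quantity; 0.3 requires same-direction
significance in roughly a third of the weighted evidence and gives
precision = recall = 1.0 on the default synthetic conditions. It is a
named config key (`mmas_threshold`), never a literal in stage code.

## Synthetic data: what it emulates, what it does not

Modules are driven by shared latent factors: member gene
x = a·f + ε with unit noise and equal loadings, so the within-module
mean correlation is a²/(a² + 1) and the loading is solved from the
target ρ̄ (default 0.3, a typical co-expression module strength).
Generation is O(genes), and ρ̄ is controlled directly; realized ρ̄ is
within ±0.05 of target at n ≥ 100 (tested). Planted gene–module
associations add the module's factor at effect 0.8 to background genes
(about one third with negative sign); planted module couplings share
factors at γ = 0.6 with the planted sign. Default compendium: 10
datasets × 100 samples, 2000 genes, 20 disjoint modules of 10–30 genes,
1.5% of genes carrying planted associations.

The genome is one 30 Mb chromosome with genes evenly spaced — the
minimal geometry on which both the cis window (≤ 1 Mb) and the trans
distance (≥ 5 Mb) are realizable. Planted cis/trans variants are placed
by the same distance rules the classifier applies, so planted class and
called class agree by construction (asserted, 100%). Genotypes are
independent binomial dosages (MAF uniform in [0.1, 0.5]); planted
effects add β·dosage (β = 0.8) to the target gene. Methylation bins are
100 bp, non-overlapping, Beta(2,2) levels, contexts cycled CG/CH/C, with
a subset coupled linearly to a neighboring gene's expression.

The regulatory prior is a DAG by construction: TFs are ordered and
TF→TF edges respect the order. TFs are real genes of the universe so
their expression exists for the learner stage; the planted driver is a
gene already planted to associate with the designated module, which
makes "driver expression predicts module summary" true by construction
at a known effect size.

A second species for conservation testing copies module memberships
through a 1:1 ortholog map (ids prefixed `B_`), scrambles a configurable
fraction of modules (default 0.2) into species-specific functions, and
re-simulates expression independently. The homology table contains the
true orthologs at E ∈ [1e−30, 1e−10], identity 65–95%, plus decoys that
fail the filters.

Not emulated: linkage disequilibrium, population structure, batch
effects, count noise, overlapping module memberships, trans-acting hubs,
tissue heterogeneity. Passing recovery tests therefore demonstrates the
correctness of the inference machinery under the stated generative
model, not robustness to real-data confounding (the upstream tools that
handle confounding are outside this package's scope).

## eQTL scanning

Per-variant simple linear regression (β = cov/var, t on n − 2 df,
two-sided). Missing genotypes are excluded pairwise, never imputed;
variants monomorphic in the shared samples, or with fewer than 20 shared
samples after exclusion, are skipped with a logged reason. P-values are
floored at the smallest positive double so perfect fits stay
representable. No covariate or population-structure correction is
applied — the study design this mirrors removes confounders upstream.

Classification is total and deterministic: distance to the nearer gene-
body boundary (a proxy for the exon boundary; an exon BED can refine),
cis ≤ 1 Mb, trans ≥ 5 Mb or another chromosome, the 1–5 Mb gap
unclassified. The "association peak" is the minimum-p variant per gene
per region, ties broken by variant id. Significance follows the study
convention: raw p < 2.46e−4 for cis, BH-adjusted p < 1.51e−13 within the
trans family. Both printed source exponents are physically impossible as
p-values (> 1); they are interpreted as 1e−4 / 1e−13 scale, kept
configurable, and echoed into run metadata. Methylation pseudo-genotypes
use the same scan with BH < 0.05 per methylation context.

## Causal graph and regulator ranking

Prior edges with non-TF sources are dropped and counted. Cycles among
TFs (possible in binding-site priors) are resolved by removing, per
detected cycle, the minimum-weight edge (ties: lexicographic
source/target) until acyclic — the mildest deterministic intervention
that enforces the DAG requirement. eQTL support upgrades an edge's
evidence to "both" when the target has a significant eQTL whose peak
lies within 1 Mb (configurable) of the source TF's locus.

Key-driver enrichment uses the downstream neighborhood within depth
h = 2 (configurable 1–3; depth 1 is direct targets, 3 dilutes sharply),
upper-tail hypergeometric over the declared universe, BH across tested
nodes, driver call at adjusted p < 0.05 and neighborhood ≥ 5. Leaves are
flagged untested rather than given p = 1 silently.

The learners predict the module summary — the first principal component
of the standardized module submatrix, sign-anchored to correlate
positively with the module mean (the standard eigengene choice; the
response variable is recorded in output metadata because no single
convention exists). The zoo holds six learner families (ordinary linear,
elastic-net penalized linear spanning ridge- and lasso-type penalties,
k-nearest-neighbour, random-forest tree ensemble, RBF support-vector
kernel regressor, and a single-hidden-layer perceptron), each behind a
standardizing pipeline with fixed small hyperparameter grids selected by
inner 3-fold CV — deterministic and desk-scale, in place of
black-box hyperparameter search, which is not this package's
contribution. Outer evaluation is 5-fold CV RMSE with fold assignment
deterministic from the seed. The ranking machinery is learner-count-
agnostic.

Shapley values are exact by full subset enumeration for ≤ 12 features
(4096 coalition evaluations, each a mean prediction over the background
sample with out-of-coalition features replaced by background values —
the interventional convention). Efficiency Σφ = f(x) − E[f] holds to
numerical precision by telescoping; the linear closed form
φᵢ = βᵢ(xᵢ − mean bgᵢ) is used as an independent cross-check in tests,
never as the implementation. Above 12 features, permutation sampling
with ≥ 200 permutations reports a Monte-Carlo standard error. Regulator
prevalence is 100 · (#models with the feature in their top-k) / #models,
rounded to one decimal; ties break by mean |φ| then name.

## Numerical and engineering choices

- Coordinates are 0-based half-open everywhere internally; BED passes
  through, VCF positions are shifted by one at the boundary.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; identical configs give byte-identical output
  TSVs (asserted), and every output carries a header comment with the
  config hash and seed. The hash excludes the output directory.
- VIF is floored at 1.0 before use so slightly negative ρ̄ estimates
  cannot deflate the variance.
- Boundary convention: strict inequality everywhere a threshold is
  compared (`adj_p < α`, `p < α/K`), so a p exactly at the threshold is
  not significant.
- The hypergeometric tail is computed as `sf(k − 1)`, the exact upper
  tail P(X ≥ k); the cell-type module uses `fisher_exact` so the
  equality of the two routes (to 1e−12) is a genuine cross-check.
- Empirical p-values use the +1 convention and can never be zero.
- Degenerate inputs fail loudly: constant seed genes, modules with < 2
  usable genes, empty samples and rank-zero submatrices raise typed
  errors; an all-identical statistic vector yields z = 0, p = 1 rather
  than an error.

## Problem sizes

Tests and the acceptance script run the full default study conditions
(10 × 100 × 2000, 20 modules) for recovery, 2000 tests for calibration,
10⁴–10⁵ permutations for the oracle comparisons, 10⁶ draws for the
Monte-Carlo hypergeometric check, 100–500 replicates for eQTL power and
bias, and 50 simulated graphs for driver recovery. These sizes give
stable estimates (binomial standard errors well inside the asserted
margins) while keeping the whole suite in the low minutes on one CPU.

## Known limitations

- The meta-analysis weight formula is a reasoned choice, not an
  identified quantity; alternative weights can change borderline GMAS
  values (the provenance metadata exists for exactly this comparison).
- "Pearson's rank correlation" is ambiguous in the source tradition;
  the correlation network defaults to Pearson on values with a
  `method="spearman"` switch, and neither is asserted as canonical.
- The cis threshold is exposed as a plain number; whether it should be
  re-derived per-gene at a target FDR on new data is left to the user.
- MMAS asymmetry is bounded empirically on the default conditions, not
  theoretically.
- Exact Shapley cost is 2^p; the cap at 12 features is a hard refusal,
  not a silent fallback.
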