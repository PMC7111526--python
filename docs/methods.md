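# Methods

`metabosysgen` implements the analysis chain for a systems-genetics study of
an inbred-line metabolome: fully homozygous lines, both sexes, replicate
pools per line and sex, a few hundred metabolite abundances, transcript line
means, and organismal trait line means measured on the same genotypes. This
note records the models, the numerical choices, what the synthetic generator
does and does not emulate, and the design decisions taken where the design
was genuinely open.

## Variance components and broad-sense heritability

Replicate-level abundance of each metabolite is modelled as

    Y = mu + L + S + LxS + e

with line `L` and line-by-sex `LxS` random, sex `S` fixed; per-sex analyses
use the reduced model `Y = mu + L + e`. Components are estimated by REML on
the variance ratios `sigma2/sigma2_e`, profiled over the residual variance.
Because lines are independent, the restricted likelihood factorizes into
per-line blocks (6x6 for 2 sexes x 3 replicates), which are solved batched;
optimization is L-BFGS-B followed by a Nelder-Mead polish
(`xatol 1e-10`), with ratios bounded in [0, 1e8]. On balanced data the REML
optimum coincides with the classical expected-mean-squares estimators
whenever those are positive; the suite asserts agreement to 1e-6, and the
EMS estimators with their F-tests are exposed as `method="anova"`.

Broad-sense heritability is `H2 = (s2_L + s2_LxS) / (s2_L + s2_LxS + s2_e)`
— sex, a fixed effect, contributes to neither numerator nor denominator —
and is defined as 0 when the total variance is 0. Random terms are tested by
restricted likelihood ratio against the model without the term, referred to
the boundary mixture `0.5*chi2_0 + 0.5*chi2_1`; the fixed sex effect uses a
Wald F with denominator df `(L-1)(S-1)`, the balanced-ANOVA stratum.
Missing abundances are simply omitted (unbalanced REML), not imputed.
Line-variable metabolites are flagged at Benjamini-Hochberg FDR < 0.05.

## Metabolite modules and module PCs

Genetically variable metabolites are clustered on the absolute Pearson
correlation of their line means (Spearman is available). The weight between
two analytes is a shifted sigmoid of |r|,

    w = 1/(1 + exp(-s(|r| - t))) - 1/(1 + exp(st)),

so that |r| = 0 maps to weight 0 exactly — uncorrelated analytes are
disconnected, and an identity correlation matrix yields the all-singleton
partition, which plain modularity cannot produce (the singleton partition of
a complete positive graph always has Q < 0). For each `(s, t)` on a fixed
grid (s in {5, 10, 20, 30}, t in {0.2 ... 0.8}), the weighted modularity is
maximized by recursive spectral bipartition (leading eigenvector of the
generalized modularity matrix) with deterministic Kernighan-Lin refinement;
the transform with the highest resulting modularity wins. Modules are
numbered by descending mean within-module |r| (singletons count 0), ties by
size then first analyte id, so the partition is invariant to input order.

Module PCA standardizes each analyte's line means (modules mix abundance
scales) and retains every PC explaining more than 4% of the module variance,
extended in decreasing order until the retained set cumulatively explains
more than 90% (a 1e-9 roundoff guard keeps an exact-boundary sum on the
"extend" side). PC signs are fixed so the largest-|loading| analyte loads
positively; scores are zero-mean across lines.

## mQTL mapping

Genotypes are two homozygous classes coded {0, 1}. The panel is chosen
unrelated and free of inversions and endosymbiont infection, so the
association model reduces to OLS of the line-level phenotype on the genotype
class — the pooled-variance two-sample t-test — applied per variant with
pairwise-complete lines. Variants are kept when the minor class has at least
4 lines (MAF >= 0.1 at 40 lines); genome-wide significance is Bonferroni
`0.05 / n_tests`. The reported effect is the coded-1 minus coded-0 class
mean difference, so inverting the coding flips the sign and leaves P
unchanged (a "minor minus major" effect cannot satisfy that invariance,
since recoding does not change which class is minor). Intergenic hits are
single-linkage merged into regions at a 2 kb gap; in-gene hits carry the
gene label (site classes accepted as input annotation). A planted effect of
2 residual SDs at minor count 10/40 is detected at the panel-scale
genome-wide threshold in well over half of simulations, with power monotone
in effect size; at the 1.56M-test threshold of the full variant catalogue
the same effect is underpowered (~20%), which is a property of the t test,
not of the implementation.

## MWAS and trait clustering

Traits are screened against metabolites and module PCs by Spearman rank
correlation at a nominal P < 0.05, uncorrected — the screen feeds network
assembly and fold-internal enrichment, not headline inference. P-values use
the t approximation, with exact permutation enumeration available for
n <= 8. For trait clustering each trait is represented by its signed rho
profile with non-significant entries zeroed; the distance between traits is
1 - Pearson correlation of profiles, with average linkage (complete linkage
and full profiles are config options). Dendrograms export as Newick.

## Integrated networks

For one trait and sex: metabolites with trait P < 0.05; transcripts linked
to those metabolites at Spearman |rho| > 0.45; each metabolite's mQTLs
tested against its linked transcripts with the same OLS as mapping, kept at
the metabolite-specific Bonferroni threshold `0.05 / (that metabolite's mQTL
count)` (the count of mQTLs only, not mQTLs x genes — the rule divides by
the mQTL number alone). Nodes are typed (metabolite with super pathway,
gene, variant), flagged when directly associated with the trait at nominal
P < 0.05; correlation edges carry the sign of rho. Node and edge insertion
is sorted, so identical inputs produce byte-identical GraphML. meQTLs are
labelled cis when the variant falls within the linked gene body +- 1 kb
(config-exposed; "cis" has no canonical window in this design) and trans
otherwise.

## Prediction

Kernels are `K = WW'/p` from column-centered features scaled to unit sample
SD (n-1 denominator); with that scaling `trace(K) = n-1` exactly. One- and
two-kernel BLUP models are fitted by REML — a single kernel is profiled on
its eigenbasis so each likelihood evaluation is O(n); two kernels use
bounded 2-D optimization — and held-out lines are predicted as
`mu + Cov(g*, y) V^-1 (y - mu)`. With a fixed variance ratio these
predictions are algebraically identical to ridge regression on W at penalty
`p * sigma2_e / sigma2_K`; the suite asserts the identity to 1e-8.

All cross-validation is leave-one-out and strictly fold-internal: feature
centering and scaling, enrichment selection, and variance components are
re-estimated on the 39 training lines of every fold. The combined MWAS-BLUP
model re-runs a per-metabolite linear regression inside each fold and builds
the kernel from metabolites with P < x, x in {0.5, 0.4, 0.3, 0.2, 0.1,
0.05}; a fold selecting nothing falls back to the training mean (flagged).
The elastic net (lasso/ridge mixing alpha, penalty lambda) uses coordinate
descent paths per fold over a grid of alpha in {0.05 ... 1.0} and 50
log-spaced lambdas spanning four decades down from the data-driven maximum;
the reported model is the grid point with the highest leave-one-out
accuracy (non-nested selection, matching the study design this emulates).

Accuracy is the Pearson correlation of predicted and observed line values,
computed on predictions whose fold intercepts are aligned to a common value.
The alignment matters: each fold's training mean is `(S - y_i)/(n - 1)`,
exactly anti-correlated with the held-out value, so raw leave-one-out
predictions of a no-signal model have accuracy near -1 by construction.
Aligning intercepts correlates the fitted line effects with the
observations instead; a model with zero predictive variance in every fold
then produces constant predictions and is reported as accuracy 0 with a
degenerate flag (the same convention covers an elastic net whose
coefficients are all zero). Even so, adaptively re-estimating variance
components inside each fold leaves a small negative bias (~ -0.1) in
permuted-label accuracy: REML picks a positive kernel variance exactly when
the training labels show spurious kernel signal, and the resulting
extrapolation anti-correlates with the exchangeable held-out label. A
fixed-ratio control run is unbiased (mean -0.003), confirming the machinery;
the bias is a property of adaptive tuning under leave-one-out, and a
*positive* permuted-label mean would be the signature of leakage.

## Synthetic panel generator

The generator emulates the study design: 40 inbred lines, 2 sexes, 3
replicate pools, ~200 metabolites with mean broad-sense heritability 0.43
(line-by-sex takes 25% of the genetic variance by default), unit residual
variance, a block-modular correlation structure (exchangeable correlation
within modules via one shared factor per module), sparse planted mQTL and
eQTL effects in residual-SD units, and traits that are noisy linear
functions of a chosen metabolite subset with a specified trait-level
heritability. Genotypes draw each variant's minor-class count uniformly
between the MAF floor and n/2, so every variant satisfies the minor-class
constraint by construction. All draws flow from a single integer seed.

It does not emulate: linkage disequilibrium (variants are independent),
inversions or endosymbiont infection (the emulated panel was chosen free of
both), run-day batch effects, missing-value patterns of real MS data, or
peak-level noise. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
those real-data features.

## Problem sizes used by tests and the acceptance script

Variance-component recovery uses 200 metabolites x 40 lines x 2 sexes x 3
reps; null calibration uses 1000-variant scans and 100-400 simulation
replicates; network recovery uses 50 seeds of a 40-line, 60-variant,
12-metabolite, 6-gene panel with one planted chain at 2.5 SD on a common
variant (rank correlations lose power on rare variants, so chains are
planted at minor count >= 15); prediction checks use 10 seeds of a
200-metabolite panel with 5 causal metabolites at trait h2 = 0.7, and 100
label permutations. These sizes were chosen so each property is measured
with comfortable statistical margin on a single CPU.

## Repository shape

Stages that are fit/predict- or transform-shaped are sklearn-style
estimators (`KernelBLUP`, `MWASEnrichedBLUP`, `ModularityClustering`,
`ModulePCA`) and compose with sklearn model selection; the remaining stages
(variance components, association scans, network assembly, the generator)
are plain functions, with the thin `metabosysgen` CLI on top.

## Known limitations

- Modularity maximization is a heuristic; very weak block structure can
  fragment or merge modules, and the transform grid bounds the resolution.
- The two-kernel REML uses dense O(n^3) likelihood evaluations — fine for
  panels of tens of lines, not for thousands.
- Exact Spearman permutation P is enumerated only for n <= 8.
- The mQTL model deliberately omits relatedness and covariate corrections;
  it is the faithful reduction for an unrelated, covariate-free panel and
  should not be applied to structured populations.
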