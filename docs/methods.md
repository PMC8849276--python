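# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, the synthetic cohort's generative assumptions, and
the numerical choices that affect results.

## Study design being modelled

A nested case-control design inside a hospital cohort of children with
complicated severe malnutrition: nonsurvivors (NS, died in hospital)
matched 1:1 to survivors (S, discharged alive within 14 days) on
propensity scores built from age, HIV status and MUAC. Admission blood
samples are profiled on three blocks — targeted metabolites (µM),
untargeted TMT-plex proteins (reporter intensity), and Luminex
inflammatory mediators (pg/mL). All matched-design statistics respect
the pairing; all model fitting happens on log10, autoscaled
concentrations.

## Synthetic cohort generator

The generator produces the study's statistical structure with known
ground truth. Defaults are the cohort's conditions: 92 pairs, 206
metabolites (a Biocrates-style panel — 22 amino acids, 20 biogenic
amines, 40 acylcarnitines, 90 glycerophospholipids, 15 sphingomyelins,
hexoses — plus 18 organic acids), 229 proteins, 29 cytokines.

Generative model, per analyte $a$ and subject $i$:

$$\log_{10} x_{ia} = m_a + u_{p(i),a} + s_a z_{ia}
 + \mathbb{1}[i \in NS,\ a \in D]\,\delta_a \sigma_a g_i$$

* $m_a$: baseline log-abundance, normal per block (metabolites
  $\mathcal N(1, 0.6^2)$, proteins $\mathcal N(4, 0.5^2)$, cytokines
  $\mathcal N(1, 0.7^2)$) — log-normal concentrations reflect
  multiplicative biology and guarantee positivity.
* $u_{p,a} \sim \mathcal N(0, 0.15^2)$: pair-shared random effect (the
  matched design's within-pair correlation), independent across
  analytes.
* $z_{ia}$: standard normal with within-class factor correlation
  $\rho = 0.3$ (analytes of one biochemical class co-vary, as in the
  clustered heatmaps of real panels); $s_a \sim U(0.15, 0.35)$.
* Planted differential set $D$ (defaults 20 metabolites / 15 proteins /
  4 cytokines, magnitudes $U(0.6, 1.2)$): the shift is
  $\delta_a$ in units of the within-group SD
  $\sigma_a = \sqrt{0.15^2 + s_a^2}$, with signs mirroring the reported
  signature (organic acids, acylcarnitines and cytokines up in NS;
  lysoPC/SM/PC lipids down; others random). Nonsurvivors who die
  earlier carry proportionally larger shifts (factors 1.4 / 1.0 / 0.6
  for death at days ≤ 3 / 4-7 / > 7, normalized to unit mean under the
  geometric time-to-death law) so the deviation-Z-score analysis has a
  recoverable gradient.
* Group-specific correlation pairs (default 8 amino-acid pairs,
  $r_S = 0.7 \to r_{NS} = 0.0$): both analytes are drawn jointly from a
  group-specific bivariate Gaussian on the log scale. These analytes
  carry no pair random effect, so the planted within-group correlation
  is exact rather than diluted; they are never in $D$.
* IL8 is coupled to the pooled short-chain fatty acids
  (propionate + isobutyrate + butyrate) with log-scale correlation 0.3,
  preserving IL8's marginal moments, so the pooled-SCFA analysis has a
  planted target; IL8 is excluded from the cytokine differential pool.
* Censoring/missingness: metabolites are masked below a per-analyte
  LOD (2% quantile; a 6% subset at the 35% quantile fails the
  detection rule in both groups); cytokines analogously (34% heavily
  censored, matching 19/29 analyzed); proteins have 5%
  missing-at-random dropout with an 8% subset at 30% (removed by the
  >20% rule); TMT batches (5 pairs per batch) shift protein log-means
  with SD 0.2.
* QC replicates (8) are built with *exact* per-analyte sample CV —
  replicates are mean·(1 + cv·z) with z standardised — drawn from
  $U(0.02, 0.25)$ (pass) or $U(0.35, 0.60)$ (fail, 25% of analytes),
  so the CV filter's decisions are deterministic given the draw and the
  failing fraction is exactly binomial. With these defaults ~142 of 206
  metabolites survive QC, close to the real cohort's 144.
* Clinical covariates: matched variables (age, MUAC, HIV) are shared
  within pairs up to noise (the matching already happened); danger-sign
  flags are Bernoulli with group-specific prevalences taken from the
  cohort's characteristics table, so the clinical view carries weak
  outcome signal.

What the generator does **not** emulate: instrument-level artifacts
(drift, carryover, isotope effects), non-normal heavy tails, missing
blocks per subject (the real study profiled 90 pairs for metabolomics
and 87 for proteomics; here all blocks cover all pairs), informative
(non-MAR) protein dropout, and biological pathway structure beyond
class-level correlation. Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated under a faithful
covariance/censoring structure — not that the trial's specific analyte
lists would be reproduced on real data.

A separate pool generator (`generate_unmatched_pool`) produces
unmatched, covariate-confounded NS/S subjects for exercising the
matching stage; case status is sampled probabilistically from the
confounded propensity so the pool is never linearly separable.

## Preprocessing

* CV filter: sd/mean of raw QC replicates (sample SD); raw-scale CV is
  the platform convention. Retention requires CV < 0.30 **and**
  detection ≥ 80% in NS or in S (the "either group" rule), applied on
  the analysis sample. Zero-mean QC replicates make the CV undefined;
  the analyte is removed with reason `cv_fail`. Every removal carries
  a reason code and `assayed = retained + removed` is enforced.
* Non-detects are imputed at LOD/2 (half the limit of detection).
* Proteins missing in > 20% of subjects are removed; the rest are
  imputed by k-nearest neighbours (k = 10, nan-Euclidean distances over
  shared observed analytes, unweighted neighbour mean — the sklearn
  convention). The same kNN imputer serves all blocks for uniformity
  and determinism, rather than a bagged-tree imputer for isolated
  missing panels.
* Batch correction is a ComBat-style location/scale adjustment on the
  log10 scale: standardize each analyte against its pooled mean and
  pooled within-batch variance, estimate per-batch location/scale,
  optionally shrink them toward their across-analyte moments by the
  parametric empirical-Bayes iteration, adjust, and back-transform.
  Non-parametric ComBat is not implemented. Singleton batches require
  shrinkage.
* Transformation: log10, then per-analyte mean-centering and division
  by the sample SD (ddof = 1). Zero-variance columns are dropped with
  a warning rather than erroring — degenerate synthetic columns should
  not kill a pipeline run. Autoscaling is idempotent within 1e-8.

## Matching

Propensity scores are maximum-likelihood logistic regression of case
status on age, HIV (dummy-coded, "unknown" its own level) and MUAC;
constant covariates are absorbed by the intercept. Perfect separation
raises with advice to refit with a ridge penalty (`ridge > 0` uses the
L2-regularized fit). Matching is greedy 1:1 without replacement on
|logit score differences|, processing cases in descending propensity
order (hardest first) with lexicographic subject-id tie-breaks; no
caliper by default, an optional caliper flag is provided. Balance is
reported as SMD = (mean difference)/√(mean of variances) and variance
ratios, before and after matching; categorical covariates expand to
level proportions. These ordering/caliper choices are documented
defaults, not reconstructions of the original analysis.

## Univariate screen

One conditional-logistic fit per analyte (plus an optional covariate
difference term for edema/WHZ adjustment). Newton-Raphson with step
damping; convergence at max |score| < 1e-8 within 50 iterations.
Separation (differences of one sign) is detected by coefficient
divergence; the estimate is flagged and the p-value falls back to the
Rao score test at β = 0. BH-FDR runs within each block (the blocks use
different significance rules, so pooling families would mix criteria).
Fold change is the NS/S ratio of arithmetic means of raw
concentrations; a geometric-mean option exists (the convention is not
identifiable from summary tables). All-constant within-pair analytes
report p = 1 and fold change 1.

Ratios are sums of raw concentrations in numerator and denominator
(denominator `unit` = plain sum), computed per subject and screened
exactly like analytes with a $q<0.05$ rule. Only the four named ratios
are built in; the remaining panel ratios are user-configurable
definitions.

## Stability selection

The elastic-net objective is the mean logistic deviance plus
$\lambda(\alpha\|\beta\|_1 + \tfrac{1-\alpha}{2}\|\beta\|_2^2)$ with
unpenalized intercept, solved by IRLS with an inner active-set
coordinate descent on the weighted least-squares subproblem
(curvature floored at 1e-6, full KKT sweeps between active-set
passes), warm-started along a descending 100-point log grid from
$\lambda_{max}$ to $10^{-3}\lambda_{max}$. Final fits converge at max
coefficient change < 1e-7; the CV exploration paths use 3e-3, since
misclassification counts are insensitive to coefficient perturbations
at that scale (supports agree with the tight tolerance on > 99% of
grid points in testing).

The resampling unit is the matched pair, preserving the 1:1 design;
each of the B = 200 bootstrap iterations draws pairs with replacement,
tunes λ by five-fold CV (folds assign whole pairs; ties go to the
largest λ), refits at the optimum and records the nonzero support.
Per-iteration RNG streams are spawned from the master seed, so the
aggregate is independent of execution order; degenerate resamples are
redrawn and counted (pair resampling cannot actually produce a single
class — the guard is defensive). The elastic-net likelihood itself is
unconditional on the case/control labels; the matched structure is
honored through pair-level resampling and fold assignment.

## Multilevel PLS-DA

The within-pair transformation replaces each row by its deviation from
the pair mean (±half the case-control difference; column sums exactly
zero). NIPALS PLS1 against y = ±1: unit-norm weight w ∝ X'y, score
t = Xw, rank-one deflation of X; y is not deflated. Predictions use
the regression vector $b = W(P^\top W)^{-1}q$. Reported statistics use
the discriminant convention: residuals are zeroed once the prediction
is on the correct side of the label with at least unit magnitude.
$DR^2$ applies this to training predictions, $DQ^2$ to held-out
predictions, so $DQ^2 \le DR^2$ in practice (a plain training $R^2$
can fall below a strongly discriminating model's $DQ^2$, which is why
the discounted fit is the right comparator). Cross-validation assigns
whole pairs to folds (balanced classes by construction); held-out
pairs are decomposed with their own pair means, which needs no labels.
Defaults: 2 components (1-5 available), 10 folds, 50 repeats for the
mean ± SD summaries (the repeat count behind reported SDs is a
package choice).

## Differential correlation networks

Pearson correlations per group; within-group significance from the
t-distribution on n−2 df; BH-FDR over all pairs within each group
separately. An edge requires FDR-significance (q < 0.05) in at least
one group **and** Fisher-z difference p < 0.05 (no multiplicity
control across the z-tests — the screening step is the within-group
FDR). Group n is the per-group complete-observation count. Edge
attributes: direction (strengthened/weakened by |r_NS| vs |r_S|), sign
(of the significant correlation; the larger |r| when both qualify),
width |r_NS − r_S|. Node degree counts differential edges only. The
network is invariant to analyte input order.

The cross-block heatmap uses hierarchical agglomerative clustering on
1 − r with average linkage (single linkage is exposed for outlier
inspection); leaf order uses scipy's deterministic lower-index-first
tie-break. The pooled SCFA analysis sums propionate, isobutyrate and
butyrate per subject and correlates with IL8 on the log10 scale,
reporting r, p, medians and the above/below-median 2×2 table.

## Similarity network fusion

Per view: distance (standardized Euclidean for omics, scaled by
√p so the kernel scale is dimension-free; Gower for the mixed clinical
view), then the scaled-exponential kernel
$W_{ij}=\exp(-d_{ij}^2/(\mu\varepsilon_{ij}))$ with
$\varepsilon_{ij}$ the mean of the two subjects' K-NN mean distances
and $d_{ij}$. Fusion: $P$ = full kernel row-normalized with half the
mass on the diagonal, $S$ = row-normalized K-NN kernel,
$P^{(v)} \leftarrow S^{(v)}\,\overline{P^{(u\neq v)}}\,S^{(v)\top}$,
re-symmetrized and re-normalized each iteration (row sums of every P
stay 1 within 1e-8; the final fused average is symmetrized, which
perturbs its row sums at the percent level). Defaults K = 20, µ = 0.5,
t = 20 iterations (all configurable; the convergence warning fires if
the Frobenius change is still above 1e-4). Spectral clustering is the
normalized-cut construction (symmetric normalized affinity, top-k
eigenvectors, row-normalized, k-means with a fixed seed and 50
restarts). Concordance is the NMI between a single view's spectral
labels and the fused labels at k = 2; degenerate single-cluster
labelings define NMI = 0. The real study's 0.7 (omics) vs 0.1
(clinical) concordances are treated as an ordering property, not
numeric targets — the statistic behind those numbers is not published.

Deviation Z-scores stratify nonsurvivors by time to death (≤ 3, 4-7,
> 7 days) and report (stratum mean − survivor mean)/survivor SD per
analyte; zero survivor SD is flagged.

## Pipeline and determinism

`run_pipeline` executes simulate → preprocess → match → summarize →
univariate (+ ratios) → stability → union → PLS-DA → diffcorr → SNF,
writing flat TSV/JSON artifacts and a manifest of parameters, derived
seeds (all spawned from one master seed) and SHA-256 file hashes.
Stability selection runs on the metabolite and protein blocks (the
mediator panel is small and is carried whole into the network stage,
as in the study's cross-correlation analysis). Two runs with the same
config and seed produce byte-identical numeric artifacts;
`resume=True` skips stages whose artifacts match their recorded
hashes. Sensitivity options: `adjust_for: edema|whz` adds the
covariate difference to the univariate models; `residualize: true`
replaces each analyte by its OLS residual on the covariate
(re-autoscaled; analytes numerically exhausted by the covariate are
dropped with a warning) before the multivariable stages.

Problem sizes in the test-suite simulations (90 pairs × 100 analytes
for selection recovery, 1000 null analytes for calibration, 10 seeds
for recovery rates) are chosen to give stable Monte-Carlo verdicts on
a single CPU; the acceptance script runs the full default scale.

## Known limitations

* The conditional-logistic screen is exact only for 1:1 matching; m:n
  sets are out of scope.
* Score-test fallback under separation gives a joint p-value when a
  covariate term is present.
* ComBat is parametric-EB only; reference-batch and covariate-preserving
  variants are not implemented.
* SNF cluster-number selection (eigen-gap/rotation cost) is not
  implemented; k is user-chosen (2 and 4 by default).
* The fold-change convention (arithmetic vs geometric means) changes
  numeric values for skewed analytes; both are provided, arithmetic is
  the default.
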