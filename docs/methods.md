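# Methods

## The problem

Multi-item survey scales are modeled with latent variables: a multidimensional
graded response (MGR) model for ordinal items, or a confirmatory factor
analysis (CFA) model for numeric items. Differential item functioning (DIF)
means that item parameters — thresholds, intercepts, loadings, latent
(co)variances — depend on covariates of the respondents, so two people at the
same latent level answer differently because of group membership. When the
relevant subgroups are unknown, `mgrtree` searches for them with model-based
recursive partitioning: a tree (or a forest of decorrelated trees) over the
partitioning covariates, with one fitted measurement model per node.

## Measurement models

An ordinal spec defines, for items i = 1..m with categories 0..l_i, the
probit cumulative response model

    P(Y_i >= k | xi) = Phi(beta_i' xi - alpha_ik),

equivalently a latent response y*_i = beta_i' xi + e_i, e_i ~ N(0, 1),
discretized at strictly increasing thresholds alpha_ik. The implied
latent-response covariance is `Sigma* = Lambda Phi Lambda' + I`; the unit
unique variance is the scale-setting convention matching the probit link, and
the model-implied correlation structure `kappa(theta) = corr(Sigma*)` is what
the distribution-free estimator fits. A numeric spec is the standard factor
model `Y = pi + Lambda xi + eps` with free residual variances.

Identification follows the usual anchoring rule: a latent variable's variance
is fixed at 1 exactly when its first (anchoring) loading is free. The
benchmark model is a multistate structure with latent item-effect variables:
reference state latents `eta_t` (one per timepoint), item-effect latents
`b_i` shared across timepoints, every discrimination fixed at 1, all
thresholds and all latent (co)variances free. For 3 timepoints x 3
five-category items this gives 51 free parameters (36 thresholds, 5
variances, 10 covariances); its numeric twin has 33 (9 intercepts, 9 residual
variances, 15 latent (co)variances).

## Two-stage estimation

**Growth stage (ML).** Trees are grown with limited-information maximum
likelihood: minimize `F_ML = ln|Sigma(theta)| + tr(S Sigma^-1) - ln|S| - m`.
Ordinal responses are deliberately treated as numeric scores 0..l_i during
growth and the numeric twin of the spec is fitted — a distributional
compromise that buys casewise log-likelihoods and analytic score
contributions, the raw material of the instability tests. The sample
covariance uses divisor n so the estimating equation (score columns summing
to zero at the optimum) holds exactly; the casewise log-likelihood kernel
omits the constant `-(m/2) ln 2 pi`, which cancels in every difference,
score and LR statistic. Optimization is quasi-Newton (L-BFGS-B) on the free
structural parameters with variances log-transformed; intercepts are profiled
out at the sample means. Starting values: identity latent covariance,
loadings at pattern values, residual variances at half the sample variances;
child nodes warm-start from their parent. Convergence is declared at a
projected-gradient tolerance that keeps the per-case score-sum residual below
1e-4 (typically ~1e-7).

**Evaluation stage (WLS).** Terminal nodes of ordinal trees are re-estimated
distribution-free: thresholds from cumulative margins
(`alpha_ik = Phi^-1(cum. proportion)`), pairwise polychoric correlations by
two-step ML over the contingency table with thresholds fixed (bivariate
normal rectangle probabilities via a vectorized Gauss–Legendre
Drezner–Wesolowsky quadrature, validated against scipy's multivariate normal
CDF), then `F_WLS = (kappa-hat - kappa(theta))' W (kappa-hat - kappa(theta))`
minimized over the structural parameters. The weight matrix is the inverse of
the empirical asymptotic covariance of the polychoric vector, assembled from
casewise pairwise-likelihood influence functions (score over information per
case); threshold-estimation variability is ignored, the usual two-step
simplification. `chi2 = n * F_WLS`; RMSEA = sqrt(max(chi2 - df, 0)/(df(n-1)))
with a two-sided 95% confidence interval from inverting the noncentral
chi-square CDF. A diagonal-weights (DWLS) fallback exists behind a flag for
large item sets and is labeled a deviation from the full-weights definition.

## Instability tests and splitting

From a converged node fit, casewise scores `psi(y_j, theta-hat)` are
decorrelated with the root inverse of their empirical outer-product
covariance and accumulated along the covariate ordering into the process
`B(j/n)`. Statistics:

- numeric covariates: `maxLM = max_t ||B(t)||^2 / (t(1-t))` over the trimmed
  window (default trim 0.1, plus any minimum-child-size restriction); the
  argmax is the candidate split point;
- unordered categorical: `LMuo`, the sum of squared scaled category score
  sums, chi-square with k(C-1) df;
- ordered covariates: `maxLMo`, the maxLM form evaluated only at the C-1
  level cuts.

p-values: chi-square tail for LMuo; for maxLM/maxLMo a seeded Brownian-bridge
simulation (5000 replicates; the maxLM null table is computed once per
(k, trim) on a 200-point grid and cached — a fixed dedicated seed makes
p-values deterministic and shareable across nodes and trees). A closed-form
crossing-probability approximation (Miller–Siegmund) is available for maxLM
with a single parameter; it is a tail approximation, accurate below p ~ 0.02
and crude near 0.05, which is why simulation is the default.

Covariate selection takes the smallest Bonferroni-adjusted p-value (factor =
number of covariates actually tested at the node); splitting stops when no
adjusted p-value is below alpha (default 0.05), when a child would fall below
the minimum node size, or below the fitting floor of k+10 cases. Simulated
p-values cannot resolve below ~1/5000 while the LMuo chi-square tail can be
arbitrarily small; covariates whose p-value hits the simulation floor are
therefore ranked by the pointwise chi-square log-tail of their statistic — a
comparable monotone proxy used only for ranking, never for the significance
decision. Without this, categorical covariates would always win under strong
DIF regardless of relative signal.

Three split strategies: `score` (cut at the statistic's argmax; one fit per
node), `objective` (fit both children at every admissible cut, keep the cut
minimizing the summed child deviance), `naive` (per covariate the max-LR cut,
selection by smallest adjusted LR p-value; retained for comparison, it is far
more expensive). Categorical splits search all 2^(C-1)-1 binary partitions
(C <= 10); ties break to the smallest boundary / lexicographically smallest
subset. Tied covariate values stay adjacent in the ordering (within-tie order
randomized under the node's seeded generator) and cuts are only placed
between distinct values. Scores are taken with respect to the full model
parameter vector including residual variances by default; an option restricts
them to the item-parameter view.

## Forests

Ensembles grow `n_trees` trees on the full sample — no bagging, so every
node's parameter estimates are exactly replicable on the original data — and
decorrelate them solely by redrawing `mtry` candidate covariates at every
node (defaults mirror the benchmark settings: 50 trees for a single-sample
analysis, 20 for repetition experiments, mtry 3, minimum node 100, RMSEA
cutoff 0.05). Terminal nodes are WLS-refit (identical case sets share one
refit across trees); leaves passing the fit cutoff are pooled, merged by
case-index set (different but equivalent rules collapse), counted across
trees ("frequency"), annotated with strict-superset links, and sorted by fit.

A caveat this package makes explicit: the benchmark model's latent covariance
matrix is fully free, so the family nests near-independence — a leaf of pure
random responses fits it essentially perfectly (kappa-hat ~ 0 is matched by
Phi ~ 0), and mixtures of one well-fitting group with random cases are
approximately representable through attenuated covariances. The RMSEA cutoff
therefore ranks subgroups more than it excludes them for this family; the
subset annotations and the frequency column are the practical tools for
reading a forest report, and subgroup recovery is defined by exact
case-set identity (a Jaccard >= 0.95 relaxation is available behind a flag),
not by the filter.

## Synthetic benchmark scenarios

`simulate_pieg` draws latent vectors from N(0, latent_cov), adds the item
effects and a standard-normal unique part, and discretizes at the thresholds;
`simulate_cfa` is the numeric twin. Group parameters are sampled per
subgroup — thresholds sorted N(0,1) draws (redrawn until adjacent gaps are
at least 0.25, avoiding near-empty categories), latent variances
Uniform(0.5, 1.5), correlations Uniform(0.1, 0.5) projected to the nearest
positive-definite correlation matrix, intercepts N(0,1), residual variances
Uniform(0.5, 1.5) — and resampled (budget 40 tries) until the subgroup's own
model attains RMSEA <= 0.05 on its own data, so planted subgroups genuinely
fit.

Scenario 1 (single-tree benchmark): n = 2000, four subgroups of 500 defined
by `R1 = {num1 < 100, cat1 in {1,5}}`, `R2 = {num1 < 100, cat1 in {2,3,4}}`,
`R3 = {num1 >= 100, cat2 <= 2}`, `R4 = {num1 >= 100, cat2 >= 3}`; num1 is an
integer 1..200, cat1 is treated as unordered (its defining subset {1,5} is
non-contiguous), cat2 as ordered; five uninformative covariates (two numeric,
three ordinal) are independent of the groups. The partition is expressible by
one depth-2 binary tree. Scenario 2 (forest benchmark): two exclusive
subgroups of 500 — `R1 = {cat2 in {3,4}, num1 <= 50}`,
`R2 = {dicho1 = 0, cat1 in {1,4,5}}`, with cat1/cat2 unordered here and
dicho1 dichotomous — and 1000 cases of random responses (uniform categories,
or Uniform(-3, 3) values on the numeric scale); covariates of non-members are
rejection-sampled so that neither rule fires for them, making manifest labels
and rules exactly consistent. This structure is not representable by a
single binary tree, which is what motivates the ensemble.

What the generator does *not* emulate: missing data, longitudinal dropout,
non-normal latent distributions, partial (item-subset) DIF, or covariate
correlation structures. Passing benchmarks therefore demonstrate recovery of
cleanly planted, covariate-exclusive subgroups under correctly specified
measurement models — not performance on messy survey data.

## Tree-stability taxonomy

Against a scenario manifest a grown tree is classified as `stable` (leaf
partition identical to the planted subgroups), `inaccurate_split_point`
(right covariates and exact categorical/ordinal boundaries, right leaf
count, but a numeric split point misplaced) or `incorrect_split` (any split
on an irrelevant covariate, wrong subset/cut, or wrong structure). On ordinal
data the typical failure mode is a num1 boundary a few values off — the
growth-stage compromise costs split-point precision, not structure — while
numeric-response trees are more often exactly stable.

## Numerical choices

- L-BFGS-B with ftol 1e-13 / projected-gradient 1e-7 (growth fits), so the
  gradient criterion, not the function criterion, terminates.
- Non-positive-definite implied covariances during line search return a large
  objective value; fitted latent covariances may be slightly indefinite
  (boundary solutions), which downstream code tolerates.
- Polychoric optimization: bounded scalar minimization on (-0.999, 0.999),
  xatol 1e-7; boundary estimates are clamped with a warning.
- Weight matrices are repaired with a 1e-8 relative ridge when near-singular;
  rank-deficient score covariances use a pseudo root-inverse with the
  effective parameter count reported.
- Degenerate inputs: constant covariates are skipped with a note; items with
  a single observed category make a node unevaluable for WLS (named in the
  error); missing values are rejected everywhere (out of scope).
- Determinism: every random element (scenario generation, within-tie
  ordering, mtry draws, null-table simulation) flows from explicit seeds;
  repeated runs are bit-identical.

## Problem sizes used in the shipped experiments

The repository's test suite and the acceptance script run the benchmark at
desk scale, chosen as the package's own reproducible defaults: single-tree
stability over 10–20 generated samples per response scale, forest recovery
over 10–12 datasets with 10-tree ensembles (the single-sample forest default
remains 50 trees), and null-calibration sweeps of 500 fitted replicates.
Full-scale repetitions (100 datasets x 20 trees) run through the same entry
points by raising the counts.

## Known limitations

- Each grown tree tests several nodes at family-wise alpha, so false-positive
  splits accumulate over the tree: with ~5-7 tested nodes per tree at
  alpha = 0.05, roughly a fifth to a quarter of trees acquire one borderline
  spurious split inside an otherwise correct structure. This multiplicity
  across nodes is inherent to model-based recursive partitioning (no
  tree-level correction is applied); forests absorb it through aggregation.
- Instability tests apply to the ML growth stage only; score-based tests for
  WLS-fitted ordinal models are not provided (none exist in the underlying
  theory yet), so terminal-node evaluation is diagnostic, not inferential.
- The growth-stage compromise (ordinal-as-numeric) biases split-point
  precision on numeric covariates; forests, not single trees, are the
  recommended remedy.
- Full-information marginal ML partitioning is out of scope (computationally
  infeasible for multidimensional models); no missing data, no surrogate
  splits, no pruning, no multiway splits, no variable importance.
- The maxLM closed form is k = 1 only and tail-accurate; simulated p-values
  are floored at ~1/n_sim (see the ranking proxy above).
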