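# mgrtree

Recursive partitioning for detecting **differential item functioning (DIF)**
in multidimensional graded response (MGR) and confirmatory factor analysis
(CFA) measurement models.

## Who this is for

Survey methodologists and psychometricians who measure latent traits with
multi-item ordinal scales and cannot assume measurement invariance — but also
cannot pre-specify which subgroups violate it. `mgrtree` searches a set of
partitioning covariates (demographics, design variables, ...) for subgroups
whose item parameters differ, with a single interpretable decision tree or a
more robust forest of decorrelated trees.

## The model and the method

For items i = 1..m with ordered categories k = 0..l_i and latent vector
&xi;, the MGR model is the probit cumulative response model

```
P(Y_i >= k | xi) = Phi(beta_i' xi - alpha_ik),
```

equivalently a normal latent response `y*_i = beta_i' xi + e_i` discretized
at increasing thresholds `alpha_ik`; the numeric counterpart is the factor
model `Y = pi + Lambda xi + eps`. DIF means the item parameter vector
(thresholds/intercepts, loadings, latent covariances) depends on covariates
Z.

Trees are grown in two stages:

1. **Growth** — limited-information ML (minimizing
   `F_ML = ln|Sigma(theta)| + tr(S Sigma^-1) - ln|S| - m`; ordinal responses
   treated as numeric scores at this stage). In every node, casewise score
   contributions feed generalized M-fluctuation tests of parameter stability:
   `maxLM` for numeric covariates, `LMuo` for unordered categorical, `maxLMo`
   for ordered ones, Bonferroni-corrected per node. The covariate with the
   smallest adjusted p-value below alpha is split at the cut maximizing the
   score statistic (or, optionally, minimizing the segmented deviance, or by
   the classical LR search).
2. **Evaluation** — terminal nodes are re-estimated distribution-free:
   thresholds from cumulative margins, polychoric correlations, and a full
   weighted least squares fit
   `F_WLS = (kappa-hat - kappa(theta))' W (kappa-hat - kappa(theta))` with
   chi-square and RMSEA fit indices.

Forests grow many trees on the full sample (no bagging — estimates stay
replicable), decorrelated by redrawing `mtry` candidate covariates at every
node; well-fitting terminal subgroups are pooled across trees, merged by
case set, counted, and sorted by fit. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

Simulate the single-tree benchmark (2000 cases, 9 five-category items from a
multistate model with latent item effects — 51 free parameters — and four
planted subgroups of 500 defined over covariates num1, cat1, cat2, plus five
inert covariates), then grow and evaluate a tree:

```python
from mgrtree import build_pieg_spec, DifTree, TreeControls
from mgrtree.simulate import make_scenario1

spec = build_pieg_spec(3, 3, 5)            # 3 timepoints x 3 items, 5 categories
data, cov, manifest = make_scenario1("ordinal", seed=3)
results = DifTree(data, cov, spec, kinds=manifest.kinds,
                  controls=TreeControls(seed=1)).fit()
results.refit_terminal_nodes()
print(results.summary())
```

```
DIF recursive-partitioning tree
  method = score, alpha = 0.05, bonferroni = True, min_size = 0, seed = 1
  n = 2000, leaves = 4
[0] n=2000  split: num1
|- num1 <= 99
|  [1] n=1000  split: cat1
|  |- cat1 in {1, 5}
|  |  * [3] n=500  chi2=15.29 df=21 rmsea=0.000  <num1 <= 99 & cat1 in {1, 5}>
|  |- cat1 not in {1, 5}
|  |  * [4] n=500  chi2=22.53 df=21 rmsea=0.012  <num1 <= 99 & cat1 not in {1, 5}>
|- num1 > 99
|  [2] n=1000  split: cat2
|  |- cat2 <= 2
|  |  * [5] n=500  chi2=23.40 df=21 rmsea=0.015  <num1 > 99 & cat2 <= 2>
|  |- cat2 > 2
|  |  * [6] n=500  chi2=27.37 df=21 rmsea=0.025  <num1 > 99 & cat2 > 2>
```

The tree recovers the four planted subgroups exactly: the root splits the
numeric covariate at 99/100, then cat1 into the non-contiguous subset {1, 5}
and cat2 at its planted cut. Each leaf's distribution-free refit reports its
own chi-square and RMSEA — all four subgroup models fit well (RMSEA at or
near 0 on 21 degrees of freedom), e.g. for the first leaf:

```
Ordinal WLS fit
  n = 500, moments = 36, df = 21
  F_WLS = 0.030578, chi2 = 15.289, p = 0.8082
  RMSEA = 0.0000  95% CI = (0.0000, 0.0297)
```

For complex structures a single tree cannot represent, grow a forest:

```python
from mgrtree import DifForest, ForestControls, TreeControls
from mgrtree.simulate import make_scenario2

data, cov, manifest = make_scenario2("ordinal", seed=11)
forest = DifForest(data, cov, build_pieg_spec(3, 3, 5), kinds=manifest.kinds,
                   controls=ForestControls(n_trees=50, mtry=3, seed=5,
                                           tree_controls=TreeControls(min_size=100))).fit()
print(forest.summary())       # rule, n, chi2, df, rmsea, frequency, subset links
```

A command-line interface wraps the same pipeline
(`mgrtree simulate|tree|forest|recovery`, see `--help`), writing delimited
reports plus a JSON manifest of seeds and controls for every run.

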