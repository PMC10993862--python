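"""Recursive-partitioning engine: stopping rules, split-point oracles,
partition invariants, terminal-node refits and stability classification."""

import numpy as np
import pandas as pd
import pytest

from mgrtree.model_spec import build_pieg_spec
from mgrtree.simulate import make_scenario1, sample_group_parameters, simulate_cfa
from mgrtree.tree import (
    DifTree,
    SplitRule,
    TreeControls,
    classify_tree_stability,
    infer_kinds,
)


@pytest.fixture(scope="module")
def cfa_spec():
    return build_pieg_spec(3, 3, 5, response_scale="numeric")


@pytest.fixture(scope="module")
def null_sample(cfa_spec):
    """One homogeneous population: no DIF anywhere."""
    rng = np.random.default_rng(100)
    params = sample_group_parameters(cfa_spec, rng)
    data = simulate_cfa(params, 1200, rng, spec=cfa_spec)
    Z = pd.DataFrame({
        "z1": rng.normal(size=1200),
        "z2": rng.integers(0, 5, 1200),
        "z3": rng.integers(0, 2, 1200),
    })
    kinds = {"z1": "numeric", "z2": "ordinal", "z3": "categorical"}
    return data, Z, kinds


@pytest.fixture(scope="module")
def dichotomous_dif_sample(cfa_spec):
    """DIF planted only across a dichotomous covariate."""
    rng = np.random.default_rng(101)
    pa = sample_group_parameters(cfa_spec, rng)
    pb = sample_group_parameters(cfa_spec, rng)
    pb.intercepts = pa.intercepts + 0.5
    da = simulate_cfa(pa, 600, rng, spec=cfa_spec)
    db = simulate_cfa(pb, 600, rng, spec=cfa_spec)
    data = pd.concat([da, db], ignore_index=True)
    Z = pd.DataFrame({
        "grp": np.repeat([0, 1], 600),
        "noise": rng.normal(size=1200),
    })
    perm = rng.permutation(1200)
    return (data.iloc[perm].reset_index(drop=True),
            Z.iloc[perm].reset_index(drop=True),
            {"grp": "categorical", "noise": "numeric"})


def test_no_dif_yields_single_root(cfa_spec, null_sample):
    data, Z, kinds = null_sample
    res = DifTree(data, Z, cfa_spec, kinds=kinds,
                  controls=TreeControls(seed=0)).fit()
    assert res.n_leaves == 1
    assert res.root.is_terminal


def test_alpha_to_zero_yields_single_root(cfa_spec, dichotomous_dif_sample):
    data, Z, kinds = dichotomous_dif_sample
    res = DifTree(data, Z, cfa_spec, kinds=kinds,
                  controls=TreeControls(alpha=1e-300, seed=0)).fit()
    assert res.n_leaves == 1


def test_min_size_half_sample_limits_depth(cfa_spec, dichotomous_dif_sample):
    data, Z, kinds = dichotomous_dif_sample
    res = DifTree(data, Z, cfa_spec, kinds=kinds,
                  controls=TreeControls(min_size=len(data) // 2, seed=0)).fit()
    assert max(nd.depth for nd in res.nodes) <= 1


def test_dichotomous_dif_single_split(cfa_spec, dichotomous_dif_sample):
    data, Z, kinds = dichotomous_dif_sample
    res = DifTree(data, Z, cfa_spec, kinds=kinds,
                  controls=TreeControls(seed=0)).fit()
    assert res.root.split is not None
    assert res.root.split.covariate == "grp"
    assert res.n_leaves == 2
    left = res.root.children[0]
    assert set(np.unique(Z["grp"].to_numpy()[left.case_index])) in (
        {0}, {1})


def test_leaves_partition_sample(cfa_spec, dichotomous_dif_sample,
                                 scenario1_ordinal):
    data, Z, kinds = dichotomous_dif_sample
    res = DifTree(data, Z, cfa_spec, kinds=kinds,
                  controls=TreeControls(seed=0)).fit()
    all_cases = np.concatenate([leaf.case_index for leaf in res.leaves()])
    assert len(all_cases) == len(data)
    assert len(np.unique(all_cases)) == len(data)


def test_score_guided_boundary_matches_exhaustive_oracle(cfa_spec):
    """The score-guided numeric boundary equals the argmax of an explicit
    loop over admissible cuts."""
    rng = np.random.default_rng(102)
    pa = sample_group_parameters(cfa_spec, rng)
    pb = sample_group_parameters(cfa_spec, rng)
    da = simulate_cfa(pa, 400, rng, spec=cfa_spec)
    db = simulate_cfa(pb, 400, rng, spec=cfa_spec)
    data = pd.concat([da, db], ignore_index=True)
    z = np.concatenate([rng.integers(1, 100, 400), rng.integers(100, 201, 400)])
    Z = pd.DataFrame({"num": z})
    model = DifTree(data, Z, cfa_spec, kinds={"num": "numeric"},
                    controls=TreeControls(seed=0))
    res = model.fit()
    rule = res.root.split
    assert rule is not None
    # oracle
    from mgrtree.instability import score_process
    scores = res.root.ml_fit.score_matrix()
    proc = score_process(scores, z, rng=np.random.default_rng(0))
    n = len(z)
    best, bidx = -np.inf, None
    floor = model._floor
    for j in range(1, n):
        if proc.z_sorted[j] == proc.z_sorted[j - 1]:
            continue
        t = j / n
        if t < 0.1 or t > 0.9 or j < floor or n - j < floor:
            continue
        lm = (proc.process[j] ** 2).sum() / (t * (1 - t))
        if lm > best:
            best, bidx = lm, j
    assert rule.boundary == proc.z_sorted[bidx - 1]


def test_objective_split_matches_bruteforce_and_score(cfa_spec):
    """Objective-comparison split minimizes the summed child deviance over
    all candidates and lands near the score-guided boundary."""
    rng = np.random.default_rng(103)
    pa = sample_group_parameters(cfa_spec, rng)
    pb = sample_group_parameters(cfa_spec, rng)
    pb.intercepts = pa.intercepts + 0.8
    da = simulate_cfa(pa, 300, rng, spec=cfa_spec)
    db = simulate_cfa(pb, 300, rng, spec=cfa_spec)
    data = pd.concat([da, db], ignore_index=True)
    z = np.repeat(np.arange(12), 50)  # ordinal with 12 levels -> few cuts
    Z = pd.DataFrame({"lev": z})
    model = DifTree(data, Z, cfa_spec, kinds={"lev": "numeric"},
                    controls=TreeControls(method="objective", seed=0))
    res = model.fit()
    rule = res.root.split
    assert rule is not None
    # brute force over candidate rules
    root = res.root
    devs = {}
    for cand in model._candidate_rules(root, "lev"):
        dev, _, _ = model._children_deviance(root, cand)
        if dev is not None:
            devs[cand.boundary] = dev
    assert rule.boundary == min(devs, key=lambda b: (devs[b], b))
    assert abs(rule.boundary - 5) <= 1  # planted break at level 6


def test_naive_reduces_to_lr_split_search(cfa_spec, dichotomous_dif_sample):
    data, Z, kinds = dichotomous_dif_sample
    res = DifTree(data, Z[["grp"]], cfa_spec, kinds={"grp": "categorical"},
                  controls=TreeControls(method="naive", seed=0,
                                        max_depth=1)).fit()
    assert res.root.split is not None
    assert res.root.split.covariate == "grp"


def test_naive_null_stops(cfa_spec, null_sample):
    data, Z, kinds = null_sample
    res = DifTree(data, Z[["z3"]], cfa_spec, kinds={"z3": "categorical"},
                  controls=TreeControls(method="naive", seed=0,
                                        max_depth=1)).fit()
    # a single dichotomous covariate without DIF: usually no split
    assert res.n_leaves in (1, 2)


def test_scenario1_tree_recovers_subgroups(scenario1_ordinal):
    data, cov, man = scenario1_ordinal
    spec = build_pieg_spec(3, 3, 5)
    res = DifTree(data, cov, spec, kinds=man.kinds,
                  controls=TreeControls(seed=1)).fit()
    label = classify_tree_stability(res, man)
    assert label in ("stable", "inaccurate_split_point")
    truth = {man.case_set(g) for g in man.group_names()}
    if label == "stable":
        assert set(res.leaf_case_sets()) == truth


def test_refit_terminal_nodes_ordinal(scenario1_ordinal):
    data, cov, man = scenario1_ordinal
    spec = build_pieg_spec(3, 3, 5)
    res = DifTree(data, cov, spec, kinds=man.kinds,
                  controls=TreeControls(seed=1)).fit()
    res.refit_terminal_nodes()
    for leaf in res.leaves():
        assert leaf.unevaluable or leaf.wls_fit is not None
    good = [leaf.wls_fit.rmsea for leaf in res.leaves() if leaf.wls_fit]
    assert all(np.isfinite(r) for r in good)
    rendered = res.render()
    assert "rmsea" in rendered and "n=" in rendered


def test_refit_skipped_for_numeric(cfa_spec, null_sample):
    data, Z, kinds = null_sample
    res = DifTree(data, Z, cfa_spec, kinds=kinds,
                  controls=TreeControls(seed=0)).fit()
    res.refit_terminal_nodes()
    assert all(leaf.wls_fit is None for leaf in res.leaves())
    assert res.leaf_fit_indices(res.leaves()[0]) is not None  # ML indices


def test_classification_definitions(scenario1_ordinal):
    """Boundary misplacement on num1 -> inaccurate; a rand split ->
    incorrect."""
    data, cov, man = scenario1_ordinal
    spec = build_pieg_spec(3, 3, 5)
    res = DifTree(data, cov, spec, kinds=man.kinds,
                  controls=TreeControls(seed=1)).fit()
    assert classify_tree_stability(res, man) in (
        "stable", "inaccurate_split_point")
    # surgically misplace the numeric boundary: reclassify cases
    root = res.root
    num_nodes = [nd for nd in res.nodes
                 if nd.split and nd.split.kind == "numeric_threshold"]
    def repartition(node):
        if node.is_terminal:
            return
        z = res.model.exog[node.split.covariate].to_numpy()[node.case_index]
        left = node.split.goes_left(z)
        node.children[0].case_index = node.case_index[left]
        node.children[1].case_index = node.case_index[~left]
        for child in node.children:
            repartition(child)

    if num_nodes:
        nd = num_nodes[0]
        nd.split = SplitRule(nd.split.covariate, "numeric_threshold",
                             nd.split.boundary - 3.0)
        repartition(nd)
        assert classify_tree_stability(res, man) == "inaccurate_split_point"
        # a split on an irrelevant covariate is always incorrect
        nd.split = SplitRule("rand3", "ordinal_threshold", 2)
        assert classify_tree_stability(res, man) == "incorrect_split"


def test_infer_kinds():
    df = pd.DataFrame({
        "a": np.linspace(0, 1, 20),
        "b": np.tile(np.arange(4), 5),
        "c": pd.Categorical(list("xyxy") * 5),
    })
    kinds = infer_kinds(df)
    assert kinds == {"a": "numeric", "b": "ordinal", "c": "categorical"}


def test_category_subset_rule_semantics():
    rule = SplitRule("c", "category_subset", frozenset({1, 5}))
    z = np.array([1, 2, 3, 5, 4])
    assert rule.goes_left(z).tolist() == [True, False, False, True, False]
    assert "in {1, 5}" in rule.describe(True)
    assert "not in" in rule.describe(False)
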