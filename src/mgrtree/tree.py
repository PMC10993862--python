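"""Model-based recursive partitioning for MGR / CFA measurement models.

A :class:`DifTree` grows a binary decision tree over partitioning covariates.
In every node the measurement model is fitted by limited-information ML
(ordinal responses treated as numeric scores -- the growth-stage compromise),
parameter stability with respect to each candidate covariate is tested with
the kind-appropriate score-based statistic (maxLM / LMuo / maxLMo) under a
node-wise Bonferroni correction, and -- if instability is significant -- the
node is split on the covariate with the smallest adjusted p-value. Three split
strategies are available:

* ``"score"`` (score-guided): the cut maximizing the score-based statistic;
  one model fit per node.
* ``"objective"`` (partykit-style): among admissible cuts, the one minimizing
  the summed deviance of the two child fits; one fit per candidate
  segmentation.
* ``"naive"`` (likelihood-ratio): per covariate the cut maximizing the LR
  statistic against the template fit, covariate selection by smallest
  (Bonferroni-adjusted) LR p-value.

Terminal nodes of ordinal-response trees are then re-estimated with the
distribution-free WLS engine to obtain interpretable parameters and fit
indices (chi2, RMSEA).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instability import (
    max_lm_numeric,
    score_process,
    test_all_covariates,
)
from .ml import CovarianceStructureML, lr_test
from .model_spec import MgrModelSpec
from .wls import OrdinalWLS

__all__ = [
    "SplitRule",
    "TreeNode",
    "TreeControls",
    "DifTree",
    "TreeResults",
    "classify_tree_stability",
    "infer_kinds",
]

_MAX_CATEGORICAL = 10


@dataclass(frozen=True)
class SplitRule:
    """A binary split condition: left child satisfies the rule."""

    covariate: str
    kind: str  # numeric_threshold | ordinal_threshold | category_subset
    boundary: object  # threshold c (z <= c left) or frozenset A (z in A left)
    tied: bool = False

    def goes_left(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "category_subset":
            return np.isin(z, list(self.boundary))
        return np.asarray(z) <= self.boundary

    def describe(self, left: bool = True) -> str:
        if self.kind == "category_subset":
            vals = sorted(self.boundary)
            if left:
                return f"{self.covariate} in {{{', '.join(map(str, vals))}}}"
            return f"{self.covariate} not in {{{', '.join(map(str, vals))}}}"
        op = "<=" if left else ">"
        b = self.boundary
        btxt = f"{b:g}" if isinstance(b, float) else str(b)
        return f"{self.covariate} {op} {btxt}"


@dataclass
class TreeNode:
    id: int
    depth: int
    case_index: np.ndarray
    ml_fit: object = None
    instability: list = field(default_factory=list)
    split: SplitRule = None
    children: list = field(default_factory=list)
    wls_fit: object = None
    rule_path: list = field(default_factory=list)
    note: str = ""
    unevaluable: bool = False

    @property
    def is_terminal(self) -> bool:
        return self.split is None

    @property
    def n(self) -> int:
        return len(self.case_index)

    def rule_string(self) -> str:
        return " & ".join(self.rule_path) if self.rule_path else "<root>"


@dataclass
class TreeControls:
    """Controls of the tree-growing process.

    ``min_size`` is the minimum terminal-node size (0: only the fitting floor
    of ``k_free + fit_floor_extra`` cases per child applies). ``mtry`` draws a
    random covariate subset per node (forest use); None tests all covariates.
    """

    alpha: float = 0.05
    bonferroni: bool = True
    min_size: int = 0
    trim: float = 0.1
    method: str = "score"
    seed: int = 0
    max_depth: int = None
    mtry: int = None
    n_sim: int = 5000
    exclude_residual_scores: bool = False
    fit_floor_extra: int = 10
    max_candidates: int = 512

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("score", "objective", "naive"):
            raise ValueError(f"unknown method {self.method!r}")


def infer_kinds(covariates: pd.DataFrame) -> dict:
    """Heuristic covariate kinds: pandas categoricals are categorical,
    integer columns with few levels are ordinal, everything else numeric."""
    kinds = {}
    for col in covariates.columns:
        s = covariates[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            kinds[col] = "categorical"
        elif np.issubdtype(s.dtype, np.integer) and s.nunique() <= 10:
            kinds[col] = "ordinal"
        else:
            kinds[col] = "numeric"
    return kinds


class DifTree:
    """Model-based recursive partitioning tree for DIF detection.

    Parameters
    ----------
    endog : DataFrame or array, response data (rows aligned with ``exog``).
    exog : DataFrame of partitioning covariates.
    spec : MgrModelSpec of the measurement model.
    kinds : dict covariate -> kind; inferred when omitted.
    controls : TreeControls
    """

    def __init__(self, endog, exog: pd.DataFrame, spec: MgrModelSpec,
                 kinds: dict = None, controls: TreeControls = None):
        if hasattr(endog, "columns"):
            endog = endog[spec.item_names]
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog.reset_index(drop=True)
        if len(self.exog) != len(self.endog):
            raise ValueError("endog and exog are not row-aligned")
        self.spec = spec
        self.kinds = infer_kinds(exog) if kinds is None else dict(kinds)
        self.controls = controls if controls is not None else TreeControls()
        self.k_growth = spec.numeric_twin().k_free
        floor = self.k_growth + self.controls.fit_floor_extra
        if 0 < self.controls.min_size < floor:
            warnings.warn(
                f"min_size {self.controls.min_size} below the fitting floor "
                f"{floor}; the floor is enforced anyway")
        self._floor = max(self.controls.min_size, floor)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "TreeResults":
        self._nodes = []
        root_idx = np.arange(len(self.endog))
        root_fit = self._fit_node(root_idx, start=None)
        if root_fit is None or not root_fit.converged:
            raise RuntimeError("root model fit did not converge")
        root = TreeNode(id=0, depth=0, case_index=root_idx, ml_fit=root_fit)
        self._nodes.append(root)
        self._grow(root)
        return TreeResults(self, root, self._nodes)

    def _node_rng(self, node_id: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.controls.seed,
                                   spawn_key=(node_id,)))

    def _fit_node(self, idx, start=None):
        try:
            model = CovarianceStructureML(self.endog[idx], self.spec)
            return model.fit(start_params=start)
        except (ValueError, np.linalg.LinAlgError):
            return None

    def _struct_params(self, fit):
        flat = fit.params.to_flat()
        nfree_pi = int(fit.model.spec.intercepts_free.sum())
        return flat[nfree_pi:]

    # ----------------------------------------------------------- recursion
    def _grow(self, node: TreeNode):
        ctl = self.controls
        rng = self._node_rng(node.id)
        if ctl.max_depth is not None and node.depth >= ctl.max_depth:
            return
        if node.n < 2 * self._floor:
            return
        cols = list(self.exog.columns)
        if ctl.mtry is not None and ctl.mtry < len(cols):
            cols = sorted(rng.choice(cols, size=ctl.mtry, replace=False))
        zsub = self.exog.iloc[node.case_index][cols]

        if ctl.method == "naive":
            picked = self._find_split_naive(node, zsub)
            if picked is None:
                return
            rule = picked
        else:
            scores = node.ml_fit.score_matrix()
            # note: the null-table seed stays at its fixed default so the
            # simulated reference distributions are deterministic tables
            # shared across nodes and trees; ctl.seed only drives tie
            # ordering and the per-node covariate draw
            results, selected = test_all_covariates(
                scores, zsub, self.kinds, alpha=ctl.alpha,
                bonferroni=ctl.bonferroni, trim=ctl.trim,
                min_size=self._floor,
                exclude_residual_scores=ctl.exclude_residual_scores,
                n_sim=ctl.n_sim, rng=rng)
            node.instability = results
            if selected is None:
                return
            if ctl.method == "score":
                rule = self.find_split_score_guided(node, selected, rng)
            else:
                rule = self.find_split_objective(node, selected)
            if rule is None:
                return

        zcol = self.exog[rule.covariate].to_numpy()[node.case_index]
        left_mask = rule.goes_left(zcol)
        li = node.case_index[left_mask]
        ri = node.case_index[~left_mask]
        if min(len(li), len(ri)) < self._floor:
            return
        start = self._struct_params(node.ml_fit)
        lfit = self._fit_node(li, start=start)
        rfit = self._fit_node(ri, start=start)
        if lfit is None or rfit is None or not (lfit.converged and rfit.converged):
            node.note = "child fit failed to converge; node kept terminal"
            warnings.warn(node.note)
            return
        node.split = rule
        for idx, fit, left in ((li, lfit, True), (ri, rfit, False)):
            child = TreeNode(
                id=len(self._nodes), depth=node.depth + 1, case_index=idx,
                ml_fit=fit,
                rule_path=node.rule_path + [rule.describe(left)])
            node.children.append(child)
            self._nodes.append(child)
        for child in node.children:
            self._grow(child)

    # -------------------------------------------------------- split search
    def _admissible_level_cuts(self, z: np.ndarray):
        """Ordinal cut levels whose children satisfy the fitting floor."""
        levels = np.unique(z)
        out = []
        for lev in levels[:-1]:
            nl = int((z <= lev).sum())
            if self._floor <= nl <= len(z) - self._floor:
                out.append(lev)
        return out

    def _admissible_subsets(self, z: np.ndarray):
        cats = np.unique(z)
        if len(cats) > _MAX_CATEGORICAL:
            raise ValueError(
                f"categorical covariate with {len(cats)} levels: exhaustive "
                f"subset search is limited to {_MAX_CATEGORICAL}; recode or "
                "declare the covariate ordinal")
        first, rest = cats[0], cats[1:]
        subsets = []
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                a = frozenset([first, *combo])
                if len(a) == len(cats):
                    continue
                nl = int(np.isin(z, list(a)).sum())
                if self._floor <= nl <= len(z) - self._floor:
                    subsets.append(a)
        return subsets

    def find_split_score_guided(self, node: TreeNode, covariate: str, rng=None):
        """Cut at the argmax of the score-based statistic (one fit per node)."""
        ctl = self.controls
        z = self.exog[covariate].to_numpy()[node.case_index]
        kind = self.kinds[covariate]
        scores = node.ml_fit.score_matrix()
        if kind == "numeric":
            proc = score_process(scores, z, rng=rng)
            stat, cut = max_lm_numeric(proc, trim=ctl.trim, min_size=self._floor)
            if stat is None:
                return None
            return SplitRule(covariate, "numeric_threshold",
                             float(proc.z_sorted[cut - 1]))
        proc = score_process(scores, z, rng=rng)
        n = node.n
        if kind == "ordinal":
            best, best_lm = None, -np.inf
            for lev in self._admissible_level_cuts(z):
                j = int((proc.z_sorted <= lev).sum())
                t = j / n
                lm = (proc.process[j] ** 2).sum() / (t * (1 - t))
                if lm > best_lm + 1e-12:
                    best, best_lm = lev, lm
            if best is None:
                return None
            return SplitRule(covariate, "ordinal_threshold", best)
        # categorical: exhaustive binary partitions scored by the LM form
        droot = proc.decorrelation
        psi = scores.values
        best, best_lm, tied = None, -np.inf, False
        for a in self._admissible_subsets(z):
            mask = np.isin(z, list(a))
            t = mask.mean()
            s = droot @ psi[mask].sum(axis=0) / np.sqrt(n)
            lm = (s @ s) / (t * (1 - t))
            if lm > best_lm + 1e-12:
                best, best_lm, tied = a, lm, False
            elif abs(lm - best_lm) <= 1e-12 and best is not None:
                tied = True
                if tuple(sorted(a)) < tuple(sorted(best)):
                    best = a
        if best is None:
            return None
        return SplitRule(covariate, "category_subset", best, tied=tied)

    def _candidate_rules(self, node: TreeNode, covariate: str):
        z = self.exog[covariate].to_numpy()[node.case_index]
        kind = self.kinds[covariate]
        if kind == "categorical":
            return [SplitRule(covariate, "category_subset", a)
                    for a in self._admissible_subsets(z)]
        levels = self._admissible_level_cuts(z)
        if kind == "numeric" and len(levels) > self.controls.max_candidates:
            qs = np.linspace(0, 1, self.controls.max_candidates)
            levels = sorted(set(np.quantile(np.asarray(levels, float), qs)))
        rkind = "numeric_threshold" if kind == "numeric" else "ordinal_threshold"
        return [SplitRule(covariate, rkind, lev) for lev in levels]

    def _children_deviance(self, node: TreeNode, rule: SplitRule):
        """Summed children deviance -2 (ll_left + ll_right); None if a child
        fit fails."""
        z = self.exog[rule.covariate].to_numpy()[node.case_index]
        mask = rule.goes_left(z)
        start = self._struct_params(node.ml_fit)
        lfit = self._fit_node(node.case_index[mask], start=start)
        rfit = self._fit_node(node.case_index[~mask], start=start)
        if lfit is None or rfit is None or not (lfit.converged and rfit.converged):
            return None, None, None
        return -2.0 * (lfit.llf + rfit.llf), lfit, rfit

    def find_split_objective(self, node: TreeNode, covariate: str):
        """Exhaustive segmented-objective comparison: one child-pair fit per
        admissible cut, choose the cut minimizing the summed deviance."""
        best, best_dev, tied = None, np.inf, False
        for rule in self._candidate_rules(node, covariate):
            dev, _, _ = self._children_deviance(node, rule)
            if dev is None:
                continue
            if dev < best_dev - 1e-9:
                best, best_dev, tied = rule, dev, False
            elif dev <= best_dev + 1e-9 and best is not None:
                tied = True
        if best is not None and tied:
            best = SplitRule(best.covariate, best.kind, best.boundary, tied=True)
        return best

    def _find_split_naive(self, node: TreeNode, zsub: pd.DataFrame):
        """Per covariate the max-LR cut; covariate by smallest adjusted
        LR p-value."""
        ctl = self.controls
        entries = []
        for col in zsub.columns:
            best_rule, best_stat = None, -np.inf
            for rule in self._candidate_rules(node, col):
                dev, lfit, rfit = self._children_deviance(node, rule)
                if dev is None:
                    continue
                stat, df, p = lr_test(node.ml_fit, lfit, rfit)
                if stat > best_stat:
                    best_rule, best_stat, best_p = rule, stat, p
            if best_rule is not None:
                entries.append((best_p, col, best_rule))
        if not entries:
            return None
        r = len(entries) if ctl.bonferroni else 1
        entries.sort(key=lambda e: (e[0], e[1]))
        p, col, rule = entries[0]
        if min(1.0, r * p) < ctl.alpha:
            return rule
        return None


class TreeResults:
    """A grown DIF tree: per-node fits, split rules and leaf partition."""

    def __init__(self, model: DifTree, root: TreeNode, nodes: list):
        self.model = model
        self.root = root
        self.nodes = nodes

    def leaves(self) -> list:
        return [nd for nd in self.nodes if nd.is_terminal]

    def leaf_case_sets(self) -> list:
        return [frozenset(nd.case_index.tolist()) for nd in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def refit_terminal_nodes(self, cache: dict = None) -> "TreeResults":
        """WLS re-estimation of every leaf (ordinal responses).

        Numeric-response trees keep their ML fits (the refit does not apply);
        leaves too homogeneous for polychoric estimation are flagged
        unevaluable. ``cache`` (case-set -> WLSResults) lets a forest share
        refits of identical leaves across trees (no bagging, so the same
        case set always carries the same data).
        """
        if not self.model.spec.is_ordinal:
            return self
        data = self.model.endog.astype(int)
        for leaf in self.leaves():
            if leaf.wls_fit is not None:
                continue
            key = frozenset(leaf.case_index.tolist())
            if cache is not None and key in cache:
                leaf.wls_fit = cache[key]
                continue
            try:
                leaf.wls_fit = OrdinalWLS(data[leaf.case_index],
                                          self.model.spec).fit()
                if cache is not None:
                    cache[key] = leaf.wls_fit
            except (ValueError, np.linalg.LinAlgError) as exc:
                leaf.unevaluable = True
                leaf.note = f"WLS refit failed: {exc}"
        return self

    def leaf_fit_indices(self, leaf: TreeNode):
        """(chi2, df, p, rmsea, ci) of a leaf: WLS for ordinal responses,
        ML-based otherwise."""
        if self.model.spec.is_ordinal:
            if leaf.wls_fit is None:
                self.refit_terminal_nodes()
            if leaf.wls_fit is None:
                return None
            return leaf.wls_fit.fit_indices()
        return leaf.ml_fit.fit_indices()

    def render(self) -> str:
        """Indented text diagram of the tree."""
        lines = []

        def rec(node, prefix):
            tag = f"[{node.id}] n={node.n}"
            if node.is_terminal:
                fi = None
                if node.wls_fit is not None:
                    fi = node.wls_fit
                if fi is not None:
                    tag += (f"  chi2={fi.chi2:.2f} df={fi.df} "
                            f"rmsea={fi.rmsea:.3f}")
                lines.append(f"{prefix}* {tag}  <{node.rule_string()}>")
            else:
                lines.append(f"{prefix}{tag}  split: {node.split.covariate}")
                for child, left in zip(node.children, (True, False)):
                    lines.append(
                        f"{prefix}|- {node.split.describe(left)}")
                    rec(child, prefix + "|  ")

        rec(self.root, "")
        return "\n".join(lines)

    def summary(self) -> str:
        ctl = self.model.controls
        head = [
            "DIF recursive-partitioning tree",
            f"  method = {ctl.method}, alpha = {ctl.alpha}, "
            f"bonferroni = {ctl.bonferroni}, min_size = {ctl.min_size}, "
            f"seed = {ctl.seed}",
            f"  n = {self.root.n}, leaves = {self.n_leaves}",
            "",
        ]
        return "\n".join(head) + self.render()


def classify_tree_stability(results: TreeResults, manifest) -> str:
    """Classify a grown tree against a scenario manifest.

    ``"stable"``: leaf partition coincides exactly with the planted subgroups
    (all split covariates and boundaries effectively correct).
    ``"inaccurate_split_point"``: the correct covariates (and exact
    categorical/ordinal boundaries) are used and the leaf count is right, but
    a numeric split point is misplaced.
    ``"incorrect_split"``: at least one faulty split (wrong covariate, wrong
    categorical subset / ordinal cut, or wrong structure).
    """
    labels = np.asarray(manifest.labels)
    if len(labels) != results.root.n:
        raise ValueError("manifest does not match the fitted sample")
    group_names = [g for g in manifest.group_names() if g != "random"]
    truth = {frozenset(np.where(labels == g)[0].tolist()) for g in group_names}
    leaf_sets = set(results.leaf_case_sets())

    relevant = {cond[0] for rules in manifest.subgroup_rules.values()
                for cond in rules}
    internal = [nd for nd in results.nodes if not nd.is_terminal]
    for nd in internal:
        if nd.split.covariate not in relevant:
            return "incorrect_split"

    if truth <= leaf_sets and len(leaf_sets) == len(truth):
        return "stable"

    # boundary check for non-numeric splits
    for nd in internal:
        rule = nd.split
        conds = [cond for rules in manifest.subgroup_rules.values()
                 for cond in rules if cond[0] == rule.covariate]
        if rule.kind == "category_subset":
            sets = []
            universe = set(np.unique(results.model.exog[rule.covariate]))
            for _, op, val in conds:
                if op == "in":
                    sets.append(frozenset(val))
                    sets.append(frozenset(universe - set(val)))
            if frozenset(rule.boundary) not in sets:
                return "incorrect_split"
        elif rule.kind == "ordinal_threshold":
            bounds = set()
            for _, op, val in conds:
                if op == "<=":
                    bounds.add(val)
                elif op == "<":
                    bounds.add(val - 1)
                elif op == ">=":
                    bounds.add(val - 1)
                elif op == ">":
                    bounds.add(val)
            if rule.boundary not in bounds:
                return "incorrect_split"
    if len(leaf_sets) == len(truth):
        return "inaccurate_split_point"
    return "incorrect_split"
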