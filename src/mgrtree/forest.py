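"""Decorrelated tree ensembles for robust subgroup discovery.

A :class:`DifForest` grows ``n_trees`` recursive-partitioning trees on the
FULL sample (no bagging -- terminal-node parameter estimates stay directly
replicable on the original data), decorrelating trees solely by redrawing a
random subset of ``mtry`` candidate partitioning variables at every node.
After growth every terminal node is re-estimated (WLS for ordinal responses)
and leaves whose fit passes a cutoff (RMSEA below, or chi-square p-value
above, a threshold) are pooled into :class:`SubgroupReport` entries: identical
case sets are merged with a frequency count (the number of trees realizing
that subgroup), and strict-subset relations between reports are annotated --
recurring subsets of a well-fitting subgroup are expected by-products, not
independent findings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import MgrModelSpec
from .tree import DifTree, TreeControls, TreeResults

__all__ = [
    "ForestControls",
    "DifForest",
    "ForestResults",
    "SubgroupReport",
    "filter_subgroups",
    "recovery_experiment",
]


@dataclass
class ForestControls:
    """Ensemble controls: tree count, per-node covariate draw, fit cutoff."""

    n_trees: int = 50
    mtry: int = 3
    cutoff_kind: str = "rmsea"   # or "chi2_p"
    cutoff_value: float = 0.05
    tree_controls: TreeControls = field(default_factory=TreeControls)
    seed: int = 0
    bootstrap: bool = False  # non-canonical; kept off by default

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cutoff_kind not in ("rmsea", "chi2_p"):
            raise ValueError(f"unknown cutoff_kind {self.cutoff_kind!r}")


@dataclass
class SubgroupReport:
    """An aggregated, well-fitting subgroup found by the forest."""

    rule: str
    case_set: frozenset
    n: int
    chi2: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci: tuple
    frequency: int
    subset_of: list = field(default_factory=list)


class DifForest:
    """Ensemble of DIF trees with per-node random covariate subsampling."""

    def __init__(self, endog, exog: pd.DataFrame, spec: MgrModelSpec,
                 kinds: dict = None, controls: ForestControls = None):
        self.endog = endog
        self.exog = exog
        self.spec = spec
        self.kinds = kinds
        self.controls = controls if controls is not None else ForestControls()
        if not 1 <= self.controls.mtry <= exog.shape[1]:
            raise ValueError("mtry must be between 1 and the covariate count")

    def fit(self) -> "ForestResults":
        ctl = self.controls
        master = np.random.SeedSequence(ctl.seed)
        tree_seeds = master.generate_state(ctl.n_trees) % (2**31 - 1)
        trees, skipped = [], 0
        rng = np.random.default_rng(master.spawn(1)[0])
        wls_cache: dict = {} if not ctl.bootstrap else None
        for b in range(ctl.n_trees):
            tc = TreeControls(**{**ctl.tree_controls.__dict__,
                                 "mtry": ctl.mtry,
                                 "seed": int(tree_seeds[b])})
            endog, exog = self.endog, self.exog
            if ctl.bootstrap:
                idx = rng.integers(0, len(self.exog), size=len(self.exog))
                endog = np.asarray(self.endog)[idx]
                exog = self.exog.iloc[idx].reset_index(drop=True)
            try:
                res = DifTree(endog, exog, self.spec, kinds=self.kinds,
                              controls=tc).fit()
                res.refit_terminal_nodes(cache=wls_cache)
                trees.append(res)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                skipped += 1
        return ForestResults(self, trees, skipped)


class ForestResults:
    """Grown forest: member trees plus the aggregated subgroup report."""

    def __init__(self, model: DifForest, trees: list, skipped: int):
        self.model = model
        self.trees = trees
        self.n_skipped = skipped

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def subgroups(self) -> list:
        return filter_subgroups(self)

    def report_table(self) -> pd.DataFrame:
        rows = []
        for rep in self.subgroups():
            rows.append({
                "rule": rep.rule, "n": rep.n, "chi2": rep.chi2, "df": rep.df,
                "p": rep.p_value, "rmsea": rep.rmsea,
                "ci_low": rep.rmsea_ci[0], "ci_high": rep.rmsea_ci[1],
                "freq": rep.frequency,
                "subset_of": ";".join(rep.subset_of),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ctl = self.model.controls
        lines = [
            "DIF forest",
            f"  trees = {self.n_trees} (skipped {self.n_skipped}), "
            f"mtry = {ctl.mtry}, cutoff: {ctl.cutoff_kind} "
            f"{'<=' if ctl.cutoff_kind == 'rmsea' else '>='} {ctl.cutoff_value}",
        ]
        tab = self.report_table()
        if len(tab):
            lines.append(tab.to_string(index=False,
                                       float_format=lambda v: f"{v:.3f}"))
        else:
            lines.append("  no subgroup passed the fit cutoff")
        return "\n".join(lines)


def _leaf_passes(indices, kind: str, value: float) -> bool:
    chi2, df, p, rmsea, _ = indices
    if kind == "rmsea":
        return np.isfinite(rmsea) and rmsea <= value
    return np.isfinite(p) and p >= value


def filter_subgroups(forest: ForestResults) -> list:
    """Pool cutoff-passing leaves across trees into merged subgroup reports.

    Identity is the case-index set (different but equivalent rules merge);
    reports are sorted by fit (ascending RMSEA, then descending p-value) and
    annotated with the reports whose case sets strictly contain them.
    """
    ctl = forest.model.controls
    found: dict = {}
    for res in forest.trees:
        seen_in_tree = set()
        for leaf in res.leaves():
            indices = res.leaf_fit_indices(leaf)
            if indices is None or not _leaf_passes(indices, ctl.cutoff_kind,
                                                   ctl.cutoff_value):
                continue
            cs = frozenset(leaf.case_index.tolist())
            if cs in seen_in_tree:
                continue
            seen_in_tree.add(cs)
            chi2, df, p, rmsea, ci = indices
            if cs in found:
                found[cs].frequency += 1
            else:
                found[cs] = SubgroupReport(
                    rule=leaf.rule_string(), case_set=cs, n=len(cs),
                    chi2=chi2, df=df, p_value=p, rmsea=rmsea, rmsea_ci=ci,
                    frequency=1)
    reports = list(found.values())
    for rep in reports:
        rep.subset_of = sorted(
            other.rule for other in reports
            if other.case_set > rep.case_set)
    reports.sort(key=lambda r: (r.rmsea if np.isfinite(r.rmsea) else np.inf,
                                -(r.p_value if np.isfinite(r.p_value) else 0.0),
                                r.rule))
    return reports


def recovery_experiment(scenario: str, n_datasets: int, n_trees: int,
                        controls: ForestControls = None, seed: int = 0,
                        jaccard: float = None):
    """Repeat forests over fresh scenario samples and score subgroup recovery.

    ``scenario``: ``"sim2_ordinal"`` or ``"sim2_numeric"``. A planted
    subgroup counts as recovered when some filtered report's case set equals
    its case set exactly (or has Jaccard similarity >= ``jaccard`` when that
    relaxation is requested). Returns a dict with the fraction of forests
    recovering at least one subgroup, the fraction recovering both, and
    binomial standard errors.
    """
    from .simulate import make_scenario2

    scale = {"sim2_ordinal": "ordinal", "sim2_numeric": "numeric"}[scenario]
    if controls is None:
        controls = ForestControls(
            n_trees=n_trees, mtry=3, cutoff_kind="rmsea", cutoff_value=0.05,
            tree_controls=TreeControls(min_size=100))
    ss = np.random.SeedSequence(seed)
    data_seeds = ss.generate_state(2 * n_datasets) % (2**31 - 1)
    any_hit = np.zeros(n_datasets, dtype=bool)
    both_hit = np.zeros(n_datasets, dtype=bool)
    for d in range(n_datasets):
        data, cov, manifest = make_scenario2(scale, seed=int(data_seeds[d]))
        ctl = ForestControls(**{**controls.__dict__, "n_trees": n_trees,
                                "seed": int(data_seeds[n_datasets + d])})
        forest = DifForest(data, cov, manifest_spec(scale), kinds=manifest.kinds,
                           controls=ctl).fit()
        reports = forest.subgroups()
        hits = []
        for name in manifest.group_names():
            truth = manifest.case_set(name)
            ok = False
            for rep in reports:
                if jaccard is None:
                    ok = rep.case_set == truth
                else:
                    inter = len(rep.case_set & truth)
                    union = len(rep.case_set | truth)
                    ok = union > 0 and inter / union >= jaccard
                if ok:
                    break
            hits.append(ok)
        any_hit[d] = any(hits)
        both_hit[d] = all(hits)
    out = {}
    for key, arr in (("any", any_hit), ("both", both_hit)):
        frac = float(arr.mean())
        out[f"frac_{key}"] = frac
        out[f"se_{key}"] = float(np.sqrt(frac * (1 - frac) / n_datasets))
    return out


def manifest_spec(scale: str) -> MgrModelSpec:
    from .model_spec import build_pieg_spec

    return build_pieg_spec(3, 3, 5, response_scale=scale)
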