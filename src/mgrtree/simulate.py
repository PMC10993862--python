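"""Synthetic-data factory for the DIF partitioning experiments.

Generates ordinal data from the probit multistate model with latent item
effects (reference state latents ``eta_t``, item-effect latents ``b_i``, all
discriminations fixed at 1):

    P(Y_it >= k | eta_t, b_i) = Phi(eta_t + b_i - kappa_ikt),

implemented by drawing the latent vector from a zero-mean multivariate normal,
adding a standard-normal unique part, and discretizing at the item thresholds.
The numeric twin generates

    Y_it = pi_it + eta_t + b_i + eps_i

with independent normal residuals.

Two scenario builders plant covariate-defined DIF subgroups:

* Scenario 1 (single-tree benchmark): n = 2000, four subgroups of 500 cut out
  by num1 (integer 1..200), cat1 (5-level, unordered) and cat2 (5-level,
  ordered), plus five uninformative covariates (rand1-rand2 numeric,
  rand3-rand5 ordinal). Each subgroup gets its own parameter set.
* Scenario 2 (forest benchmark): n = 2000, two exclusive subgroups of 500
  (rules over cat2, num1, dicho1, cat1), the remaining 1000 cases filled with
  random responses (uniform categories / uniform(-3, 3) values), so that the
  measurement model holds only inside the planted subgroups and the structure
  is not representable by a single binary tree.

Group parameters are sampled per subgroup (thresholds/intercepts normal,
variances and correlations uniform) and resampled until the subgroup's own
model fits its data with RMSEA <= 0.05, so planted subgroups are genuinely
well-fitting. All randomness flows from the passed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ml import CovarianceStructureML
from .model_spec import MgrModelSpec, ParameterVector, build_pieg_spec
from .wls import OrdinalWLS

__all__ = [
    "PiegParameters",
    "ScenarioManifest",
    "sample_group_parameters",
    "simulate_pieg",
    "simulate_cfa",
    "make_scenario1",
    "make_scenario2",
]

_N_SCENARIO = 2000
_GROUP_SIZE = 500
_RMSEA_BUDGET = 40


@dataclass
class PiegParameters:
    """Parameters of one subgroup's data-generating model."""

    latent_cov: np.ndarray           # covariance of (eta_1..eta_T, b_2..b_I)
    thresholds: list = None          # per observed item, strictly increasing
    intercepts: np.ndarray = None    # numeric twin
    residual_var: np.ndarray = None  # numeric twin

    def validate(self):
        w = np.linalg.eigvalsh(self.latent_cov)
        if w.min() <= 0:
            raise ValueError("latent covariance is not positive definite")
        if self.thresholds is not None:
            for th in self.thresholds:
                if not np.all(np.diff(th) > 0):
                    raise ValueError("thresholds not strictly increasing")
        if self.residual_var is not None and np.any(self.residual_var <= 0):
            raise ValueError("residual variances must be positive")


@dataclass
class ScenarioManifest:
    """Ground truth of a simulated scenario."""

    labels: np.ndarray               # per-case subgroup name or "random"
    subgroup_rules: dict             # name -> list of (covariate, op, value)
    group_parameters: dict           # name -> PiegParameters
    kinds: dict                      # covariate -> kind
    seed: int
    response_scale: str
    rejection_counts: dict = field(default_factory=dict)

    def group_names(self) -> list:
        return list(self.subgroup_rules.keys())

    def case_set(self, name: str) -> frozenset:
        return frozenset(np.where(self.labels == name)[0].tolist())

    def evaluate_rules(self, covariates: pd.DataFrame) -> np.ndarray:
        """Re-derive labels from the rules (consistency audit)."""
        labels = np.full(len(covariates), "random", dtype=object)
        for name, conds in self.subgroup_rules.items():
            mask = np.ones(len(covariates), dtype=bool)
            for cov, op, val in conds:
                z = covariates[cov].to_numpy()
                if op == "in":
                    mask &= np.isin(z, list(val))
                elif op == "<=":
                    mask &= z <= val
                elif op == "<":
                    mask &= z < val
                elif op == ">=":
                    mask &= z >= val
                elif op == ">":
                    mask &= z > val
            labels[mask] = name
        return labels.astype(str)


def _nearest_psd_corr(r: np.ndarray) -> np.ndarray:
    """Clip eigenvalues and renormalize to unit diagonal."""
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 1e-4, None)
    r2 = (v * w) @ v.T
    d = 1.0 / np.sqrt(np.diag(r2))
    return r2 * d[:, None] * d[None, :]


def sample_group_parameters(spec: MgrModelSpec, rng: np.random.Generator,
                            min_gap: float = 0.25) -> PiegParameters:
    """Draw one subgroup's generating parameters.

    Thresholds: sorted i.i.d. N(0, 1) draws per item, redrawn until adjacent
    thresholds are at least ``min_gap`` apart (avoids near-empty categories).
    Latent variances Uniform(0.5, 1.5); latent correlations Uniform(0.1, 0.5)
    projected to the nearest positive-definite correlation matrix. Intercepts
    N(0, 1) and residual variances Uniform(0.5, 1.5) for the numeric twin.
    """
    p = spec.n_latents
    m = spec.n_items
    var = rng.uniform(0.5, 1.5, size=p)
    corr = np.eye(p)
    iu = np.triu_indices(p, 1)
    corr[iu] = rng.uniform(0.1, 0.5, size=len(iu[0]))
    corr = _nearest_psd_corr(corr + corr.T - np.eye(p) * corr.diagonal())
    cov = corr * np.sqrt(np.outer(var, var))
    params = PiegParameters(latent_cov=cov)
    if spec.is_ordinal:
        ths = []
        for i in range(m):
            nth = int(spec.n_categories[i]) - 1
            for _ in range(100):
                th = np.sort(rng.normal(size=nth))
                if nth < 2 or np.diff(th).min() >= min_gap:
                    break
            ths.append(th)
        params.thresholds = ths
    else:
        params.intercepts = rng.normal(size=m)
        params.residual_var = rng.uniform(0.5, 1.5, size=m)
    params.validate()
    return params


def simulate_pieg(params: PiegParameters, n: int, seed, spec: MgrModelSpec = None):
    """Ordinal responses (codes 0..K-1) from the probit multistate model."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spec is None:
        spec = _default_spec("ordinal")
    params.validate()
    lam = spec.loadings
    xi = rng.multivariate_normal(np.zeros(spec.n_latents), params.latent_cov,
                                 size=n, method="cholesky")
    ystar = xi @ lam.T + rng.standard_normal((n, spec.n_items))
    out = np.zeros((n, spec.n_items), dtype=int)
    for i in range(spec.n_items):
        out[:, i] = np.searchsorted(params.thresholds[i], ystar[:, i])
    return pd.DataFrame(out, columns=spec.item_names)


def simulate_cfa(params: PiegParameters, n: int, seed, spec: MgrModelSpec = None):
    """Numeric responses from the CFA twin with normal residuals."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spec is None:
        spec = _default_spec("numeric")
    params.validate()
    lam = spec.loadings
    xi = rng.multivariate_normal(np.zeros(spec.n_latents), params.latent_cov,
                                 size=n, method="cholesky")
    eps = rng.standard_normal((n, spec.n_items)) * np.sqrt(params.residual_var)
    y = params.intercepts + xi @ lam.T + eps
    return pd.DataFrame(y, columns=spec.item_names)


def _default_spec(scale: str) -> MgrModelSpec:
    return build_pieg_spec(3, 3, 5, response_scale=scale)


def _group_fits_well(data, scale: str) -> bool:
    """RMSEA <= 0.05 of the subgroup's own model on its own data."""
    try:
        if scale == "ordinal":
            fit = OrdinalWLS(data.to_numpy(), _default_spec("ordinal")).fit()
            rmsea = fit.rmsea
        else:
            res = CovarianceStructureML(data, _default_spec("numeric")).fit()
            _, _, _, rmsea, _ = res.fit_indices()
    except (ValueError, np.linalg.LinAlgError):
        return False
    return np.isfinite(rmsea) and rmsea <= 0.05


def _simulate_group(scale: str, n: int, rng) -> tuple:
    """(responses, params) resampled until the subgroup model fits well."""
    spec = _default_spec(scale)
    for attempt in range(_RMSEA_BUDGET):
        params = sample_group_parameters(spec, rng)
        if scale == "ordinal":
            data = simulate_pieg(params, n, rng, spec=spec)
            if data.nunique().min() < 2:
                continue
        else:
            data = simulate_cfa(params, n, rng, spec=spec)
        if _group_fits_well(data, scale):
            return data, params, attempt + 1
    raise RuntimeError(
        f"could not generate a well-fitting subgroup within {_RMSEA_BUDGET} "
        "attempts; inspect the parameter-sampling settings")


def _rand_covariates(rng, n: int) -> dict:
    """Uninformative partitioning variables: two numeric, three ordinal."""
    return {
        "rand1": rng.integers(1, 201, size=n),
        "rand2": rng.integers(1, 201, size=n),
        "rand3": rng.integers(1, 6, size=n),
        "rand4": rng.integers(1, 6, size=n),
        "rand5": rng.integers(1, 6, size=n),
    }


def make_scenario1(response_scale: str = "ordinal", seed: int = 0):
    """Single-tree benchmark sample.

    Returns ``(data, covariates, manifest)``: 2000 x 9 responses, 2000 x 8
    covariates, four planted subgroups of 500 defined by
    R1 = {num1 < 100, cat1 in {1, 5}}, R2 = {num1 < 100, cat1 in {2, 3, 4}},
    R3 = {num1 >= 100, cat2 <= 2}, R4 = {num1 >= 100, cat2 >= 3}.
    """
    rng = np.random.default_rng(seed)
    rules = {
        "R1": [("num1", "<", 100), ("cat1", "in", frozenset({1, 5}))],
        "R2": [("num1", "<", 100), ("cat1", "in", frozenset({2, 3, 4}))],
        "R3": [("num1", ">=", 100), ("cat2", "<=", 2)],
        "R4": [("num1", ">=", 100), ("cat2", ">=", 3)],
    }
    kinds = {"num1": "numeric", "cat1": "categorical", "cat2": "ordinal",
             "rand1": "numeric", "rand2": "numeric", "rand3": "ordinal",
             "rand4": "ordinal", "rand5": "ordinal"}
    g = _GROUP_SIZE
    num1 = np.concatenate([
        rng.integers(1, 100, size=g), rng.integers(1, 100, size=g),
        rng.integers(100, 201, size=g), rng.integers(100, 201, size=g)])
    cat1 = np.concatenate([
        rng.choice([1, 5], size=g), rng.choice([2, 3, 4], size=g),
        rng.integers(1, 6, size=g), rng.integers(1, 6, size=g)])
    cat2 = np.concatenate([
        rng.integers(1, 6, size=g), rng.integers(1, 6, size=g),
        rng.integers(1, 3, size=g), rng.integers(3, 6, size=g)])
    labels = np.repeat(["R1", "R2", "R3", "R4"], g)
    blocks, group_params, rejections = [], {}, {}
    for name in ("R1", "R2", "R3", "R4"):
        data, params, tries = _simulate_group(response_scale, g, rng)
        blocks.append(data)
        group_params[name] = params
        rejections[name] = tries
    data = pd.concat(blocks, ignore_index=True)
    cov = pd.DataFrame({"num1": num1, "cat1": cat1, "cat2": cat2,
                        **_rand_covariates(rng, 4 * g)})
    perm = rng.permutation(4 * g)
    data = data.iloc[perm].reset_index(drop=True)
    cov = cov.iloc[perm].reset_index(drop=True)
    manifest = ScenarioManifest(
        labels=labels[perm], subgroup_rules=rules, group_parameters=group_params,
        kinds=kinds, seed=seed, response_scale=response_scale,
        rejection_counts=rejections)
    assert (manifest.evaluate_rules(cov) == manifest.labels).all()
    return data, cov, manifest


def make_scenario2(response_scale: str = "ordinal", seed: int = 0):
    """Forest benchmark sample.

    Returns ``(data, covariates, manifest)``: 2000 x 9 responses, 2000 x 9
    covariates. Two exclusive planted subgroups of 500 --
    R1 = {cat2 in {3, 4}, num1 <= 50} and R2 = {dicho1 = 0, cat1 in {1, 4, 5}}
    -- and 1000 cases of random responses for which no measurement model
    holds. cat1 and cat2 are unordered here; dicho1 is dichotomous.
    """
    rng = np.random.default_rng(seed)
    rules = {
        "R1": [("cat2", "in", frozenset({3, 4})), ("num1", "<=", 50)],
        "R2": [("dicho1", "in", frozenset({0})), ("cat1", "in", frozenset({1, 4, 5}))],
    }
    kinds = {"cat1": "categorical", "cat2": "categorical", "num1": "numeric",
             "dicho1": "categorical", "rand1": "numeric", "rand2": "numeric",
             "rand3": "ordinal", "rand4": "ordinal", "rand5": "ordinal"}
    g = _GROUP_SIZE
    n = _N_SCENARIO

    def in_r1(cat2, num1):
        return (cat2 in (3, 4)) and num1 <= 50

    def in_r2(dicho1, cat1):
        return dicho1 == 0 and cat1 in (1, 4, 5)

    rows = []
    # R1 members: satisfy R1, avoid R2
    while len(rows) < g:
        cat2 = rng.choice([3, 4])
        num1 = int(rng.integers(1, 51))
        cat1 = int(rng.integers(1, 6))
        dicho1 = int(rng.integers(0, 2))
        if not in_r2(dicho1, cat1):
            rows.append((cat1, cat2, num1, dicho1))
    # R2 members: satisfy R2, avoid R1
    while len(rows) < 2 * g:
        cat1 = int(rng.choice([1, 4, 5]))
        dicho1 = 0
        cat2 = int(rng.integers(1, 6))
        num1 = int(rng.integers(1, 201))
        if not in_r1(cat2, num1):
            rows.append((cat1, cat2, num1, dicho1))
    # random half: avoid both rules
    while len(rows) < n:
        cat1 = int(rng.integers(1, 6))
        cat2 = int(rng.integers(1, 6))
        num1 = int(rng.integers(1, 201))
        dicho1 = int(rng.integers(0, 2))
        if not in_r1(cat2, num1) and not in_r2(dicho1, cat1):
            rows.append((cat1, cat2, num1, dicho1))
    zcore = pd.DataFrame(rows, columns=["cat1", "cat2", "num1", "dicho1"])
    labels = np.array(["R1"] * g + ["R2"] * g + ["random"] * (n - 2 * g))

    spec = _default_spec(response_scale)
    blocks, group_params, rejections = [], {}, {}
    for name in ("R1", "R2"):
        data, params, tries = _simulate_group(response_scale, g, rng)
        blocks.append(data)
        group_params[name] = params
        rejections[name] = tries
    if response_scale == "ordinal":
        noise = pd.DataFrame(rng.integers(0, 5, size=(n - 2 * g, spec.n_items)),
                             columns=spec.item_names)
    else:
        noise = pd.DataFrame(rng.uniform(-3.0, 3.0, size=(n - 2 * g, spec.n_items)),
                             columns=spec.item_names)
    data = pd.concat(blocks + [noise], ignore_index=True)
    cov = pd.concat([zcore, pd.DataFrame(_rand_covariates(rng, n))], axis=1)
    perm = rng.permutation(n)
    data = data.iloc[perm].reset_index(drop=True)
    cov = cov.iloc[perm].reset_index(drop=True)
    manifest = ScenarioManifest(
        labels=labels[perm], subgroup_rules=rules, group_parameters=group_params,
        kinds=kinds, seed=seed, response_scale=response_scale,
        rejection_counts=rejections)
    assert (manifest.evaluate_rules(cov) == manifest.labels).all()
    return data, cov, manifest
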