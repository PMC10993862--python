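"""Distribution-free estimation for ordinal measurement models.

Terminal-node evaluation engine: item thresholds from cumulative margins,
pairwise polychoric correlations by two-step maximum likelihood (thresholds
held fixed), and weighted least squares (WLS) fitting of the latent structure

    F_WLS(theta) = [kappa-hat - kappa(theta)]' W-hat [kappa-hat - kappa(theta)],

where ``kappa-hat`` stacks the below-diagonal polychoric correlations and
``W-hat`` is the inverse of their asymptotic covariance, assembled empirically
from casewise pairwise-likelihood influence functions. The model-implied
``kappa(theta)`` is the correlation matrix of the latent responses,
``corr(Lambda Phi Lambda' + I)``. Fit statistics use ``chi2 = n * F_WLS``
and RMSEA with a noncentral-chi-square confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .model_spec import MgrModelSpec, ParameterVector

__all__ = [
    "estimate_thresholds",
    "polychoric",
    "polychoric_pair",
    "PolychoricSummary",
    "OrdinalWLS",
    "WLSResults",
    "rmsea_from_chi2",
    "bvn_cdf",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)
_RHO_MAX = 0.999


# --------------------------------------------------------------------- bvn
def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k), vectorized in h, k.

    Gauss-Legendre quadrature on the Drezner-Wesolowsky angle representation

        Phi2(h, k, rho) = Phi(h) Phi(k)
            + (1/2pi) int_0^{asin rho} exp(-(h^2 + k^2 - 2 h k sin t)
                                           / (2 cos^2 t)) dt,

    accurate to ~1e-10 for |rho| <= 0.999 at the clipped range |h|,|k| <= 8.
    """
    h = np.clip(np.asarray(h, dtype=float), -8.5, 8.5)
    k = np.clip(np.asarray(k, dtype=float), -8.5, 8.5)
    rho = float(np.clip(rho, -_RHO_MAX, _RHO_MAX))
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return base
    asr = np.arcsin(rho)
    t = 0.5 * asr * (_GL_NODES + 1.0)  # nodes on (0, asin rho)
    sint = np.sin(t)
    cos2 = 1.0 - sint**2
    hh = h[..., None]
    kk = k[..., None]
    expo = np.exp(-(hh**2 + kk**2 - 2.0 * hh * kk * sint) / (2.0 * cos2))
    integral = 0.5 * asr * (expo * _GL_WEIGHTS).sum(axis=-1)
    return base + integral / (2.0 * np.pi)


def _bvn_pdf(h, k, rho: float):
    """phi2(h, k; rho); zero at infinite arguments."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    om = 1.0 - rho**2
    with np.errstate(over="ignore", invalid="ignore"):
        z = (h**2 - 2.0 * rho * h * k + k**2) / om
        out = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(om))
    return np.where(np.isfinite(h) & np.isfinite(k), np.nan_to_num(out), 0.0)


def _cell_probs(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a two-way table from padded thresholds.

    ``a``/``b`` include the -inf/+inf boundary entries.
    """
    aa = np.where(np.isfinite(a), a, np.sign(a) * 8.5)
    bb = np.where(np.isfinite(b), b, np.sign(b) * 8.5)
    grid = bvn_cdf(aa[:, None], bb[None, :], rho)
    p = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(p, 1e-12, None)


def _cell_dprobs(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """d cell-probability / d rho via the Plackett identity."""
    grid = _bvn_pdf(a[:, None], b[None, :], rho)
    return grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]


# -------------------------------------------------------------- thresholds
def estimate_thresholds(data) -> list:
    """Per-item threshold vectors alpha-hat = Phi^-1(cumulative proportions).

    ``data`` is an (n, m) integer table of category codes 0..l_i (a DataFrame
    or array). Raises if an item shows a single observed category.
    """
    cols = data.columns.tolist() if hasattr(data, "columns") else None
    arr = np.asarray(data, dtype=int)
    n, m = arr.shape
    out = []
    for i in range(m):
        vals = arr[:, i]
        ncat = int(vals.max()) + 1
        counts = np.bincount(vals, minlength=ncat)
        if (counts > 0).sum() < 2:
            name = cols[i] if cols else i
            raise ValueError(
                f"item {name!r} has a single observed category; the node is "
                "too homogeneous for threshold estimation"
            )
        cum = np.cumsum(counts)[:-1] / n
        out.append(stats.norm.ppf(cum))
    return out


# -------------------------------------------------------------- polychoric
@dataclass
class PolychoricSummary:
    """Two-step polychoric estimates for an ordinal item set."""

    thresholds: list
    corr_matrix: np.ndarray
    kappa_hat: np.ndarray
    acov: np.ndarray  # asymptotic covariance of kappa-hat (already / n)
    influence: np.ndarray  # n x P casewise influence contributions
    n: int
    item_names: list

    @property
    def n_pairs(self) -> int:
        return len(self.kappa_hat)


def polychoric_pair(x, y, thresholds_x=None, thresholds_y=None):
    """Two-step polychoric correlation of two ordinal variables.

    Thresholds default to the univariate margin estimates; the correlation
    maximizes the bivariate-normal likelihood of the contingency table with
    thresholds held fixed. Boundary solutions are clamped to +-0.999 with a
    warning. Returns ``(rho_hat, casewise_influence)``.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n = len(x)
    kx, ky = int(x.max()) + 1, int(y.max()) + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (x, y), 1.0)
    if thresholds_x is None:
        thresholds_x = estimate_thresholds(x[:, None])[0]
    if thresholds_y is None:
        thresholds_y = estimate_thresholds(y[:, None])[0]
    a = np.concatenate([[-np.inf], thresholds_x, [np.inf]])
    b = np.concatenate([[-np.inf], thresholds_y, [np.inf]])

    def nll(rho):
        return -(table * np.log(_cell_probs(a, b, rho))).sum()

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_MAX, _RHO_MAX), method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    if abs(rho) >= _RHO_MAX - 1e-6:
        rho = float(np.sign(rho) * _RHO_MAX)
        warnings.warn("polychoric correlation at boundary; clamped to +-0.999")
    # casewise influence: score / information of the pairwise likelihood
    p = _cell_probs(a, b, rho)
    dp = _cell_dprobs(a, b, rho)
    cell_score = dp / p
    info = (table * cell_score**2).sum() / n
    scores = cell_score[x, y]
    infl = scores / max(info, 1e-12)
    return rho, infl


def polychoric(data, item_names=None) -> PolychoricSummary:
    """Polychoric correlation matrix with empirical asymptotic covariance.

    The acov of the stacked below-diagonal correlations is assembled from the
    casewise influence contributions (outer-product estimate, divided by n);
    threshold-estimation noise is ignored (two-step convention).
    """
    if hasattr(data, "columns"):
        item_names = list(data.columns)
    arr = np.asarray(data, dtype=int)
    n, m = arr.shape
    if m < 2:
        raise ValueError("polychoric needs at least two items")
    if item_names is None:
        item_names = [f"y{i+1}" for i in range(m)]
    thresholds = estimate_thresholds(arr)
    npairs = m * (m - 1) // 2
    corr = np.eye(m)
    kappa = np.zeros(npairs)
    infl = np.zeros((n, npairs))
    pos = 0
    for s in range(m):
        for i in range(s + 1, m):
            # pair order matches row-major lower triangle (i > s)
            rho, u = polychoric_pair(
                arr[:, i], arr[:, s], thresholds[i], thresholds[s]
            )
            corr[i, s] = corr[s, i] = rho
            kappa[pos] = rho
            infl[:, pos] = u
            pos += 1
    uc = infl - infl.mean(axis=0)
    acov = uc.T @ uc / n / n
    return PolychoricSummary(
        thresholds=thresholds,
        corr_matrix=corr,
        kappa_hat=kappa,
        acov=acov,
        influence=infl,
        n=n,
        item_names=item_names,
    )


def _tri_indices(m):
    """Column-stacked lower-triangle order matching :func:`polychoric`."""
    rows, cols = [], []
    for s in range(m):
        for i in range(s + 1, m):
            rows.append(i)
            cols.append(s)
    return np.array(rows), np.array(cols)


# -------------------------------------------------------------------- WLS
class OrdinalWLS:
    """WLS estimation of an ordinal measurement model from polychorics.

    Parameters
    ----------
    endog : (n, m) ordinal table (codes 0..l_i) or DataFrame
    spec : MgrModelSpec (ordinal)
    summary : PolychoricSummary, optional
        Precomputed first-step estimates (otherwise computed from ``endog``).
    diagonal_weights : bool
        Use only the diagonal of the weight matrix (DWLS). Deviates from the
        full-weights definition; intended for large item sets.
    """

    def __init__(self, endog, spec: MgrModelSpec, summary: PolychoricSummary = None,
                 diagonal_weights: bool = False):
        if not spec.is_ordinal:
            raise ValueError("OrdinalWLS requires an ordinal spec")
        self.spec = spec
        if endog is not None and hasattr(endog, "columns"):
            endog = endog[spec.item_names]
        self.endog = endog
        self.summary = summary if summary is not None else polychoric(endog)
        self.nobs = self.summary.n
        self.diagonal_weights = diagonal_weights
        sp = spec
        self._free_names = [
            nm for nm in sp.free_parameter_names() if nm.startswith(("beta[", "var[", "cov["))
        ]
        self._rows, self._cols = _tri_indices(sp.n_items)

    def _kappa_of(self, s: np.ndarray) -> np.ndarray:
        theta = self._theta_of(s)
        lam = theta.loadings
        sig = lam @ theta.latent_cov @ lam.T + np.eye(self.spec.n_items)
        d = 1.0 / np.sqrt(np.diag(sig))
        corr = sig * d[:, None] * d[None, :]
        return corr[self._rows, self._cols]

    def _theta_of(self, s: np.ndarray) -> ParameterVector:
        # thresholds padded/clipped to the spec's category counts: a node may
        # not realize every category of every item
        ths = []
        for i in range(self.spec.n_items):
            need = int(self.spec.n_categories[i]) - 1
            th = np.clip(self.summary.thresholds[i], -8.0, 8.0)
            if len(th) < need:
                pad = th[-1] + np.arange(1, need - len(th) + 1) if len(th) else \
                    np.arange(1, need + 1, dtype=float)
                th = np.concatenate([th, pad])
            ths.append(th[:need])
        x = np.concatenate(ths + [s])
        return self.spec.unpack(x)

    def _start(self) -> np.ndarray:
        sp = self.spec
        s = []
        s.extend([1.0] * int(sp.loadings_free.sum()))
        s.extend([0.5] * int(np.diag(sp.latent_cov_free).sum()))
        s.extend([0.1] * int(sp.latent_cov_free[np.triu_indices(sp.n_latents, 1)].sum()))
        return np.asarray(s)

    def fit(self, start_params=None) -> "WLSResults":
        n_struct = len(self._free_names)
        npairs = len(self.summary.kappa_hat)
        df = npairs - n_struct
        if df < 0:
            raise ValueError("model not testable: more structural parameters "
                             "than polychoric moments")
        gamma = self.summary.acov * self.nobs  # per-case covariance
        if self.diagonal_weights:
            w = np.diag(1.0 / np.clip(np.diag(gamma), 1e-10, None))
        else:
            # repair near-singular weight matrices with a small ridge
            eps = 1e-8 * np.trace(gamma) / npairs
            w = np.linalg.inv(gamma + eps * np.eye(npairs))
        wroot = np.linalg.cholesky(0.5 * (w + w.T))

        kap = self.summary.kappa_hat
        if n_struct == 0:
            fwls = float((kap - self._kappa_of(np.zeros(0))) @ w
                         @ (kap - self._kappa_of(np.zeros(0))))
            return WLSResults(self, self._theta_of(np.zeros(0)), fwls, df, True)

        def resid(s):
            return wroot.T @ (kap - self._kappa_of(s))

        s0 = self._start() if start_params is None else np.asarray(start_params, float)
        lb = np.full(n_struct, -np.inf)
        ub = np.full(n_struct, np.inf)
        for j, nm in enumerate(self._free_names):
            if nm.startswith("var["):
                lb[j] = 1e-6
        s0 = np.clip(s0, lb + 1e-8, ub)
        res = optimize.least_squares(resid, s0, method="trf", bounds=(lb, ub),
                                     xtol=1e-12, ftol=1e-12, gtol=1e-10,
                                     max_nfev=2000)
        fwls = float(2.0 * res.cost)
        theta = self._theta_of(res.x)
        return WLSResults(self, theta, fwls, df, res.status > 0)


class WLSResults:
    """Results of an :class:`OrdinalWLS` fit: estimates and fit indices."""

    def __init__(self, model: OrdinalWLS, params: ParameterVector,
                 fwls: float, df: int, converged: bool):
        self.model = model
        self.params = params
        self.fwls = max(fwls, 0.0)
        self.df = df
        self.converged = converged
        self.nobs = model.nobs
        self.chi2 = self.nobs * self.fwls
        if df > 0:
            self.p_value = float(stats.chi2.sf(self.chi2, df))
            self.rmsea, self.rmsea_ci = rmsea_from_chi2(self.chi2, df, self.nobs)
        else:
            self.p_value = np.nan
            self.rmsea, self.rmsea_ci = np.nan, (np.nan, np.nan)

    def fit_indices(self):
        return self.chi2, self.df, self.p_value, self.rmsea, self.rmsea_ci

    def summary(self) -> str:
        lines = [
            "Ordinal WLS fit",
            f"  n = {self.nobs}, moments = {self.model.summary.n_pairs}, df = {self.df}",
            f"  F_WLS = {self.fwls:.6f}, chi2 = {self.chi2:.3f}, "
            f"p = {self.p_value:.4f}",
            f"  RMSEA = {self.rmsea:.4f}  95% CI = "
            f"({self.rmsea_ci[0]:.4f}, {self.rmsea_ci[1]:.4f})",
            f"  {'parameter':<22}{'estimate':>12}",
        ]
        flat = self.params.to_flat()
        for nm, v in zip(self.model.spec.free_parameter_names(), flat):
            lines.append(f"  {nm:<22}{v:>12.4f}")
        return "\n".join(lines)


def rmsea_from_chi2(chi2: float, df: int, n: int, conf: float = 0.95):
    """RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))) with a two-sided
    noncentral-chi-square confidence interval (default 95%)."""
    if df <= 0 or n <= 1:
        return np.nan, (np.nan, np.nan)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    lo_tail = (1.0 + conf) / 2.0
    hi_tail = (1.0 - conf) / 2.0

    def _ncp(target):
        # largest lambda with P(X_{df,lambda} <= chi2) >= target
        if stats.ncx2.cdf(chi2, df, 1e-10) < target:
            return 0.0
        hi = max(chi2, df) + 10.0
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2.0
            if hi > 1e7:
                break
        return float(optimize.brentq(
            lambda lam: stats.ncx2.cdf(chi2, df, lam) - target, 1e-10, hi))

    lam_lo = _ncp(lo_tail)
    lam_hi = _ncp(hi_tail)
    ci = (
        float(np.sqrt(lam_lo / (df * (n - 1)))),
        float(np.sqrt(lam_hi / (df * (n - 1)))),
    )
    return rmsea, ci
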