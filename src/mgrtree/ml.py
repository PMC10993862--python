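"""Limited-information maximum-likelihood estimation of covariance-structure
models.

This is the tree-growing engine. The discrepancy function

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - m

is minimized over the free parameters, with the sample covariance ``S`` taken
with divisor ``n`` so that the casewise multivariate-normal log-likelihood
kernel

    lnL(y_j, theta) = -1/2 { ln|Sigma(theta)| + (y_j - pi)' Sigma^-1 (y_j - pi) }

sums to ``-n/2 (F_ML + ln|S| + m)`` exactly; the additive ``-(m/2) ln 2 pi``
constant is omitted throughout (it cancels in scores, LR statistics and all
differences). Ordinal response data are accepted and treated as numeric scores
during this stage -- the deliberate distributional compromise of the
limited-information growth step; the model actually fitted is then the numeric
twin of the ordinal spec (free intercepts and residual variances in place of
thresholds).

Scores (casewise derivatives of lnL with respect to the free parameters) are
analytic; a central-difference fallback is used in the tests as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .model_spec import MgrModelSpec, ParameterVector, implied_moments

__all__ = ["CovarianceStructureML", "MLResults", "ScoreMatrix", "lr_test"]

_BIG = 1e10


class NotConvergedError(RuntimeError):
    pass


@dataclass
class ScoreMatrix:
    """Casewise score contributions psi(y_j, theta-hat), n x k."""

    values: np.ndarray
    param_names: list
    case_index: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


class CovarianceStructureML:
    """Covariance-structure model estimated by minimizing F_ML.

    Parameters
    ----------
    endog : DataFrame or (n, m) array
        Response data, columns aligned with ``spec.item_names``. Ordinal
        responses (integer category codes) are treated as numeric scores.
    spec : MgrModelSpec
        If ordinal, its :meth:`~mgrtree.model_spec.MgrModelSpec.numeric_twin`
        is fitted.
    """

    def __init__(self, endog, spec: MgrModelSpec):
        self.orig_spec = spec
        self.spec = spec.numeric_twin()
        if hasattr(endog, "values"):
            endog = endog[self.spec.item_names].to_numpy()
        self.endog = np.asarray(endog, dtype=float)
        if np.isnan(self.endog).any():
            raise ValueError("missing values are not supported")
        n, m = self.endog.shape
        if m != self.spec.n_items:
            raise ValueError("data has wrong number of columns")
        self.nobs = n
        self.sample_mean = self.endog.mean(axis=0)
        d = self.endog - self.sample_mean
        self.sample_cov = d.T @ d / n  # divisor n: exact score identities

        sp = self.spec
        self._struct_names = [
            nm for nm in sp.free_parameter_names() if not nm.startswith("pi[")
        ]
        self._n_var = int(np.diag(sp.latent_cov_free).sum())
        self._n_cov = int(sp.latent_cov_free[np.triu_indices(sp.n_latents, 1)].sum())
        self._n_load = int(sp.loadings_free.sum())
        self._n_res = int(sp.residual_free.sum())

    # ------------------------------------------------- structural parameters
    # optimization runs on z = structural free params with variances logged
    def _z_islog(self) -> np.ndarray:
        mask = np.zeros(len(self._struct_names), dtype=bool)
        for j, nm in enumerate(self._struct_names):
            if nm.startswith("var[") or nm.startswith("theta["):
                mask[j] = True
        return mask

    def _sigma_of(self, s: np.ndarray):
        """Sigma and its gradient pieces for structural vector s (natural scale)."""
        sp = self.spec
        theta = self._theta_of(s)
        lam = theta.loadings
        sigma = lam @ theta.latent_cov @ lam.T + np.diag(theta.residual_var)
        return 0.5 * (sigma + sigma.T), theta

    def _theta_of(self, s: np.ndarray) -> ParameterVector:
        x = np.concatenate([self.sample_mean[self.spec.intercepts_free], s])
        return self.spec.unpack(x)

    def _dsigma(self, theta: ParameterVector) -> np.ndarray:
        """(k_struct, m, m) array of dSigma/dtheta_a in flat order."""
        sp = self.spec
        m, p = sp.n_items, sp.n_latents
        lam = theta.loadings
        phi = theta.latent_cov
        out = []
        lam_phi = lam @ phi
        for i, g in zip(*np.where(sp.loadings_free)):
            d = np.zeros((m, m))
            d[i, :] += lam_phi[:, g]
            d[:, i] += lam_phi[:, g]
            out.append(d)
        for g in range(p):
            if sp.latent_cov_free[g, g]:
                lg = lam[:, g]
                out.append(np.outer(lg, lg))
        for g in range(p):
            for h in range(g + 1, p):
                if sp.latent_cov_free[g, h]:
                    d = np.outer(lam[:, g], lam[:, h])
                    out.append(d + d.T)
        for i in range(m):
            if sp.residual_free[i]:
                d = np.zeros((m, m))
                d[i, i] = 1.0
                out.append(d)
        return np.array(out) if out else np.zeros((0, m, m))

    def _fml_and_grad(self, z: np.ndarray):
        islog = self._islog
        s = z.copy()
        s[islog] = np.exp(z[islog])
        sigma, theta = self._sigma_of(s)
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return _BIG, np.zeros_like(z)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        sinv = np.linalg.inv(sigma)
        f = logdet + np.sum(sinv * self.sample_cov) - self._logdet_s - self.spec.n_items
        dsig = self._dsigma(theta)
        w = sinv - sinv @ self.sample_cov @ sinv
        grad = np.einsum("mn,anm->a", w, dsig)
        grad[islog] *= s[islog]
        return f, grad

    def start_params(self) -> np.ndarray:
        """Structural starting values: identity latent covariance, loadings at
        pattern values or 1, residual variances at half the sample variances."""
        sp = self.spec
        s = []
        s.extend([1.0] * self._n_load)
        s.extend([1.0] * self._n_var)
        s.extend([0.0] * self._n_cov)
        sv = np.diag(self.sample_cov)
        s.extend(0.5 * sv[sp.residual_free])
        return np.asarray(s)

    def fit(self, start_params=None, gtol: float = 1e-7, maxiter: int = 500):
        """Minimize F_ML; returns :class:`MLResults`.

        ``start_params`` is a structural parameter vector on the natural
        scale (warm starts from a parent node's fit).
        """
        svals = np.linalg.eigvalsh(self.sample_cov)
        if svals.min() <= 1e-12:
            raise ValueError(
                "sample covariance is singular; more cases (or fewer items) "
                "are needed in this node"
            )
        self._logdet_s = float(np.linalg.slogdet(self.sample_cov)[1])
        self._islog = self._z_islog()
        s0 = self.start_params() if start_params is None else np.asarray(start_params, float)
        z0 = s0.copy()
        z0[self._islog] = np.log(np.maximum(s0[self._islog], 1e-8))
        if len(z0) == 0:
            theta = self._theta_of(np.zeros(0))
            f, _ = self._fml_and_grad(np.zeros(0))
            return MLResults(self, theta, float(f), True, 0.0)
        res = optimize.minimize(
            self._fml_and_grad,
            z0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol},
        )
        z = res.x
        f, g = self._fml_and_grad(z)
        s = z.copy()
        s[self._islog] = np.exp(z[self._islog])
        theta = self._theta_of(s)
        # total-score infinity norm per case; Eq-9 residual of the fit
        grad_norm = float(np.abs(0.5 * self.nobs * g).max() / self.nobs) if len(g) else 0.0
        converged = bool(res.success or grad_norm <= 1e-4)
        return MLResults(self, theta, float(f), converged, grad_norm)


class MLResults:
    """Results of a :class:`CovarianceStructureML` fit."""

    def __init__(self, model, params: ParameterVector, fml: float,
                 converged: bool, gradient_norm: float):
        self.model = model
        self.params = params
        self.fml = fml
        self.converged = converged
        self.gradient_norm = gradient_norm
        self.nobs = model.nobs
        self.sample_cov = model.sample_cov
        self.sample_mean = model.sample_mean
        # direct computation: a fitted latent covariance may be slightly
        # indefinite, which the implied_moments PSD gate would reject
        lam = params.loadings
        sigma = lam @ params.latent_cov @ lam.T + np.diag(params.residual_var)
        self.sigma = 0.5 * (sigma + sigma.T)
        self.mu = params.intercepts
        self.k_free = model.spec.k_free

    # ------------------------------------------------------------ likelihood
    @property
    def llf(self) -> float:
        return float(self.casewise_loglik().sum())

    def casewise_loglik(self, endog=None) -> np.ndarray:
        """lnL(y_j, theta-hat) per case (multivariate-normal kernel, no 2-pi
        constant)."""
        y = self.model.endog if endog is None else np.asarray(endog, float)
        if np.isnan(y).any():
            raise ValueError("missing values are not supported")
        sinv = np.linalg.inv(self.sigma)
        logdet = float(np.linalg.slogdet(self.sigma)[1])
        d = y - self.mu
        quad = np.einsum("jm,mn,jn->j", d, sinv, d)
        return -0.5 * (logdet + quad)

    def score_matrix(self, endog=None) -> ScoreMatrix:
        """Casewise analytic gradients of the log-likelihood kernel at
        theta-hat, n x k, in flat parameter order."""
        if not self.converged:
            raise NotConvergedError("score test undefined off the optimum")
        model = self.model
        y = model.endog if endog is None else np.asarray(endog, float)
        sp = model.spec
        sinv = np.linalg.inv(self.sigma)
        d = y - self.mu
        u = d @ sinv  # n x m
        cols = []
        # intercepts: dlnL/dpi = Sigma^-1 (y - pi)
        cols.append(u[:, sp.intercepts_free])
        dsig = model._dsigma(self.params)
        if dsig.shape[0]:
            tr = np.einsum("mn,anm->a", sinv, dsig)
            quad = np.einsum("jm,amn,jn->ja", u, dsig, u)
            cols.append(0.5 * (quad - tr[None, :]))
        values = np.hstack(cols)
        return ScoreMatrix(
            values=values,
            param_names=sp.free_parameter_names(),
            case_index=np.arange(y.shape[0]),
        )

    def fit_indices(self, ddof_mean: bool = True):
        """(chi2, df, p, rmsea) from the ML discrepancy: chi2 = n * F_ML.

        Degrees of freedom count the non-redundant covariance moments minus
        the structural free parameters (the saturated mean absorbs the free
        intercepts).
        """
        m = self.model.spec.n_items
        n_struct = len(self.model._struct_names)
        df = m * (m + 1) // 2 - n_struct
        chi2 = self.nobs * max(self.fml, 0.0)
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
        from .wls import rmsea_from_chi2

        rmsea, ci = rmsea_from_chi2(chi2, df, self.nobs)
        return chi2, df, p, rmsea, ci

    def summary(self) -> str:
        lines = [
            "Covariance-structure ML fit",
            f"  n = {self.nobs}, items = {self.model.spec.n_items}, "
            f"free parameters = {self.k_free}",
            f"  F_ML = {self.fml:.6f}   converged = {self.converged} "
            f"(score residual {self.gradient_norm:.2e})",
            "  (log-likelihood kernel omits the -(m/2) ln 2pi constant)",
            f"  {'parameter':<22}{'estimate':>12}",
        ]
        flat = self.params.to_flat()
        for nm, v in zip(self.model.spec.free_parameter_names(), flat):
            lines.append(f"  {nm:<22}{v:>12.4f}")
        return "\n".join(lines)


def lr_test(template: MLResults, left: MLResults, right: MLResults):
    """Likelihood-ratio test of an augmented (split) model against a template.

    statistic = 2 (llf_left + llf_right - llf_template), df = k free
    parameters (every parameter is allowed to differ across the two groups),
    p from the chi-square upper tail.
    """
    if template.model.spec.free_parameter_names() != \
            left.model.spec.free_parameter_names() or \
            left.model.spec.free_parameter_names() != \
            right.model.spec.free_parameter_names():
        raise ValueError("template and augmented fits use different specs")
    stat = 2.0 * (left.llf + right.llf - template.llf)
    stat = max(stat, 0.0)
    df = template.k_free
    return stat, df, float(stats.chi2.sf(stat, df))
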