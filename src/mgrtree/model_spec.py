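"""Measurement-model specifications for multidimensional graded response (MGR)
and confirmatory factor analysis (CFA) models.

An :class:`MgrModelSpec` describes the fixed/free structure of a measurement
model: which items load on which latent variables (and whether each loading is
estimated or pinned to a value), how many ordered categories each item has
(ordinal scale) or whether intercepts and residual variances are estimated
(numeric scale), and which latent variances/covariances are free.

A :class:`ParameterVector` holds one admissible point of such a model --
thresholds, intercepts, loadings, the latent covariance matrix and residual
variances -- together with an exact round-trip mapping to a flat vector of the
*free* parameters in a deterministic order (thresholds/intercepts first, then
free loadings, latent variances, latent covariances, residual variances).

Conventions
-----------
* Ordinal categories are coded ``0 .. l_i`` internally; file readers accept
  1-based category codes and shift them down.
* The ordinal latent-response scale uses a probit link with a standard-normal
  unique part, so the implied covariance of the latent responses is
  ``Lambda Phi Lambda' + I``.
* Identification: a latent variable's variance must be fixed (conventionally
  at 1) whenever its anchoring (first) loading is free; having both free is an
  identification error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "MgrModelSpec",
    "ParameterVector",
    "IdentificationError",
    "count_free_parameters",
    "build_pieg_spec",
    "implied_moments",
]

FREE = "free"


class IdentificationError(ValueError):
    """Raised for inconsistent fixed/free identification structure."""


@dataclass
class MgrModelSpec:
    """Fixed/free structure of an MGR (ordinal) or CFA (numeric) model.

    Parameters
    ----------
    item_names : list of str
        Names of the m observed response variables.
    latent_names : list of str
        Names of the p latent variables.
    loadings : (m, p) ndarray
        Pattern values: the fixed value where ``loadings_free`` is False, the
        starting value where it is True. A zero with ``loadings_free`` False
        means "no loading".
    loadings_free : (m, p) ndarray of bool
        Which loadings are estimated.
    response_scale : {"ordinal", "numeric"}
    n_categories : (m,) ndarray of int, optional
        Number of ordered categories per item (ordinal only); categories are
        coded ``0 .. n_categories[i] - 1`` and each item has
        ``n_categories[i] - 1`` free thresholds.
    latent_cov_free : (p, p) ndarray of bool
        Which latent (co)variances are estimated (symmetric).
    latent_cov_fixed : (p, p) ndarray
        Values of the fixed latent (co)variances.
    intercepts_free : (m,) ndarray of bool, optional
        Numeric scale only.
    intercepts_fixed : (m,) ndarray, optional
    residual_free : (m,) ndarray of bool, optional
        Numeric scale only; the ordinal scale has unit unique variances by
        convention.
    residual_fixed : (m,) ndarray, optional
    """

    item_names: list
    latent_names: list
    loadings: np.ndarray
    loadings_free: np.ndarray
    response_scale: str
    latent_cov_free: np.ndarray
    latent_cov_fixed: np.ndarray
    n_categories: np.ndarray | None = None
    intercepts_free: np.ndarray | None = None
    intercepts_fixed: np.ndarray | None = None
    residual_free: np.ndarray | None = None
    residual_fixed: np.ndarray | None = None

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.loadings_free = np.asarray(self.loadings_free, dtype=bool)
        self.latent_cov_free = np.asarray(self.latent_cov_free, dtype=bool)
        self.latent_cov_fixed = np.asarray(self.latent_cov_fixed, dtype=float)
        m, p = self.n_items, self.n_latents
        if self.response_scale not in ("ordinal", "numeric"):
            raise ValueError(f"unknown response_scale {self.response_scale!r}")
        if self.response_scale == "ordinal":
            self.n_categories = np.asarray(self.n_categories, dtype=int)
            if np.any(self.n_categories < 2):
                raise ValueError("every ordinal item needs >= 2 categories")
        else:
            if self.intercepts_free is None:
                self.intercepts_free = np.ones(m, dtype=bool)
            if self.intercepts_fixed is None:
                self.intercepts_fixed = np.zeros(m)
            if self.residual_free is None:
                self.residual_free = np.ones(m, dtype=bool)
            if self.residual_fixed is None:
                self.residual_fixed = np.ones(m)
            self.intercepts_free = np.asarray(self.intercepts_free, dtype=bool)
            self.intercepts_fixed = np.asarray(self.intercepts_fixed, dtype=float)
            self.residual_free = np.asarray(self.residual_free, dtype=bool)
            self.residual_fixed = np.asarray(self.residual_fixed, dtype=float)
        self.validate()

    # ------------------------------------------------------------------ shape
    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def n_latents(self) -> int:
        return len(self.latent_names)

    @property
    def is_ordinal(self) -> bool:
        return self.response_scale == "ordinal"

    def validate(self) -> None:
        m, p = self.n_items, self.n_latents
        if self.loadings.shape != (m, p) or self.loadings_free.shape != (m, p):
            raise ValueError("loading pattern shape mismatch")
        if self.latent_cov_free.shape != (p, p):
            raise ValueError("latent covariance pattern shape mismatch")
        if not np.array_equal(self.latent_cov_free, self.latent_cov_free.T):
            raise ValueError("latent_cov_free must be symmetric")
        if not np.allclose(self.latent_cov_fixed, self.latent_cov_fixed.T):
            raise ValueError("latent_cov_fixed must be symmetric")
        nonzero = self.loadings_free | (self.loadings != 0.0)
        if not nonzero.any(axis=1).all():
            bad = [self.item_names[i] for i in np.where(~nonzero.any(axis=1))[0]]
            raise ValueError(f"items without any nonzero loading: {bad}")
        # identification: anchoring loading free together with a free variance
        # on the same latent is not identified
        for g in range(p):
            on_g = np.where(nonzero[:, g])[0]
            if len(on_g) == 0:
                continue
            anchor = on_g[0]
            if self.loadings_free[anchor, g] and self.latent_cov_free[g, g]:
                raise IdentificationError(
                    f"latent {self.latent_names[g]!r}: anchoring loading and "
                    "variance cannot both be free; fix Var to 1 or the loading"
                )

    # --------------------------------------------------------- free structure
    def free_parameter_names(self) -> list:
        """Names of the free parameters in flat order."""
        names = []
        if self.is_ordinal:
            for i, item in enumerate(self.item_names):
                for k in range(1, int(self.n_categories[i])):
                    names.append(f"alpha[{item},{k}]")
        else:
            names.extend(
                f"pi[{item}]"
                for i, item in enumerate(self.item_names)
                if self.intercepts_free[i]
            )
        for i, item in enumerate(self.item_names):
            for g, lat in enumerate(self.latent_names):
                if self.loadings_free[i, g]:
                    names.append(f"beta[{item},{lat}]")
        for g, lat in enumerate(self.latent_names):
            if self.latent_cov_free[g, g]:
                names.append(f"var[{lat}]")
        for g in range(self.n_latents):
            for h in range(g + 1, self.n_latents):
                if self.latent_cov_free[g, h]:
                    names.append(
                        f"cov[{self.latent_names[g]},{self.latent_names[h]}]"
                    )
        if not self.is_ordinal:
            names.extend(
                f"theta[{item}]"
                for i, item in enumerate(self.item_names)
                if self.residual_free[i]
            )
        return names

    @property
    def k_free(self) -> int:
        return count_free_parameters(self)

    # ------------------------------------------------------------- transforms
    def numeric_twin(self) -> "MgrModelSpec":
        """The numeric CFA counterpart used during tree growth.

        Same loading pattern and latent covariance structure, but numeric
        response scale with free intercepts and free residual variances in
        place of thresholds. Ordinal responses fitted under this spec are
        treated as numeric scores -- the deliberate distributional compromise
        of the limited-information growth stage.
        """
        if not self.is_ordinal:
            return self
        return MgrModelSpec(
            item_names=list(self.item_names),
            latent_names=list(self.latent_names),
            loadings=self.loadings.copy(),
            loadings_free=self.loadings_free.copy(),
            response_scale="numeric",
            latent_cov_free=self.latent_cov_free.copy(),
            latent_cov_fixed=self.latent_cov_fixed.copy(),
        )

    # ----------------------------------------------------------- pack/unpack
    def pack(self, theta: "ParameterVector") -> np.ndarray:
        """Flatten the free entries of ``theta`` in flat order."""
        x = []
        if self.is_ordinal:
            for i in range(self.n_items):
                x.extend(theta.thresholds[i])
        else:
            x.extend(theta.intercepts[self.intercepts_free])
        x.extend(theta.loadings[self.loadings_free])
        x.extend(theta.latent_cov[np.diag_indices(self.n_latents)][
            np.diag(self.latent_cov_free)])
        iu = np.triu_indices(self.n_latents, k=1)
        x.extend(theta.latent_cov[iu][self.latent_cov_free[iu]])
        if not self.is_ordinal:
            x.extend(theta.residual_var[self.residual_free])
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray) -> "ParameterVector":
        """Rebuild a structured :class:`ParameterVector` from a flat vector."""
        x = np.asarray(x, dtype=float)
        m, p = self.n_items, self.n_latents
        pos = 0
        thresholds = None
        intercepts = np.zeros(m)
        if self.is_ordinal:
            thresholds = []
            for i in range(m):
                nth = int(self.n_categories[i]) - 1
                thresholds.append(x[pos:pos + nth].copy())
                pos += nth
        else:
            intercepts = self.intercepts_fixed.copy()
            nfree = int(self.intercepts_free.sum())
            intercepts[self.intercepts_free] = x[pos:pos + nfree]
            pos += nfree
        loadings = self.loadings.copy()
        nfree = int(self.loadings_free.sum())
        loadings[self.loadings_free] = x[pos:pos + nfree]
        pos += nfree
        diag_free = np.diag(self.latent_cov_free)
        nfree = int(diag_free.sum())
        d = np.diag(self.latent_cov_fixed).copy()
        d[diag_free] = x[pos:pos + nfree]
        pos += nfree
        latent_cov = self.latent_cov_fixed.copy()
        latent_cov[np.diag_indices(p)] = d
        iu = np.triu_indices(p, k=1)
        off_free = self.latent_cov_free[iu]
        noff = int(off_free.sum())
        off = self.latent_cov_fixed[iu].copy()
        off[off_free] = x[pos:pos + noff]
        pos += noff
        latent_cov[iu] = off
        latent_cov[(iu[1], iu[0])] = off
        residual_var = None
        if not self.is_ordinal:
            residual_var = self.residual_fixed.copy()
            nres = int(self.residual_free.sum())
            residual_var[self.residual_free] = x[pos:pos + nres]
            pos += nres
        if pos != len(x):
            raise ValueError(f"flat vector length {len(x)}, expected {pos}")
        return ParameterVector(
            spec=self,
            thresholds=thresholds,
            intercepts=intercepts,
            loadings=loadings,
            latent_cov=latent_cov,
            residual_var=residual_var,
        )

    # ------------------------------------------------------------------- io
    @classmethod
    def from_config(cls, path) -> "MgrModelSpec":
        """Read a spec from a YAML config file.

        Keys: ``items`` (list), ``latents`` (list), ``response_scale``,
        ``loadings`` (list of ``[item, latent, "free"|value]``),
        ``n_categories`` (int or per-item map, ordinal),
        ``latent_cov`` ("free" or list of ``[l1, l2, "free"|value]``).
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        items = list(cfg["items"])
        latents = list(cfg["latents"])
        m, p = len(items), len(latents)
        loadings = np.zeros((m, p))
        free = np.zeros((m, p), dtype=bool)
        for item, lat, val in cfg["loadings"]:
            i, g = items.index(item), latents.index(lat)
            if val == FREE:
                free[i, g] = True
                loadings[i, g] = 1.0
            else:
                loadings[i, g] = float(val)
        cov_free = np.zeros((p, p), dtype=bool)
        cov_fixed = np.zeros((p, p))
        if cfg.get("latent_cov", FREE) == FREE:
            cov_free[:] = True
        else:
            for l1, l2, val in cfg["latent_cov"]:
                g, h = latents.index(l1), latents.index(l2)
                if val == FREE:
                    cov_free[g, h] = cov_free[h, g] = True
                else:
                    cov_fixed[g, h] = cov_fixed[h, g] = float(val)
        # free loadings force fixed unit variances on their anchor latents
        for g in range(p):
            on_g = np.where(free[:, g] | (loadings[:, g] != 0))[0]
            if len(on_g) and free[on_g[0], g]:
                cov_free[g, g] = False
                cov_fixed[g, g] = 1.0
        scale = cfg.get("response_scale", "ordinal")
        ncat = None
        if scale == "ordinal":
            raw = cfg.get("n_categories", 5)
            if isinstance(raw, dict):
                ncat = np.array([int(raw[i]) for i in items])
            else:
                ncat = np.full(m, int(raw))
        return cls(
            item_names=items,
            latent_names=latents,
            loadings=loadings,
            loadings_free=free,
            response_scale=scale,
            n_categories=ncat,
            latent_cov_free=cov_free,
            latent_cov_fixed=cov_fixed,
        )

    def describe(self) -> str:
        """Pretty-print the free-parameter list in flat order (audit aid)."""
        lines = [
            f"MgrModelSpec: {self.n_items} items, {self.n_latents} latents, "
            f"{self.response_scale} scale, {self.k_free} free parameters",
        ]
        lines += [f"  [{j}] {nm}" for j, nm in enumerate(self.free_parameter_names())]
        return "\n".join(lines)


@dataclass
class ParameterVector:
    """One admissible parameter point of an :class:`MgrModelSpec`.

    ``thresholds`` is a list of per-item strictly increasing arrays (ordinal),
    ``latent_cov`` the full symmetric latent covariance matrix.
    """

    spec: MgrModelSpec
    loadings: np.ndarray
    latent_cov: np.ndarray
    thresholds: list | None = None
    intercepts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    residual_var: np.ndarray | None = None

    def to_flat(self) -> np.ndarray:
        return self.spec.pack(self)

    def validate(self) -> None:
        if self.spec.is_ordinal:
            for i, th in enumerate(self.thresholds):
                if len(th) > 1 and not np.all(np.diff(th) > 0):
                    raise ValueError(
                        f"thresholds of item {self.spec.item_names[i]!r} "
                        "are not strictly increasing"
                    )
        w = np.linalg.eigvalsh(self.latent_cov)
        if w.min() <= 0:
            raise ValueError("latent covariance matrix is not positive definite")
        if self.residual_var is not None and np.any(self.residual_var <= 0):
            raise ValueError("residual variances must be positive")


def count_free_parameters(spec: MgrModelSpec) -> int:
    """Number of freely estimated parameters of ``spec``.

    Thresholds (ordinal) or intercepts (numeric), free loadings, free latent
    variances and covariances, and free residual variances (numeric).
    """
    spec.validate()
    if spec.is_ordinal:
        n = int((spec.n_categories - 1).sum())
    else:
        n = int(spec.intercepts_free.sum())
    n += int(spec.loadings_free.sum())
    n += int(np.diag(spec.latent_cov_free).sum())
    n += int(spec.latent_cov_free[np.triu_indices(spec.n_latents, k=1)].sum())
    if not spec.is_ordinal:
        n += int(spec.residual_free.sum())
    return n


def build_pieg_spec(
    n_timepoints: int,
    n_items_per_timepoint: int,
    n_categories: int,
    response_scale: str = "ordinal",
) -> MgrModelSpec:
    """Multistate measurement model with latent item-effect variables.

    One reference state latent ``eta_t`` per timepoint and one item-effect
    latent ``b_i`` for every non-reference item position (shared across
    timepoints). Item (i, t) loads with fixed unit weight on ``eta_t`` and,
    for i >= 2, on ``b_i``; all thresholds and all latent (co)variances are
    free. With ``response_scale="numeric"`` the thresholds are replaced by
    free intercepts and residual variances (the CFA twin).
    """
    T, I = int(n_timepoints), int(n_items_per_timepoint)
    if T < 1 or I < 1:
        raise ValueError("counts must be >= 1")
    if n_categories < 2:
        raise ValueError("need at least 2 response categories")
    items = [f"y{i}t{t}" for t in range(1, T + 1) for i in range(1, I + 1)]
    latents = [f"eta{t}" for t in range(1, T + 1)] + [
        f"b{i}" for i in range(2, I + 1)
    ]
    m, p = len(items), len(latents)
    loadings = np.zeros((m, p))
    for t in range(T):
        for i in range(I):
            row = t * I + i
            loadings[row, t] = 1.0
            if i >= 1:
                loadings[row, T + i - 1] = 1.0
    free = np.zeros((m, p), dtype=bool)  # all discriminations fixed at 1
    cov_free = np.ones((p, p), dtype=bool)
    cov_fixed = np.zeros((p, p))
    kwargs = {}
    if response_scale == "ordinal":
        kwargs["n_categories"] = np.full(m, int(n_categories))
    return MgrModelSpec(
        item_names=items,
        latent_names=latents,
        loadings=loadings,
        loadings_free=free,
        response_scale=response_scale,
        latent_cov_free=cov_free,
        latent_cov_fixed=cov_fixed,
        **kwargs,
    )


def implied_moments(spec: MgrModelSpec, theta: ParameterVector):
    """Model-implied mean vector and covariance matrix.

    Numeric scale: ``mu = pi``, ``Sigma = Lambda Phi Lambda' + diag(theta_eps)``.
    Ordinal scale: moments of the latent responses ``Y*`` under the probit
    convention -- ``mu = 0``, ``Sigma = Lambda Phi Lambda' + I``.
    """
    w = np.linalg.eigvalsh(theta.latent_cov)
    if w.min() < -1e-10:
        raise ValueError("latent covariance matrix is not positive semidefinite")
    lam = theta.loadings
    sigma = lam @ theta.latent_cov @ lam.T
    if spec.is_ordinal:
        sigma = sigma + np.eye(spec.n_items)
        mean = np.zeros(spec.n_items)
    else:
        sigma = sigma + np.diag(theta.residual_var)
        mean = theta.intercepts.copy()
    return mean, 0.5 * (sigma + sigma.T)
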