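import numpy as np
import pandas as pd
import pytest

from mgrtree.model_spec import (
    MgrModelSpec,
    ParameterVector,
    build_pieg_spec,
    implied_moments,
)


@pytest.fixture(scope="session")
def pieg_spec():
    return build_pieg_spec(3, 3, 5)


@pytest.fixture(scope="session")
def cfa_spec():
    return build_pieg_spec(3, 3, 5, response_scale="numeric")


@pytest.fixture(scope="session")
def cfa_theta(cfa_spec):
    """A fixed admissible parameter point of the CFA twin."""
    rng = np.random.default_rng(42)
    q = cfa_spec.n_latents
    a = rng.normal(size=(q, q))
    phi = a @ a.T / q + 0.3 * np.eye(q)
    return ParameterVector(
        spec=cfa_spec,
        loadings=cfa_spec.loadings.copy(),
        latent_cov=phi,
        intercepts=rng.normal(size=cfa_spec.n_items),
        residual_var=rng.uniform(0.5, 1.5, cfa_spec.n_items),
    )


@pytest.fixture(scope="session")
def cfa_sample(cfa_spec, cfa_theta):
    """n = 2000 numeric responses drawn from the CFA twin."""
    rng = np.random.default_rng(7)
    mean, sigma = implied_moments(cfa_spec, cfa_theta)
    y = rng.multivariate_normal(mean, sigma, size=2000)
    return pd.DataFrame(y, columns=cfa_spec.item_names)


@pytest.fixture(scope="session")
def cfa_fit(cfa_spec, cfa_sample):
    from mgrtree.ml import CovarianceStructureML

    res = CovarianceStructureML(cfa_sample, cfa_spec).fit()
    assert res.converged
    return res


@pytest.fixture(scope="session")
def scenario1_ordinal():
    from mgrtree.simulate import make_scenario1

    return make_scenario1("ordinal", seed=3)


@pytest.fixture(scope="session")
def one_item_fixed_spec():
    """1-item model with the implied variance entirely fixed at 1."""
    return MgrModelSpec(
        item_names=["y"], latent_names=["xi"], loadings=[[1.0]],
        loadings_free=[[False]], response_scale="numeric",
        latent_cov_free=[[False]], latent_cov_fixed=[[0.5]],
        residual_free=[False], residual_fixed=[0.5])
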