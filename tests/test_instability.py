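"""M-fluctuation machinery: exhaustive-oracle equivalence of the max-type
statistics, chi-square calibration of LMuo, Brownian-bridge properties and
covariate selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgrtree.instability import (
    _maxlm_closed_form,
    lm_uo_categorical,
    max_lm_numeric,
    max_lm_ordinal,
    p_value,
    score_process,
)
from mgrtree.instability import test_all_covariates as run_covariate_tests
from mgrtree.ml import ScoreMatrix


def _scores(values):
    values = np.asarray(values, dtype=float)
    return ScoreMatrix(values, [f"p{j}" for j in range(values.shape[1])],
                       np.arange(values.shape[0]))


def _null_scores(rng, n, k):
    psi = rng.standard_normal((n, k))
    return _scores(psi - psi.mean(axis=0))  # estimating equation holds


# ------------------------------------------------------------------ process
def test_zero_scores_zero_process():
    sm = _scores(np.zeros((50, 3)))
    z = np.arange(50)
    proc = score_process(sm, z)
    assert np.allclose(proc.process, 0.0)
    assert proc.k_effective == 0


def test_process_starts_and_ends_at_zero():
    rng = np.random.default_rng(0)
    sm = _null_scores(rng, 400, 4)
    proc = score_process(sm, rng.normal(size=400))
    assert np.allclose(proc.process[0], 0.0)
    assert np.abs(proc.process[-1]).max() < 1e-10


def test_bridge_variance_at_midpoint():
    """Var of each component of B(1/2) is ~ 1/4 under i.i.d. null scores."""
    rng = np.random.default_rng(1)
    n, k, reps = 200, 2, 1000
    mids = np.empty((reps, k))
    for r in range(reps):
        sm = _null_scores(rng, n, k)
        proc = score_process(sm, np.arange(n), rng=rng)
        mids[r] = proc.process[n // 2]
    var = mids.var(axis=0)
    assert np.all(np.abs(var - 0.25) < 0.035)


# ------------------------------------------------------- maxLM (numeric)
def _brute_force_maxlm(psi, z, trim, min_size=0):
    """Explicit loop over admissible cut indices evaluating the LM form."""
    n, k = psi.shape
    order = np.argsort(z, kind="stable")
    psi = psi[order]
    zs = np.asarray(z)[order]
    info = psi.T @ psi / n
    w, v = np.linalg.eigh(info)
    droot = (v * (1 / np.sqrt(np.clip(w, 1e-300, None)))) @ v.T
    best, arg = -np.inf, None
    lo = max(int(np.ceil(trim * n)), min_size, 1)
    hi = min(int(np.floor((1 - trim) * n)), n - min_size, n - 1)
    for j in range(lo, hi + 1):
        if zs[j] == zs[j - 1]:
            continue
        b = droot @ psi[:j].sum(axis=0) / np.sqrt(n)
        t = j / n
        lm = (b @ b) / (t * (1 - t))
        if lm > best:
            best, arg = lm, j
    return best, arg


def test_maxlm_matches_exhaustive_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(30, 120))
        k = int(rng.integers(1, 5))
        psi = rng.standard_normal((n, k))
        psi -= psi.mean(axis=0)
        z = rng.integers(0, n // 2, size=n).astype(float)
        sm = _scores(psi)
        proc = score_process(sm, z, rng=rng)
        stat, cut = max_lm_numeric(proc, trim=0.1)
        ref, ref_cut = _brute_force_maxlm(psi, z, 0.1)
        if stat is None:
            assert ref == -np.inf or ref is None
            continue
        assert stat == pytest.approx(ref, abs=1e-10)


def test_maxlm_zero_process_zero_statistic():
    sm = _scores(np.zeros((100, 2)))
    proc = score_process(sm, np.arange(100.0))
    stat, cut = max_lm_numeric(proc, trim=0.1)
    assert stat == 0.0


def test_maxlm_localizes_planted_break():
    """Mean shift in one score column at the midpoint: the argmax falls
    within +-5% of n of the planted index in >= 90% of simulations."""
    rng = np.random.default_rng(3)
    n, hits, reps = 500, 0, 60
    for _ in range(reps):
        psi = rng.standard_normal((n, 3))
        z = np.arange(n, dtype=float)
        psi[n // 2:, 0] += 0.8
        psi -= psi.mean(axis=0)
        proc = score_process(_scores(psi), z, rng=rng)
        stat, cut = max_lm_numeric(proc, trim=0.1)
        hits += abs(cut - n // 2) <= 0.05 * n
    assert hits >= 0.9 * reps


# --------------------------------------------------------- LMuo (categorical)
def test_lmuo_mirrored_categories_equal_terms():
    psi = np.vstack([np.full((20, 2), 0.5), np.full((20, 2), -0.5)])
    psi += np.random.default_rng(4).normal(scale=1e-3, size=psi.shape)
    psi -= psi.mean(axis=0)
    z = np.repeat([0, 1], 20)
    stat = lm_uo_categorical(_scores(psi), z)
    # mirrored sums: each category contributes half the statistic
    info = psi.T @ psi / 40
    w, v = np.linalg.eigh(info)
    droot = (v * (1 / np.sqrt(w))) @ v.T
    s0 = droot @ psi[:20].sum(axis=0)
    assert stat == pytest.approx(2 * (s0 @ s0) / (40 * 0.5), rel=1e-6)


def test_lmuo_invariant_under_relabeling():
    rng = np.random.default_rng(5)
    psi = rng.standard_normal((90, 3))
    psi -= psi.mean(axis=0)
    z = rng.integers(0, 3, 90)
    sm = _scores(psi)
    assert lm_uo_categorical(sm, z) == pytest.approx(
        lm_uo_categorical(sm, (z + 7) * 13 % 31), rel=1e-10)


def test_lmuo_null_distribution_quantile():
    """Empirical 95th percentile over null simulations within 5% of the
    chi-square quantile with k (C-1) df (n = 800, k = 3, C = 3)."""
    rng = np.random.default_rng(6)
    n, k, c, reps = 800, 3, 3, 2000
    vals = np.empty(reps)
    z = np.resize(np.repeat(np.arange(c), n // c + 1), n)
    for r in range(reps):
        sm = _null_scores(rng, n, k)
        vals[r] = lm_uo_categorical(sm, z)
    q = np.quantile(vals, 0.95)
    ref = stats.chi2.ppf(0.95, k * (c - 1))
    assert abs(q - ref) / ref < 0.05


# ----------------------------------------------------------- maxLMo (ordinal)
def test_maxlmo_two_levels_single_cut():
    rng = np.random.default_rng(7)
    psi = rng.standard_normal((60, 2))
    psi -= psi.mean(axis=0)
    z = np.repeat([1, 2], 30)
    stat, level, t, keff = max_lm_ordinal(_scores(psi), z, rng=rng)
    assert level == 1
    ref, _ = _brute_force_maxlm(psi, z.astype(float), trim=0.0)
    assert stat == pytest.approx(ref, abs=1e-10)


def test_maxlmo_matches_exhaustive_oracle_and_relabeling():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(40, 150))
        k = int(rng.integers(1, 4))
        psi = rng.standard_normal((n, k))
        psi -= psi.mean(axis=0)
        z = rng.integers(0, 5, n)
        if len(np.unique(z)) < 2:
            continue
        sm = _scores(psi)
        stat, level, t, keff = max_lm_ordinal(sm, z, rng=rng)
        # oracle: evaluate the LM form at every level cut by explicit loop
        order = np.argsort(z, kind="stable")
        psis, zs = psi[order], z[order]
        info = psi.T @ psi / n
        w, v = np.linalg.eigh(info)
        droot = (v * (1 / np.sqrt(w))) @ v.T
        best = -np.inf
        for lev in np.unique(zs)[:-1]:
            j = int((zs <= lev).sum())
            b = droot @ psis[:j].sum(axis=0) / np.sqrt(n)
            tt = j / n
            best = max(best, (b @ b) / (tt * (1 - tt)))
        assert stat == pytest.approx(best, abs=1e-10)
        # monotone relabeling leaves the statistic unchanged
        stat2, _, _, _ = max_lm_ordinal(sm, z * 10 + 3, rng=rng)
        assert stat2 == pytest.approx(stat, abs=1e-10)


# ----------------------------------------------------------------- p-values
def test_zero_statistic_p_near_one():
    assert p_value(0.0, "LMuo", 3, extra=2) == pytest.approx(1.0)
    assert p_value(0.0, "maxLM", 2, extra=0.1, n_sim=2000) > 0.99
    assert p_value(0.0, "maxLMo", 2, extra=np.array([0.3, 0.6]),
                   n_sim=2000) > 0.99


def test_lmuo_chi2_closed_form():
    assert p_value(5.991, "LMuo", 2, extra=2) == pytest.approx(0.05, abs=1e-3)


def test_maxlm_closed_form_vs_simulation_in_tail():
    """The boundary-crossing approximation (k = 1) agrees with simulation
    within 0.01 in the tail where decisions are made."""
    for stat in np.linspace(12.0, 40.0, 10):
        pc = _maxlm_closed_form(stat, 1, 0.1)
        ps = p_value(stat, "maxLM", 1, extra=0.1, method="simulate",
                     n_sim=50_000)
        assert abs(pc - ps) < 0.01


def test_maxlm_closed_form_requires_single_parameter():
    with pytest.raises(NotImplementedError):
        p_value(10.0, "maxLM", 3, extra=0.1, method="closed_form")


def test_unknown_statistic_kind_rejected():
    with pytest.raises(ValueError):
        p_value(1.0, "supW", 2, extra=None)


# ------------------------------------------------------- covariate selection
def test_single_covariate_adjustment_is_identity():
    rng = np.random.default_rng(9)
    sm = _null_scores(rng, 300, 2)
    Z = pd.DataFrame({"z": rng.normal(size=300)})
    results, _ = run_covariate_tests(sm, Z, {"z": "numeric"}, rng=rng,
                                     n_sim=2000)
    assert results[0].p_adjusted == results[0].p_value


def test_constant_covariate_skipped():
    rng = np.random.default_rng(10)
    sm = _null_scores(rng, 200, 2)
    Z = pd.DataFrame({"c": np.ones(200), "z": rng.normal(size=200)})
    results, _ = run_covariate_tests(sm, Z, {"c": "numeric", "z": "numeric"},
                                     rng=rng, n_sim=2000)
    assert not results[0].testable
    assert results[1].testable
    # Bonferroni factor counts only the tested covariates
    assert results[1].p_adjusted == results[1].p_value


def test_planted_dif_covariate_selected():
    """The covariate carrying a score shift is selected over random ones."""
    rng = np.random.default_rng(11)
    n = 600
    wins = 0
    for _ in range(20):
        psi = rng.standard_normal((n, 3))
        zdif = rng.normal(size=n)
        psi[zdif > 0, 0] += 0.6
        psi -= psi.mean(axis=0)
        Z = pd.DataFrame({
            "dif": zdif,
            "r1": rng.normal(size=n),
            "r2": rng.integers(0, 5, n),
            "r3": rng.integers(0, 3, n),
        })
        kinds = {"dif": "numeric", "r1": "numeric", "r2": "ordinal",
                 "r3": "categorical"}
        _, selected = run_covariate_tests(_scores(psi), Z, kinds, rng=rng,
                                          n_sim=2000)
        wins += selected == "dif"
    assert wins >= 19


def test_null_selection_rate_controlled():
    """Family-wise selection rate under the null stays near alpha."""
    rng = np.random.default_rng(12)
    n, reps = 300, 120
    sel = 0
    for _ in range(reps):
        sm = _null_scores(rng, n, 3)
        Z = pd.DataFrame({
            "z1": rng.normal(size=n), "z2": rng.integers(0, 5, n),
            "z3": rng.integers(0, 3, n), "z4": rng.normal(size=n),
        })
        kinds = {"z1": "numeric", "z2": "ordinal", "z3": "categorical",
                 "z4": "numeric"}
        _, selected = run_covariate_tests(sm, Z, kinds, alpha=0.05, rng=rng,
                                          n_sim=2000)
        sel += selected is not None
    assert sel / reps < 0.12


def test_item_parameter_view_drops_residual_columns():
    """The item-parameter option excludes residual-variance scores from the
    tests (the full model-parameter view is the default)."""
    rng = np.random.default_rng(13)
    psi = rng.standard_normal((200, 4))
    psi -= psi.mean(axis=0)
    sm = ScoreMatrix(psi, ["pi[y1]", "var[f]", "theta[y1]", "theta[y2]"],
                     np.arange(200))
    Z = pd.DataFrame({"z": rng.integers(0, 2, 200)})
    res_full, _ = run_covariate_tests(sm, Z, {"z": "categorical"}, rng=rng)
    res_item, _ = run_covariate_tests(sm, Z, {"z": "categorical"}, rng=rng,
                                      exclude_residual_scores=True)
    # chi-square df differ: 4 vs 2 score columns feed the LMuo statistic
    assert res_full[0].statistic != pytest.approx(res_item[0].statistic)
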