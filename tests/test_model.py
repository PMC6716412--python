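"""Gibbs kernel unit tests and sampler-level properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import countysae as cs
from countysae.model import (DualSurveySAE, Priors, update_beta,
                             update_beta_collapsed, update_lambda,
                             update_sigma, update_theta)
from countysae.transform import Level1Data


def _level1(y, v, mask, ids=None):
    y = np.atleast_2d(np.asarray(y, float))
    v = np.atleast_2d(np.asarray(v, float))
    mask = np.atleast_2d(np.asarray(mask, bool))
    m = y.shape[0]
    ids = np.array(ids if ids is not None else [f"c{i}" for i in range(m)])
    return Level1Data(ids, y, v, mask, [])


def test_priors_must_be_proper():
    with pytest.raises(ValueError, match="proper"):
        Priors(beta_var=np.inf)
    with pytest.raises(ValueError, match="sigma_df"):
        Priors(sigma_df=3)
    with pytest.raises(ValueError, match="SPD"):
        Priors(sigma_scale=np.zeros((3, 3)))


def test_burnin_must_be_smaller_than_iterations():
    l1 = _level1([0.5, 0, 0, 0], [0.01, 1, 1, 1], [True, False, False, False])
    model = DualSurveySAE(l1, np.ones((1, 1)))
    with pytest.raises(ValueError, match="n_burnin"):
        model.fit(n_iter=100, n_burnin=100)


def test_county_without_any_component_rejected():
    l1 = _level1([[0.5, 0, 0, 0], [0, 0, 0, 0]],
                 [[0.01, 1, 1, 1], [1, 1, 1, 1]],
                 [[True, False, False, False], [False] * 4])
    with pytest.raises(ValueError, match="no observed component"):
        DualSurveySAE(l1, np.ones((2, 1)))


def test_update_sigma_prior_only():
    """With no residual information the Sigma draws average to the
    inverse-Wishart prior mean scale/(df - 3 - 1)."""
    rng = np.random.default_rng(0)
    scale = 0.5 * np.eye(3)
    df = 9
    draws = np.array([update_sigma(np.zeros((0, 3)), df, scale, rng)
                      for _ in range(4000)])
    prior_mean = scale / (df - 3 - 1)
    assert np.allclose(draws.mean(axis=0), prior_mean, atol=0.012)


def test_update_lambda_concentrates_at_identity():
    """BRFSS-style data generated with lambda = 1 and very large effective n
    pin the factor at 1.0 +- 0.01."""
    rng = np.random.default_rng(1)
    m = 400
    theta_L = rng.uniform(0.3, 0.7, m)
    w = np.full(m, 1e-6)
    z = theta_L + rng.normal(0, np.sqrt(w))
    draws = [update_lambda(z, w, theta_L, np.ones(m, bool), 1.0, 1.0, rng)
             for _ in range(200)]
    assert abs(np.mean(draws) - 1.0) < 0.01


def test_update_beta_matches_conjugate_regression():
    """With orthonormal covariates, known theta and a flat-ish prior the
    draw distribution matches the OLS-based conjugate posterior."""
    rng = np.random.default_rng(2)
    m, p = 64, 2
    # orthonormal columns scaled so X'X = I
    Xr = np.linalg.qr(rng.standard_normal((m, p)))[0]
    Sigma = np.diag([0.04, 0.09, 0.01])
    B_true = rng.normal(0, 1, (3, p))
    theta = Xr @ B_true.T + rng.multivariate_normal(np.zeros(3), Sigma, m)
    beta_var = 1e6
    draws = np.array([
        update_beta(theta, Xr, np.linalg.inv(Sigma), beta_var, rng)
        for _ in range(4000)
    ])
    ols = (theta.T @ Xr)           # since X'X = I, OLS coefficients directly
    assert np.allclose(draws.mean(axis=0), ols, atol=0.03)
    # posterior variance of each entry is Sigma_ss (X'X = I), prior negligible
    emp_var = draws.var(axis=0)
    expect = np.repeat(np.diag(Sigma), p).reshape(3, p)
    assert np.allclose(emp_var, expect, rtol=0.2)


def test_update_beta_collapsed_agrees_with_conditional_in_data_rich_limit():
    """When every component is observed with tiny variance the collapsed and
    plain conditional B updates target the same tight posterior."""
    rng = np.random.default_rng(3)
    m, p = 80, 2
    X = np.column_stack([np.ones(m), rng.standard_normal(m)])
    B_true = np.array([[0.5, 0.04], [0.55, 0.02], [0.6, -0.03]])
    Sigma = 0.001 * np.eye(3)
    theta = X @ B_true.T + rng.multivariate_normal(np.zeros(3), Sigma, m)
    y = np.column_stack([theta, theta[:, 0]])
    v = np.full((m, 4), 1e-8)
    mask = np.ones((m, 4), bool)
    d1 = np.array([update_beta_collapsed(y, v, mask, X, 1.0, Sigma, 100.0, rng)
                   for _ in range(300)])
    d2 = np.array([update_beta(theta, X, np.linalg.inv(Sigma), 100.0, rng)
                   for _ in range(300)])
    assert np.allclose(d1.mean(axis=0), d2.mean(axis=0), atol=0.01)


def test_update_theta_data_dominant_limit():
    """With level-1 variance ~1e-8 the posterior mean of theta equals the
    observation to 3 decimals."""
    y = np.array([[0.55, 0.62, 0.70, 0.0]])
    v = np.array([[1e-8, 1e-8, 1e-8, 1.0]])
    mask = np.array([[True, True, True, False]])
    X = np.ones((1, 1))
    beta = np.array([[0.3], [0.3], [0.3]])
    Sigma_inv = np.linalg.inv(0.01 * np.eye(3))
    rng = np.random.default_rng(4)
    draws = np.array([
        update_theta(y, v, mask, X, beta, 1.0, Sigma_inv, rng)[0]
        for _ in range(500)
    ])
    assert np.allclose(draws.mean(axis=0), [0.55, 0.62, 0.70], atol=1e-3)


def test_update_theta_respects_truncation():
    y = np.array([[1.6, 0.0, 0.0, 0.0]])     # beyond pi/2
    v = np.array([[1e-4, 1, 1, 1]])
    mask = np.array([[True, False, False, False]])
    X = np.ones((1, 1))
    beta = np.array([[1.5], [0.5], [0.5]])
    rng = np.random.default_rng(5)
    draws = np.array([
        update_theta(y, v, mask, X, beta, 1.0, np.eye(3) * 100, rng)[0]
        for _ in range(200)
    ])
    assert draws.max() <= np.pi / 2 + 1e-12
    assert draws.min() >= 0


def test_singular_precision_names_county():
    y = np.array([[0.5, 0, 0, 0]])
    v = np.array([[0.01, 1, 1, 1]])
    mask = np.array([[True, False, False, False]])
    X = np.ones((1, 1))
    beta = np.array([[0.5], [0.5], [0.5]])
    bad_prec = np.diag([1.0, 1.0, -1.0])     # not a valid precision
    with pytest.raises(np.linalg.LinAlgError, match="county index"):
        update_theta(y, v, mask, X, beta, 1.0, bad_prec,
                     np.random.default_rng(0))


def test_telephone_only_county_gets_proper_posteriors():
    """A county observed only through the telephone survey still receives
    finite, positive-variance posteriors for all three strata."""
    rng = np.random.default_rng(6)
    m = 30
    X = np.column_stack([np.ones(m), rng.standard_normal(m)])
    y = np.zeros((m, 4))
    v = np.ones((m, 4))
    mask = np.zeros((m, 4), bool)
    y[:, 3] = 0.5 + 0.05 * rng.standard_normal(m)
    v[:, 3] = 1.0 / (4 * 80)
    mask[:, 3] = True
    # a few counties also carry stratum data
    y[:5, :3] = 0.5
    v[:5, :3] = 1.0 / (4 * 10)
    mask[:5, :3] = True
    l1 = _level1(y, v, mask)
    res = DualSurveySAE(l1, X).fit(n_iter=1500, n_burnin=500, n_chains=2,
                                   seed=0)
    th = res.theta_for("c20")                  # telephone-only county
    assert th.shape[1] == 3
    assert np.all(np.isfinite(th))
    assert np.all(th.std(axis=0) > 0)


def test_exchangeability_under_county_permutation(small_world):
    """Relabeling counties leaves per-county posterior means unchanged up to
    Monte Carlo error and does not move the hyperparameter posteriors."""
    _, counties, nhis, brfss = small_world
    nd, bd = cs.direct_estimates(nhis), cs.direct_estimates(brfss)
    l1 = assemble = cs.assemble_level1(nd, bd)
    truth = cs.synthetic.counties_to_frame(counties).set_index("county_id")
    X = truth.loc[l1.county_ids, ["x0", "x1", "x2"]].to_numpy()

    rng = np.random.default_rng(9)
    perm = rng.permutation(len(l1))
    l1p = Level1Data(l1.county_ids[perm], l1.y[perm], l1.v[perm],
                     l1.mask[perm], [])
    res1 = DualSurveySAE(l1, X).fit(n_iter=4000, n_burnin=1000, seed=1)
    res2 = DualSurveySAE(l1p, X[perm]).fit(n_iter=4000, n_burnin=1000, seed=1)

    t1 = {cid: res1.theta_for(cid).mean(axis=0) for cid in l1.county_ids}
    t2 = {cid: res2.theta_for(cid).mean(axis=0) for cid in l1.county_ids}
    diffs = np.array([t1[c] - t2[c] for c in l1.county_ids])
    assert np.max(np.abs(diffs)) < 0.05
    assert res1.lambda_draws.mean() == pytest.approx(
        res2.lambda_draws.mean(), abs=0.02)


def test_fixed_blocks_are_held():
    l1 = _level1([0.5, 0, 0, 0], [1e-4, 1, 1, 1], [True, False, False, False])
    fixed = {"beta": np.full((3, 1), 0.5), "lambda": 1.0,
             "Sigma": 0.01 * np.eye(3)}
    res = DualSurveySAE(l1, np.ones((1, 1)), fixed=fixed).fit(
        n_iter=200, n_burnin=50, n_chains=1, seed=0)
    assert np.all(res.lambda_draws == 1.0)
    assert np.all(res.beta_draws == 0.5)


def test_summary_table_shape(small_world):
    _, counties, nhis, brfss = small_world
    l1 = cs.assemble_level1(cs.direct_estimates(nhis),
                            cs.direct_estimates(brfss))
    truth = cs.synthetic.counties_to_frame(counties).set_index("county_id")
    X = truth.loc[l1.county_ids, ["x0", "x1", "x2"]].to_numpy()
    res = DualSurveySAE(l1, X).fit(n_iter=600, n_burnin=200, seed=2)
    tab = res.summary()
    assert {"parameter", "mean", "sd", "q2.5", "q97.5"} <= set(tab.columns)
    assert (tab["q2.5"] <= tab["q97.5"]).all()
    assert len(tab) == 9 + 1 + 6              # beta entries + lambda + Sigma
    # every Sigma draw SPD, lambda positive, theta within range
    assert np.all(res.lambda_draws > 0)
    assert np.all(np.linalg.eigvalsh(res.sigma_draws) > 0)
    assert res.theta_draws.min() >= 0
    assert res.theta_draws.max() <= np.pi / 2
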