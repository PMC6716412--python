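"""Hierarchical Bayes area-level model for two coupled surveys, fit by Gibbs.

Model.  For county i with transformed stratum means
theta_i = (theta_iL, theta_iC, theta_iN):

* level 1 (sampling model, arcsine-root scale, variances known):
  - in-person survey stratum estimates:  y_is ~ N(theta_is, v_is)
  - telephone survey (landline frame):   z_i  ~ N(lambda * theta_iL, w_i)
  where lambda is a single unknown factor absorbing the telephone survey's
  proportionate noncoverage/nonresponse bias relative to the in-person one;
* level 2 (linking model):
  theta_i = B x_i + u_i,   u_i ~ MVN(0, Sigma)
  with covariate vector x_i (intercept included) and a full 3x3 random-effect
  covariance so information is shared across phone strata within county.

Priors (diffuse but proper): vec(B) ~ N(0, beta_var * I);
lambda ~ N(lambda_mean, lambda_var) truncated to (0, inf);
Sigma ~ Inverse-Wishart(sigma_df, sigma_scale).

All full conditionals are conjugate (normal / truncated normal /
inverse-Wishart), so the posterior is sampled by plain Gibbs.  Missing
level-1 components are handled by likelihood masking, never imputation, so a
county with only the telephone component still receives a proper posterior
for all three strata through the covariates, Sigma and lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transform import COMPONENTS, Level1Data

__all__ = [
    "Priors",
    "SAEResults",
    "DualSurveySAE",
    "update_theta",
    "update_beta",
    "update_lambda",
    "update_sigma",
]

_HALF_PI = np.pi / 2


@dataclass
class Priors:
    """Diffuse-but-proper prior hyperparameters.

    beta_var: prior variance of each regression coefficient (flat-ish).
    lambda_mean/lambda_var: normal prior on the bias factor, truncated to
    (0, inf); the default centers at 1 ("no bias").
    sigma_df/sigma_scale: inverse-Wishart on the 3x3 random-effect covariance.
    """

    beta_var: float = 100.0
    lambda_mean: float = 1.0
    lambda_var: float = 1.0
    sigma_df: int = 5
    sigma_scale: np.ndarray = field(default_factory=lambda: 0.01 * np.eye(3))

    def __post_init__(self) -> None:
        self.sigma_scale = np.asarray(self.sigma_scale, dtype=float)
        if not (np.isfinite(self.beta_var) and self.beta_var > 0):
            raise ValueError("beta_var must be finite and positive (proper prior)")
        if not (np.isfinite(self.lambda_var) and self.lambda_var > 0):
            raise ValueError("lambda_var must be finite and positive")
        if self.sigma_df < 4:
            raise ValueError("sigma_df must be >= 4 (proper inverse-Wishart)")
        if self.sigma_scale.shape != (3, 3) or \
                np.any(np.linalg.eigvalsh(self.sigma_scale) <= 0):
            raise ValueError("sigma_scale must be 3x3 SPD")


# ---------------------------------------------------------------------------
# Gibbs kernels (exposed individually for unit testing)
# ---------------------------------------------------------------------------

def update_theta(y, v, mask, X, beta, lam, Sigma_inv, rng,
                 truncate=True, max_tries=100):
    """Draw all county mean vectors theta_i from their full conditionals.

    Each conditional is MVN with precision Sigma_inv + D_i, where D_i is the
    diagonal data precision: the landline entry collects both the in-person
    landline component (1/v_iL) and the telephone component (lambda^2/w_i).
    With ``truncate``, draws are restricted to [0, pi/2]^3 by rejection
    (clipped after ``max_tries``).
    """
    m = y.shape[0]
    d = np.zeros((m, 3))
    b = np.zeros((m, 3))
    mk = mask.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_v = np.where(mask, 1.0 / v, 0.0)
    # in-person components map 1:1 onto strata
    d[:, :3] += mk[:, :3] * inv_v[:, :3]
    b[:, :3] += mk[:, :3] * inv_v[:, :3] * y[:, :3]
    # telephone component observes lambda * theta_L
    d[:, 0] += mk[:, 3] * lam**2 * inv_v[:, 3]
    b[:, 0] += mk[:, 3] * lam * inv_v[:, 3] * y[:, 3]

    prior_mean = X @ beta.T                           # (m, 3)
    prec = Sigma_inv[None, :, :] + np.einsum("ij,jk->ijk", d, np.eye(3))
    rhs = (Sigma_inv @ prior_mean.T).T + b            # (m, 3)

    try:
        chol = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        ok = np.array([np.all(np.linalg.eigvalsh(prec[i]) > 0)
                       for i in range(m)])
        bad = int(np.argmin(ok))
        raise np.linalg.LinAlgError(
            f"singular precision matrix in theta update at county index {bad}")
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]

    def draw(idx):
        z = rng.standard_normal((len(idx), 3, 1))
        step = np.linalg.solve(np.transpose(chol[idx], (0, 2, 1)), z)[..., 0]
        return mean[idx] + step

    theta = draw(np.arange(m))
    if truncate:
        for _ in range(max_tries):
            bad = np.where(np.any((theta < 0) | (theta > _HALF_PI), axis=1))[0]
            if bad.size == 0:
                break
            theta[bad] = draw(bad)
        theta = np.clip(theta, 0.0, _HALF_PI)
    return theta


def update_beta(theta, X, Sigma_inv, beta_var, rng):
    """Draw the 3 x p coefficient matrix B from its full conditional.

    theta_i ~ MVN(B x_i, Sigma) with known Sigma and N(0, beta_var I) prior
    on vec(B) gives a conjugate multivariate-regression normal:
    precision (X'X) kron Sigma_inv + I/beta_var.
    """
    p = X.shape[1]
    XtX = X.T @ X
    prec = np.kron(XtX, Sigma_inv) + np.eye(3 * p) / beta_var
    rhs = (Sigma_inv @ theta.T @ X).flatten(order="F")
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(3 * p)
    bvec = mean + np.linalg.solve(chol.T, z)
    return bvec.reshape((3, p), order="F")


def update_beta_collapsed(y, v, mask, X, lam, Sigma, beta_var, rng,
                          big_var=1e10):
    """Draw B from its conditional given (Sigma, lambda) with theta integrated out.

    Marginally y_i ~ N(A B x_i, A Sigma A' + V_i) with the fixed 4x3 loading
    A = [I_3; lam e_L'], so vec(B) remains conjugate normal.  Collapsing theta
    removes the B<->theta random walk that makes the plain conditional update
    mix slowly when most counties carry little stratum-level data.  Missing
    components enter with a huge variance (zero information).
    """
    m, p = X.shape
    A = np.vstack([np.eye(3), lam * np.eye(3)[0]])          # (4, 3)
    V = np.where(mask, v, big_var)                           # (m, 4)
    C = (A @ Sigma @ A.T)[None, :, :] + np.einsum(
        "ij,jk->ijk", V, np.eye(4))
    Cinv = np.linalg.inv(C)
    G = np.einsum("kj,ikl,lm->ijm", A, Cinv, A)              # (m, 3, 3)
    yy = np.where(mask, y, 0.0)
    H = np.einsum("kj,ikl,il->ij", A, Cinv, yy)              # (m, 3)
    P4 = np.einsum("ij,ik,ist->jskt", X, X, G)               # (p,3,p,3)
    prec = P4.reshape(3 * p, 3 * p) + np.eye(3 * p) / beta_var
    rhs = np.einsum("ij,is->js", X, H).reshape(-1)
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    bvec = mean + np.linalg.solve(chol.T, rng.standard_normal(3 * p))
    return bvec.reshape((3, p), order="F")


def update_lambda(z, w, theta_L, mask, lambda_mean, lambda_var, rng):
    """Draw the telephone-survey bias factor from its truncated-normal conditional.

    z_i ~ N(lambda theta_iL, w_i) over counties with a telephone component,
    prior N(lambda_mean, lambda_var) restricted to lambda > 0.
    """
    if mask.any():
        t = theta_L[mask]
        zz = z[mask]
        ww = w[mask]
        prec = 1.0 / lambda_var + np.sum(t**2 / ww)
        mu = (lambda_mean / lambda_var + np.sum(t * zz / ww)) / prec
    else:
        prec = 1.0 / lambda_var
        mu = lambda_mean
    sd = 1.0 / np.sqrt(prec)
    a = (0.0 - mu) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd,
                                     random_state=rng))


def update_sigma(resid, sigma_df, sigma_scale, rng):
    """Draw the random-effect covariance from inverse-Wishart(df + m, scale + R'R)."""
    m = resid.shape[0]
    scale = sigma_scale + resid.T @ resid
    return stats.invwishart.rvs(df=sigma_df + m, scale=scale, random_state=rng)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DualSurveySAE:
    """Area-level small area model combining two surveys.

    Parameters
    ----------
    level1 : Level1Data
        Per-county arcsine-scale observation vectors with variances and mask.
    covariates : (m, p) array
        County covariate matrix aligned to ``level1.county_ids`` (intercept
        column included).
    priors : Priors, optional
    truncate_theta : bool
        Restrict theta draws to [0, pi/2] (keeps the back-transform
        well-defined).  Disable only for prior-sampling diagnostics.
    fixed : dict, optional
        Testing hook: hold any of {'beta', 'lambda', 'Sigma'} at given values
        instead of sampling them.
    """

    def __init__(self, level1: Level1Data, covariates, priors: Priors | None = None,
                 truncate_theta: bool = True, fixed: dict | None = None):
        self.level1 = level1
        self.X = np.asarray(covariates, dtype=float)
        m = len(level1)
        if self.X.ndim != 2 or self.X.shape[0] != m:
            raise ValueError("covariate matrix must have one row per retained county")
        if m and not level1.mask.any():
            # prior-sampling mode: every component masked — allowed
            pass
        elif m and np.any(~level1.mask.any(axis=1)):
            bad = level1.county_ids[~level1.mask.any(axis=1)]
            raise ValueError(f"counties with no observed component: {list(bad)}")
        self.priors = priors if priors is not None else Priors()
        self.truncate_theta = truncate_theta
        self.fixed = dict(fixed) if fixed else {}

    @classmethod
    def from_dataframes(cls, level1_df: pd.DataFrame, covariates_df: pd.DataFrame,
                        **kwargs) -> "DualSurveySAE":
        """Build from the level-1 long table and a county covariate table.

        ``covariates_df`` must have a ``county_id`` column; remaining numeric
        columns are the covariates (include the intercept explicitly or pass
        ``add_intercept=True``).
        """
        add_intercept = kwargs.pop("add_intercept", False)
        lvl = Level1Data.from_frame(level1_df)
        cov = covariates_df.set_index("county_id").loc[lvl.county_ids]
        X = cov.to_numpy(dtype=float)
        if add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return cls(lvl, X, **kwargs)

    # -- initialization ----------------------------------------------------
    def _initial_values(self, rng: np.random.Generator):
        m = len(self.level1)
        p = self.X.shape[1]
        y, mask = self.level1.y, self.level1.mask
        beta = np.zeros((3, p))
        for s in range(3):
            obs = mask[:, s]
            if s == 0:
                # fall back to the telephone component where landline missing
                use_b = mask[:, 3] & ~obs
                ys = np.where(obs, y[:, 0], y[:, 3])
                obs = obs | use_b
            else:
                ys = y[:, s]
            if obs.sum() >= p:
                beta[s], *_ = np.linalg.lstsq(self.X[obs], ys[obs], rcond=None)
            else:
                beta[s, 0] = np.pi / 6
        beta = beta + rng.normal(0.0, 0.02, beta.shape)
        theta = self.X @ beta.T
        for s in range(3):
            theta[:, s] = np.where(mask[:, s], y[:, s], theta[:, s])
        theta = np.clip(theta, 0.01, _HALF_PI - 0.01)
        lam = float(np.exp(rng.normal(0.0, 0.05)))
        Sigma = 0.01 * np.eye(3)
        return beta, theta, lam, Sigma

    # -- sampling ----------------------------------------------------------
    def fit(self, n_iter: int = 4000, n_burnin: int = 1000, n_chains: int = 2,
            thin: int = 1, seed: int | None = None,
            collapsed: bool = True) -> "SAEResults":
        """Run the Gibbs sampler and return an :class:`SAEResults`.

        Chains are seeded independently from ``seed``; with fewer than two
        chains the split-Rhat/ESS diagnostics are skipped.  ``collapsed``
        draws B with theta integrated out (a blocked update of (B, theta)
        that mixes far better); the plain conditional update is kept for
        reference and testing.
        """
        if n_burnin >= n_iter:
            raise ValueError("n_burnin must be < n_iter")
        pri = self.priors
        m = len(self.level1)
        p = self.X.shape[1]
        y, v, mask = self.level1.y, self.level1.v, self.level1.mask
        n_keep = (n_iter - n_burnin) // thin

        beta_d = np.empty((n_chains, n_keep, 3, p))
        lam_d = np.empty((n_chains, n_keep))
        Sigma_d = np.empty((n_chains, n_keep, 3, 3))
        theta_d = np.empty((n_chains, n_keep, m, 3))

        for c in range(n_chains):
            ss = np.random.SeedSequence(seed if seed is not None else 0,
                                        spawn_key=(c,))
            rng = np.random.default_rng(ss)
            beta, theta, lam, Sigma = self._initial_values(rng)
            if "beta" in self.fixed:
                beta = np.asarray(self.fixed["beta"], dtype=float)
            if "lambda" in self.fixed:
                lam = float(self.fixed["lambda"])
            if "Sigma" in self.fixed:
                Sigma = np.asarray(self.fixed["Sigma"], dtype=float)
            Sigma_inv = np.linalg.inv(Sigma)

            k = 0
            for it in range(n_iter):
                if collapsed and "beta" not in self.fixed:
                    beta = update_beta_collapsed(y, v, mask, self.X, lam,
                                                 Sigma, pri.beta_var, rng)
                theta = update_theta(y, v, mask, self.X, beta, lam, Sigma_inv,
                                     rng, truncate=self.truncate_theta)
                if not collapsed and "beta" not in self.fixed:
                    beta = update_beta(theta, self.X, Sigma_inv,
                                       pri.beta_var, rng)
                if "lambda" not in self.fixed:
                    lam = update_lambda(y[:, 3], v[:, 3], theta[:, 0],
                                        mask[:, 3], pri.lambda_mean,
                                        pri.lambda_var, rng)
                if "Sigma" not in self.fixed:
                    resid = theta - self.X @ beta.T
                    Sigma = update_sigma(resid, pri.sigma_df,
                                         pri.sigma_scale, rng)
                    Sigma_inv = np.linalg.inv(Sigma)
                if it >= n_burnin and (it - n_burnin) % thin == 0:
                    beta_d[c, k] = beta
                    lam_d[c, k] = lam
                    Sigma_d[c, k] = Sigma
                    theta_d[c, k] = theta
                    k += 1

        return SAEResults(self, beta_d, lam_d, Sigma_d, theta_d)


class SAEResults:
    """Posterior draws and diagnostics from :meth:`DualSurveySAE.fit`.

    Draw arrays keep the (chain, draw, ...) layout; the ``*_draws``
    properties give chain-flattened views.  ``diagnostics`` holds max
    split-Rhat and min bulk-ESS over beta, lambda and Sigma entries, plus a
    ``converged`` flag (Rhat <= 1.1 and ESS >= 400).
    """

    def __init__(self, model: DualSurveySAE, beta, lam, Sigma, theta):
        self.model = model
        self.county_ids = model.level1.county_ids
        self._beta = beta
        self._lambda = lam
        self._Sigma = Sigma
        self._theta = theta
        self.diagnostics = self._compute_diagnostics()
        if not self.diagnostics.get("converged", True):
            warnings.warn(
                "Gibbs sampler convergence diagnostics failed: "
                f"max Rhat={self.diagnostics['rhat_max']:.3f}, "
                f"min ESS={self.diagnostics['ess_min']:.0f}",
                RuntimeWarning,
            )

    # flattened draws -------------------------------------------------------
    @property
    def beta_draws(self):
        return self._beta.reshape(-1, *self._beta.shape[2:])

    @property
    def lambda_draws(self):
        return self._lambda.reshape(-1)

    @property
    def sigma_draws(self):
        return self._Sigma.reshape(-1, 3, 3)

    @property
    def theta_draws(self):
        return self._theta.reshape(-1, *self._theta.shape[2:])

    @property
    def n_draws(self):
        return self.lambda_draws.size

    def _fixed(self, name):
        return name in self.model.fixed

    def _compute_diagnostics(self) -> dict:
        n_chains = self._lambda.shape[0]
        free = {}
        if not self._fixed("beta"):
            free["beta"] = self._beta
        if not self._fixed("lambda"):
            free["lambda"] = self._lambda
        if not self._fixed("Sigma"):
            free["Sigma"] = self._Sigma
        if n_chains < 2 or not free:
            return {"rhat_max": np.nan, "ess_min": np.nan, "converged": True,
                    "note": "diagnostics need >= 2 chains and free parameters"}
        import arviz as az
        idata = az.from_dict(posterior=free)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rhat_max = float(max(np.nanmax(rhat[k].values) for k in free))
        ess_min = float(min(np.nanmin(ess[k].values) for k in free))
        return {
            "rhat_max": rhat_max,
            "ess_min": ess_min,
            "converged": bool(rhat_max <= 1.1 and ess_min >= 400),
        }

    # reporting -------------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior summary table for beta, lambda and Sigma."""
        rows = []

        def add(name, draws):
            q = np.percentile(draws, [2.5, 97.5])
            rows.append({
                "parameter": name,
                "mean": float(np.mean(draws)),
                "sd": float(np.std(draws, ddof=1)),
                "q2.5": q[0],
                "q97.5": q[1],
            })

        p = self._beta.shape[-1]
        strata = ("landline", "cellonly", "nophone")
        for s in range(3):
            for j in range(p):
                add(f"beta[{strata[s]},x{j}]", self._beta[..., s, j])
        add("lambda", self._lambda)
        for s in range(3):
            for t in range(s, 3):
                add(f"Sigma[{strata[s]},{strata[t]}]", self._Sigma[..., s, t])
        df = pd.DataFrame(rows)
        df.attrs["diagnostics"] = self.diagnostics
        return df

    def theta_for(self, county_id) -> np.ndarray:
        """(n_draws, 3) transformed-scale draws for one county."""
        idx = np.where(self.county_ids == county_id)[0]
        if idx.size == 0:
            raise KeyError(f"county {county_id!r} not in fitted model")
        return self.theta_draws[:, idx[0], :]

    def modeled_prevalence(self) -> dict[str, np.ndarray]:
        """Posterior mean stratum prevalences per county (draw-wise sin^2)."""
        prev = np.sin(self.theta_draws) ** 2        # (draws, m, 3)
        return {
            "county_id": self.county_ids,
            "mean": prev.mean(axis=0),
            "sd": prev.std(axis=0, ddof=1),
        }

    def county_estimates(self, phi, outcome: str = "outcome",
                         alpha: float = 0.05) -> pd.DataFrame:
        """Combined county prevalences with credible intervals.

        ``phi`` is a DataFrame with ``county_id`` and the three stratum share
        columns (``phi_landline``, ``phi_cellonly``, ``phi_nophone``); the
        composition is applied per posterior draw.
        """
        from .compose import compose_counties
        return compose_counties(self, phi, outcome=outcome, alpha=alpha)

    def draws_frame(self) -> pd.DataFrame:
        """Long-format hyperparameter draws (parameter, chain, iteration, value)."""
        rec = []
        n_chains, n_keep = self._lambda.shape
        p = self._beta.shape[-1]
        for c in range(n_chains):
            for k in range(n_keep):
                rec.append({"parameter": "lambda", "chain": c,
                            "iteration": k, "value": self._lambda[c, k]})
        for s in range(3):
            for j in range(p):
                for c in range(n_chains):
                    for k in range(n_keep):
                        rec.append({"parameter": f"beta[{s},{j}]", "chain": c,
                                    "iteration": k,
                                    "value": self._beta[c, k, s, j]})
        for s in range(3):
            for t in range(3):
                for c in range(n_chains):
                    for k in range(n_keep):
                        rec.append({"parameter": f"Sigma[{s},{t}]", "chain": c,
                                    "iteration": k,
                                    "value": self._Sigma[c, k, s, t]})
        return pd.DataFrame(rec)

    def plot_funnel(self, funnel_points: pd.DataFrame, ax=None):
        """Scatter of direct-to-model ratios against effective sample size."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(funnel_points["brfss_n_eff"], funnel_points["ratio"],
                   s=12, alpha=0.6)
        ax.axhline(1.0, color="k", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("telephone-survey effective sample size")
        ax.set_ylabel("adjusted direct / modeled landline")
        return ax
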