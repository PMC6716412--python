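"""Phone-composition smoothing and the combined county estimate.

The combined county prevalence is the phone-composition-weighted mixture of
stratum prevalences, computed per posterior draw:

    pi_i^(g) = sum_s phi_is * sin^2(theta_is^(g))

so the back-transform nonlinearity is handled inside the posterior rather
than applied to posterior means.  The composition weights phi are treated as
fixed and known at composition time; their own sampling uncertainty is not
propagated (a stated limitation).

County compositions themselves are estimated from the in-person survey's
phone-status counts by empirical-Bayes shrinkage of the log-odds (cell-only
vs landline, no-phone vs landline) toward a county-covariate regression.
Counties with no sample receive the pure regression prediction; counties
with large samples keep their empirical shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import STRATA, SurveyMicrodata

__all__ = [
    "PhoneComposition",
    "CountySAE",
    "smooth_phone_composition",
    "phone_counts",
    "compose_county",
    "compose_counties",
]


@dataclass
class PhoneComposition:
    """Estimated phone-status shares for one county."""

    county_id: str
    phi_hat: np.ndarray
    source: str  # 'input_file' or 'smoothed'

    def __post_init__(self) -> None:
        self.phi_hat = np.asarray(self.phi_hat, dtype=float)
        if np.any((self.phi_hat < 0) | (self.phi_hat > 1)) or \
                abs(self.phi_hat.sum() - 1.0) > 1e-9:
            raise ValueError("phi_hat must be a simplex over the 3 strata")


@dataclass
class CountySAE:
    """Combined county prevalence: posterior mean with 95% credible bounds."""

    county_id: str
    outcome: str
    estimate: float
    ci_lower: float
    ci_upper: float
    posterior_sd: float

    def __post_init__(self) -> None:
        # tolerate float rounding at zero-width intervals
        tol = 1e-9
        if self.ci_lower - tol <= self.estimate <= self.ci_upper + tol:
            self.ci_lower = min(self.ci_lower, self.estimate)
            self.ci_upper = max(self.ci_upper, self.estimate)
        ok = 0.0 <= self.ci_lower <= self.estimate <= self.ci_upper <= 1.0
        if not ok:
            raise ValueError("require 0 <= ci_lower <= estimate <= ci_upper <= 1")


def phone_counts(microdata: SurveyMicrodata) -> pd.DataFrame:
    """County x stratum respondent counts (for composition smoothing)."""
    tab = (microdata.rows.groupby(["county_id", "phone_stratum"])
           .size().unstack(fill_value=0))
    for s in STRATA:
        if s not in tab.columns:
            tab[s] = 0
    return tab[list(STRATA)].reset_index()


def _eb_logodds(l_obs, s2, X, obs, n_iter=10):
    """Shrink observed log-odds toward a covariate regression.

    Between-county variance tau2 is estimated by a weighted moment matcher
    (Fay-Herriot style); the shrinkage weight per county is
    tau2 / (tau2 + sampling variance).
    """
    tau2 = 0.1
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        w = 1.0 / (s2[obs] + tau2)
        res = sm.WLS(l_obs[obs], X[obs], weights=w).fit()
        beta = res.params
        resid = l_obs[obs] - X[obs] @ beta
        # moment estimate of the between-county variance
        tau2 = max(float(np.average(resid**2 - s2[obs], weights=w)), 1e-6)
    pred = X @ beta
    shrink = np.zeros(len(l_obs))
    shrink[obs] = tau2 / (tau2 + s2[obs])
    out = pred.copy()
    out[obs] = shrink[obs] * l_obs[obs] + (1 - shrink[obs]) * pred[obs]
    return out


def smooth_phone_composition(nhis_counts: pd.DataFrame, covariates: pd.DataFrame,
                             ) -> list[PhoneComposition]:
    """Empirical-Bayes multinomial-logit smoothing of county phone shares.

    ``nhis_counts``: columns county_id, landline, cellonly, nophone (counts,
    zero rows allowed).  ``covariates``: county_id plus covariate columns
    (intercept included) covering every county to be estimated.
    """
    cov = covariates.set_index("county_id")
    counts = nhis_counts.set_index("county_id").reindex(cov.index, fill_value=0)
    if counts[list(STRATA)].to_numpy().sum() == 0:
        raise ValueError("all phone-status counts are zero nationally")

    X = cov.to_numpy(dtype=float)
    nL = counts["landline"].to_numpy(dtype=float)
    logodds = np.zeros((len(cov), 2))
    total = counts[list(STRATA)].sum(axis=1).to_numpy(dtype=float)
    obs = total > 0
    for k, s in enumerate(("cellonly", "nophone")):
        ns = counts[s].to_numpy(dtype=float)
        l_obs = np.log((ns + 0.5) / (nL + 0.5))
        s2 = 1.0 / (ns + 0.5) + 1.0 / (nL + 0.5)
        logodds[:, k] = _eb_logodds(l_obs, s2, X, obs)

    expo = np.exp(np.column_stack([np.zeros(len(cov)), logodds]))
    phi = expo / expo.sum(axis=1, keepdims=True)
    return [
        PhoneComposition(cid, phi[i], "smoothed")
        for i, cid in enumerate(cov.index)
    ]


def compositions_to_frame(comps: list[PhoneComposition]) -> pd.DataFrame:
    return pd.DataFrame([
        {"county_id": c.county_id,
         **{f"phi_{s}": c.phi_hat[k] for k, s in enumerate(STRATA)},
         "source": c.source}
        for c in comps
    ])


def compose_county(theta_draws: np.ndarray, phi, county_id="", outcome="outcome",
                   alpha: float = 0.05, min_draws: int = 400) -> CountySAE:
    """Combine stratum draws into one county prevalence with credible bounds.

    Per draw g: pi^(g) = sum_s phi_s sin^2(theta_s^(g)); the estimate is the
    draw mean, the interval the equal-tailed (alpha/2, 1-alpha/2) percentiles.
    """
    theta_draws = np.asarray(theta_draws, dtype=float)
    if theta_draws.ndim != 2 or theta_draws.shape[1] != 3:
        raise ValueError("theta_draws must be (n_draws, 3)")
    if theta_draws.shape[0] < min_draws:
        raise ValueError(f"need >= {min_draws} retained draws")
    phi_vec = phi.phi_hat if isinstance(phi, PhoneComposition) else np.asarray(phi, float)
    pi = (np.sin(theta_draws) ** 2) @ phi_vec
    lo, hi = np.percentile(pi, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if np.ptp(pi) == 0:
        warnings.warn(f"degenerate draws for county {county_id}: zero-width CI",
                      RuntimeWarning)
    return CountySAE(
        county_id=county_id,
        outcome=outcome,
        estimate=float(pi.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        posterior_sd=float(pi.std(ddof=1)) if len(pi) > 1 else 0.0,
    )


def compose_counties(results, phi_df: pd.DataFrame, outcome="outcome",
                     alpha: float = 0.05) -> pd.DataFrame:
    """Combined estimates for every fitted county present in ``phi_df``."""
    phi_df = phi_df.set_index("county_id")
    cols = [f"phi_{s}" for s in STRATA]
    rec = []
    theta = results.theta_draws  # (draws, m, 3)
    for i, cid in enumerate(results.county_ids):
        if cid not in phi_df.index:
            continue
        phi = phi_df.loc[cid, cols].to_numpy(dtype=float)
        sae = compose_county(theta[:, i, :], phi / phi.sum(), county_id=cid,
                             outcome=outcome, alpha=alpha)
        rec.append({
            "county_id": cid, "outcome": outcome,
            "estimate": sae.estimate, "ci_lower": sae.ci_lower,
            "ci_upper": sae.ci_upper, "posterior_sd": sae.posterior_sd,
        })
    return pd.DataFrame(rec)
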