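"""Synthetic two-survey county data generator.

Emulates the joint structure that the dual-survey small-area model assumes:

* an in-person household survey ("NHIS-like") that reaches households in all
  three telephone strata (landline, cell-only, no phone) but, by design,
  samples only about a quarter of counties, with small per-county samples;
* a much larger telephone survey ("BRFSS-like") that samples the landline
  stratum only, in every county, with a multiplicative bias factor
  ``lambda_true`` acting on the arcsine-root (transformed) scale.

County truth is generated from the model itself: transformed stratum means
``theta_i = B x_i + u_i`` with correlated county random effects
``u_i ~ MVN(0, Sigma_true)``, county phone-status compositions ``phi_i`` from
a logistic-normal centered at the national household shares, and respondent
outcomes Bernoulli(sin^2 theta).  Survey weights are lognormal with a
configurable coefficient of variation, so Kish design effects ≈ 1 + CV^2 > 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STRATA",
    "NATIONAL_PHONE_SHARES",
    "CountyTruth",
    "GeneratorConfig",
    "SurveyMicrodata",
    "generate_counties",
    "counties_to_frame",
    "sample_nhis",
    "sample_brfss",
]

#: Telephone strata, in the fixed component order used throughout.
STRATA = ("landline", "cellonly", "nophone")

#: National household telephone-status shares used as the composition center.
NATIONAL_PHONE_SHARES = (0.750, 0.232, 0.018)

_STAGES = ("counties", "nhis", "brfss")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream per pipeline stage."""
    key = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _default_beta(p: int) -> np.ndarray:
    # Intercepts place stratum prevalences at 17.7 / 27.3 / 30.9 % (the
    # landline < cell-only < no-phone smoking gradient); slopes are small
    # covariate effects on the transformed scale.
    intercepts = np.arcsin(np.sqrt([0.177, 0.273, 0.309]))
    beta = np.zeros((3, p))
    beta[:, 0] = intercepts
    for j in range(1, p):
        beta[:, j] = (0.04 if j % 2 else -0.03) * np.array([1.0, 1.0, 1.25])
    return beta


def _default_sigma() -> np.ndarray:
    corr = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
    return 0.002 * corr


@dataclass
class CountyTruth:
    """True state of one synthetic county.

    ``theta_true`` holds the transformed-scale stratum means (radians),
    ``pi_true = sin^2(theta_true)`` the stratum prevalences, and
    ``pi_combined_true`` the phone-composition-weighted county prevalence.
    """

    county_id: str
    population: int
    covariates: np.ndarray
    phi: np.ndarray
    theta_true: np.ndarray

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        if self.population <= 0:
            raise ValueError("population must be positive")
        if np.any(self.phi < 0) or abs(self.phi.sum() - 1.0) > 1e-12:
            raise ValueError("phi must be a simplex over the 3 strata")
        if np.any(self.theta_true < 0) or np.any(self.theta_true > np.pi / 2):
            raise ValueError("theta_true components must lie in [0, pi/2]")

    @property
    def pi_true(self) -> np.ndarray:
        return np.sin(self.theta_true) ** 2

    @property
    def pi_combined_true(self) -> float:
        return float(self.phi @ self.pi_true)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic two-survey world.

    Defaults mirror the magnitudes of the real study: ~25% NHIS county
    coverage, a ~10x BRFSS/NHIS per-county sample-size ratio, a landline
    noncoverage bias factor below one, stratum prevalence gaps of the
    smoking-gradient size, and unequal weights giving design effects > 1.
    """

    m_counties: int = 300
    p_covariates: int = 3
    beta_true: np.ndarray | None = None
    Sigma_true: np.ndarray | None = None
    lambda_true: float = 0.9
    nhis_county_fraction: float = 0.25
    nhis_mean_n: int = 12
    brfss_mean_n: int = 120
    weight_cv: float = 0.7
    phi_center: tuple[float, float, float] = NATIONAL_PHONE_SHARES
    phi_logit_sd: float = 0.4
    pop_log_mean: float = 10.0
    pop_log_sd: float = 1.2
    theta_clip: float = 0.02
    nhis_psu_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_counties < 1 or self.p_covariates < 1:
            raise ValueError("m_counties and p_covariates must be positive")
        if self.beta_true is None:
            self.beta_true = _default_beta(self.p_covariates)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (3, self.p_covariates):
            raise ValueError("beta_true must be 3 x p_covariates")
        if self.Sigma_true is None:
            self.Sigma_true = _default_sigma()
        self.Sigma_true = np.asarray(self.Sigma_true, dtype=float)
        if not np.allclose(self.Sigma_true, self.Sigma_true.T):
            raise ValueError("Sigma_true must be symmetric")
        eig = np.linalg.eigvalsh(self.Sigma_true)
        if np.any(eig < 0):
            raise ValueError("Sigma_true must be positive semi-definite")
        if self.lambda_true <= 0:
            raise ValueError("lambda_true must be positive")
        if not 0 < self.nhis_county_fraction <= 1:
            raise ValueError("nhis_county_fraction must lie in (0, 1]")
        if self.weight_cv < 0:
            raise ValueError("weight_cv must be nonnegative")


@dataclass
class SurveyMicrodata:
    """Respondent rows for one pseudo-survey.

    ``rows`` columns: county_id, phone_stratum, outcome (0/1), weight,
    design_stratum, psu.
    """

    survey_name: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if self.survey_name not in ("NHIS", "BRFSS"):
            raise ValueError("survey_name must be NHIS or BRFSS")
        required = {"county_id", "phone_stratum", "outcome", "weight",
                    "design_stratum", "psu"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"rows missing columns: {sorted(missing)}")
        if len(self.rows):
            if (self.rows["weight"] <= 0).any():
                raise ValueError("all weights must be positive")
            bad = ~self.rows["phone_stratum"].isin(STRATA)
            if bad.any():
                raise ValueError("unknown phone_stratum label")
            if self.survey_name == "BRFSS" and \
                    (self.rows["phone_stratum"] != "landline").any():
                raise ValueError("BRFSS rows must all be landline")

    def to_csv(self, path, seed: int | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# survey={self.survey_name}")
            if seed is not None:
                fh.write(f" seed={seed}")
            fh.write("\n")
            self.rows.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, survey_name: str | None = None) -> "SurveyMicrodata":
        name = survey_name
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("survey="):
                        name = tok.split("=", 1)[1]
                rows = pd.read_csv(fh)
            else:
                fh.seek(0)
                rows = pd.read_csv(fh)
        if name is None:
            raise ValueError("survey_name not given and not found in header")
        return cls(name, rows)


def generate_counties(config: GeneratorConfig) -> list[CountyTruth]:
    """Draw county truth: covariates, populations, phone shares, stratum means.

    theta_i = B x_i + u_i, u_i ~ MVN(0, Sigma_true), clipped to
    [theta_clip, pi/2 - theta_clip]; phi_i logistic-normal centered at the
    national shares.  Deterministic given ``config.seed``.
    """
    rng = _stage_rng(config.seed, "counties")
    m, p = config.m_counties, config.p_covariates

    X = np.ones((m, p))
    if p > 1:
        X[:, 1:] = rng.standard_normal((m, p - 1))

    # county random effects; eigen factor so exactly singular Sigma is allowed
    vals, vecs = np.linalg.eigh(config.Sigma_true)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    u = rng.standard_normal((m, 3)) @ L.T
    theta = X @ config.beta_true.T + u
    theta = np.clip(theta, config.theta_clip, np.pi / 2 - config.theta_clip)

    center = np.asarray(config.phi_center, dtype=float)
    eta0 = np.log(center[1:] / center[0])
    eta = eta0 + rng.normal(0.0, config.phi_logit_sd, (m, 2))
    expo = np.exp(np.column_stack([np.zeros(m), eta]))
    phi = expo / expo.sum(axis=1, keepdims=True)

    pop = np.maximum(
        rng.lognormal(config.pop_log_mean, config.pop_log_sd, m), 100.0
    ).astype(int)

    width = len(str(m))
    return [
        CountyTruth(
            county_id=f"c{i:0{width}d}",
            population=int(pop[i]),
            covariates=X[i],
            phi=phi[i] / phi[i].sum(),
            theta_true=theta[i],
        )
        for i in range(m)
    ]


def counties_to_frame(counties: list[CountyTruth]) -> pd.DataFrame:
    """Tabular view of county truth (one row per county)."""
    rec = []
    for c in counties:
        row = {"county_id": c.county_id, "population": c.population}
        row.update({f"x{j}": v for j, v in enumerate(c.covariates)})
        row.update({f"phi_{s}": v for s, v in zip(STRATA, c.phi)})
        row.update({f"theta_{s}": v for s, v in zip(STRATA, c.theta_true)})
        row.update({f"pi_{s}": v for s, v in zip(STRATA, c.pi_true)})
        row["pi_combined"] = c.pi_combined_true
        rec.append(row)
    return pd.DataFrame(rec)


def _truncated_poisson(rng: np.random.Generator, mean: float, low: int = 2) -> int:
    n = int(rng.poisson(mean))
    tries = 0
    while n < low:
        n = int(rng.poisson(mean))
        tries += 1
        if tries > 1000:
            return low
    return n


def _weights(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sig2 = np.log1p(cv**2)
    return rng.lognormal(-sig2 / 2, np.sqrt(sig2), n)


def sample_nhis(counties: list[CountyTruth], config: GeneratorConfig) -> SurveyMicrodata:
    """Simulate the in-person survey: a random ~25% of counties, all strata.

    Within a sampled county respondents are allocated to phone strata in
    proportion to phi_i; outcomes are Bernoulli(sin^2 theta_is); weights are
    lognormal with the configured CV; respondents are grouped into PSUs of
    ``nhis_psu_size``.
    """
    rng = _stage_rng(config.seed, "nhis")
    m = len(counties)
    k = int(round(m * config.nhis_county_fraction))
    if k < 1:
        raise ValueError("nhis_county_fraction * m_counties < 1: no county sampled")
    sampled = rng.choice(m, size=k, replace=False)

    chunks: list[pd.DataFrame] = []
    for idx in np.sort(sampled):
        c = counties[idx]
        n = _truncated_poisson(rng, config.nhis_mean_n)
        alloc = rng.multinomial(n, c.phi)
        w = _weights(rng, n, config.weight_cv)
        strat = np.repeat(np.array(STRATA), alloc)
        p = np.repeat(np.sin(c.theta_true) ** 2, alloc)
        y = rng.binomial(1, p)
        pos = np.arange(n)
        chunks.append(pd.DataFrame({
            "county_id": c.county_id,
            "phone_stratum": strat,
            "outcome": y,
            "weight": w,
            "design_stratum": f"ds_{c.county_id}",
            "psu": [f"{c.county_id}_psu{j // config.nhis_psu_size}" for j in pos],
        }))
    cols = ["county_id", "phone_stratum", "outcome", "weight",
            "design_stratum", "psu"]
    rows = (pd.concat(chunks, ignore_index=True) if chunks
            else pd.DataFrame(columns=cols))
    return SurveyMicrodata("NHIS", rows[cols])


def sample_brfss(counties: list[CountyTruth], config: GeneratorConfig) -> SurveyMicrodata:
    """Simulate the telephone survey: every county, landline stratum only.

    The transformed-scale mean of the county sample is lambda_true * theta_iL,
    i.e. respondents succeed with probability sin^2(lambda_true * theta_iL).
    Per-county sample size is Poisson with a population-proportional mean
    (county telephone samples scale with population), truncated at 2.
    """
    rng = _stage_rng(config.seed, "brfss")
    theta_L = np.array([c.theta_true[0] for c in counties])
    biased = config.lambda_true * theta_L
    if np.any(biased >= np.pi / 2):
        raise ValueError(
            "lambda_true * theta_landline >= pi/2 for some county: "
            "biased prevalence undefined"
        )
    pops = np.array([c.population for c in counties], dtype=float)
    rate = config.brfss_mean_n * pops / pops.mean()

    chunks: list[pd.DataFrame] = []
    for i, c in enumerate(counties):
        n = _truncated_poisson(rng, rate[i])
        p = float(np.sin(biased[i]) ** 2)
        chunks.append(pd.DataFrame({
            "county_id": c.county_id,
            "phone_stratum": "landline",
            "outcome": rng.binomial(1, p, n),
            "weight": _weights(rng, n, config.weight_cv),
            "design_stratum": f"ds_{c.county_id}",
            "psu": [f"{c.county_id}_b{j}" for j in range(n)],
        }))
    cols = ["county_id", "phone_stratum", "outcome", "weight",
            "design_stratum", "psu"]
    rows = (pd.concat(chunks, ignore_index=True) if chunks
            else pd.DataFrame(columns=cols))
    return SurveyMicrodata("BRFSS", rows[cols])
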