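"""Survey-weighted direct prevalence estimates with design effects.

Produces county-level (and national) weighted prevalence estimates per phone
stratum, with a Kish-approximation design effect, effective sample size
``n_eff = n / deff``, and the with-replacement binomial variance
``deff * p(1-p) / n``.  These are the level-1 inputs of the area-level model.

The full Taylor-linearized stratified-PSU variance is deliberately not
implemented: the model consumes only (p_hat, var_hat, n_eff) and the
synthetic weights are the only source of design effect; PSU and design
stratum labels are carried through so a linearized estimator could be added
without changing the output format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import STRATA, SurveyMicrodata

__all__ = [
    "OutcomeDefinition",
    "OUTCOMES",
    "NATIONAL_ID",
    "weighted_prevalence",
    "kish_deff",
    "direct_estimates",
]

#: county_id used for the pooled national record.
NATIONAL_ID = "NATIONAL"


@dataclass(frozen=True)
class OutcomeDefinition:
    """A prevalence outcome with its denominator filter.

    ``sex_filter`` restricts the denominator by sex ('all', 'male',
    'female'); ``min_age`` is the minimum age in years.  Filters apply only
    when the microdata carry ``sex`` / ``age`` columns; the synthetic
    generator produces a single generic outcome without demographics.
    """

    name: str
    sex_filter: str
    min_age: int
    description: str

    def filter_rows(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows
        if self.sex_filter != "all" and "sex" in out.columns:
            out = out[out["sex"] == self.sex_filter]
        if "age" in out.columns:
            out = out[out["age"] >= self.min_age]
        return out


#: The 11 shipped outcome definitions (smoking and cancer-screening measures).
OUTCOMES: dict[str, OutcomeDefinition] = {
    d.name: d
    for d in [
        OutcomeDefinition("current_smoking", "all", 18,
                          "Currently smokes, >=100 cigarettes lifetime, age 18+"),
        OutcomeDefinition("current_smoking_male", "male", 18,
                          "Current smoking among men 18+"),
        OutcomeDefinition("current_smoking_female", "female", 18,
                          "Current smoking among women 18+"),
        OutcomeDefinition("ever_smoking", "all", 18,
                          "Smoked >=100 cigarettes lifetime, age 18+"),
        OutcomeDefinition("ever_smoking_male", "male", 18,
                          "Ever smoking among men 18+"),
        OutcomeDefinition("ever_smoking_female", "female", 18,
                          "Ever smoking among women 18+"),
        OutcomeDefinition("mammography", "female", 40,
                          "Mammogram within past 2 years, women 40+"),
        OutcomeDefinition("pap_test", "female", 18,
                          "Papanicolaou test within past 3 years, women 18+"),
        OutcomeDefinition("hfobt", "all", 50,
                          "Home fecal occult blood test within past 2 years, 50+"),
        OutcomeDefinition("colorectal_endoscopy", "all", 50,
                          "Any colorectal endoscopy ever, age 50+"),
        OutcomeDefinition("crc_screening", "all", 50,
                          "HFOBT in past 2 years or any endoscopy ever, 50+"),
    ]
}


def weighted_prevalence(y, w) -> float:
    """Horvitz-Thompson style weighted proportion sum(w*y)/sum(w)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size == 0:
        raise ValueError("empty input: estimate undefined (exclude the county)")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w * y) / np.sum(w))


def kish_deff(w) -> float:
    """Kish design effect of unequal weighting: n * sum(w^2) / (sum w)^2."""
    w = np.asarray(w, dtype=float)
    if w.size == 0 or np.any(w <= 0):
        raise ValueError("weights must be a nonempty positive vector")
    return float(len(w) * np.sum(w**2) / np.sum(w) ** 2)


def _estimate_record(sub: pd.DataFrame, county_id, stratum: str) -> dict:
    y = sub["outcome"].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    n = len(y)
    p = weighted_prevalence(y, w)
    deff = kish_deff(w)
    n_eff = n / deff
    if p in (0.0, 1.0):
        # variance floor: avoids a zero level-1 variance at the boundary
        var = (1.0 / (4.0 * n_eff)) / n
    else:
        var = deff * p * (1.0 - p) / n
    return {
        "county_id": county_id,
        "stratum": stratum,
        "p_hat": p,
        "var_hat": var,
        "n": n,
        "deff": deff,
        "n_eff": n_eff,
    }


def direct_estimates(
    microdata: SurveyMicrodata,
    outcome: OutcomeDefinition | None = None,
    by_stratum: bool = True,
    include_national: bool = True,
) -> pd.DataFrame:
    """Direct estimates per county x stratum, plus county and national pools.

    One record is emitted per county x stratum with >=1 respondent, plus a
    pooled ``stratum='all'`` record per county, and (optionally) national
    records pooling every county with full weights.  Counties absent from
    the microdata yield no record (missing by design, not zero).
    """
    rows = microdata.rows
    if outcome is not None:
        rows = outcome.filter_rows(rows)
    if len(rows):
        unknown = set(rows["phone_stratum"].unique()) - set(STRATA)
        if unknown:
            raise ValueError(f"unknown stratum labels: {sorted(unknown)}")

    rec: list[dict] = []
    for cid, sub in rows.groupby("county_id", sort=True):
        if by_stratum:
            for s, ssub in sub.groupby("phone_stratum", sort=False):
                rec.append(_estimate_record(ssub, cid, s))
        rec.append(_estimate_record(sub, cid, "all"))
    if include_national and len(rows):
        if by_stratum:
            for s, ssub in rows.groupby("phone_stratum", sort=False):
                rec.append(_estimate_record(ssub, NATIONAL_ID, s))
        rec.append(_estimate_record(rows, NATIONAL_ID, "all"))

    cols = ["county_id", "stratum", "p_hat", "var_hat", "n", "deff", "n_eff"]
    out = pd.DataFrame(rec, columns=cols)
    if outcome is not None:
        out.insert(2, "outcome", outcome.name)
    return out
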