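"""Internal and external validation battery for the small area estimates.

Four numeric checks:

* funnel: ratios of bias-adjusted telephone-survey direct estimates to the
  modeled landline estimates, summarized as mean |log ratio| per
  effective-sample-size bin — the ratios should converge to one as the
  county's telephone sample grows;
* national aggregation: the population-weighted aggregate of county modeled
  estimates should track the in-person survey's national direct estimate
  (the unbiased benchmark), not the telephone survey's;
* county summaries: the Table-2-style seven-number summary (min, quartiles,
  max, mean, sd) per outcome;
* external correlation: weighted Pearson correlation between the county
  estimates and an external county rate table (e.g. registry mortality),
  weighted by the inverse variance of the external rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transform import from_arcsine, to_arcsine

__all__ = [
    "FunnelPoint",
    "ValidationReport",
    "funnel_ratios",
    "funnel_summary",
    "aggregate_national",
    "weighted_correlation",
    "summarize_counties",
]

#: n_eff bin edges used for the funnel summary.
FUNNEL_BINS = (25.0, 100.0)


@dataclass
class FunnelPoint:
    county_id: str
    ratio: float
    brfss_n_eff: float

    def __post_init__(self) -> None:
        if self.ratio <= 0 or self.brfss_n_eff <= 0:
            raise ValueError("ratio and n_eff must be positive")


@dataclass
class ValidationReport:
    funnel: pd.DataFrame
    funnel_bins: pd.DataFrame
    national_check: pd.DataFrame
    summaries: pd.DataFrame
    external_corr: dict = field(default_factory=dict)


def funnel_ratios(brfss_direct: pd.DataFrame, lambda_hat: float,
                  modeled_landline: pd.DataFrame) -> pd.DataFrame:
    """Per-county ratio of adjusted telephone direct to modeled landline estimate.

    The telephone direct estimate is moved to the transformed scale, divided
    by the estimated bias factor, and back-transformed before the ratio:
    ratio_i = sin^2(z_i / lambda_hat) / modeled_i.  ``modeled_landline``:
    columns county_id, modeled (prevalence scale).
    """
    if lambda_hat <= 0:
        raise ValueError("lambda_hat must be positive")
    modeled = modeled_landline.set_index("county_id")["modeled"]
    sub = brfss_direct[(brfss_direct["stratum"] == "landline")]
    rec = []
    for _, r in sub.iterrows():
        cid = r["county_id"]
        if cid not in modeled.index:
            continue
        mod = float(modeled.loc[cid])
        if mod <= 0:
            continue  # skipped: modeled estimate zero
        z, _ = to_arcsine(r["p_hat"], r["n_eff"], n=r["n"])
        adj = from_arcsine(min(z / lambda_hat, np.pi / 2))
        if adj <= 0:
            continue
        rec.append({"county_id": cid, "ratio": adj / mod,
                    "brfss_n_eff": float(r["n_eff"])})
    return pd.DataFrame(rec, columns=["county_id", "ratio", "brfss_n_eff"])


def funnel_summary(points: pd.DataFrame, bins=FUNNEL_BINS) -> pd.DataFrame:
    """Mean |log ratio| per effective-sample-size bin."""
    lo, hi = bins
    labels = [f"<= {lo:g}", f"{lo:g} - {hi:g}", f"> {hi:g}"]
    edges = [-np.inf, lo, hi, np.inf]
    cats = pd.cut(points["brfss_n_eff"], edges, labels=labels)
    out = (points.assign(abs_log_ratio=np.abs(np.log(points["ratio"])), bin=cats)
           .groupby("bin", observed=False)["abs_log_ratio"]
           .agg(["mean", "count"]).reset_index())
    return out.rename(columns={"mean": "mean_abs_log_ratio", "count": "n_counties"})


def aggregate_national(county_saes: pd.DataFrame, populations: pd.DataFrame) -> float:
    """Population-weighted national aggregate of county modeled estimates."""
    pops = populations.set_index("county_id")["population"]
    missing = set(county_saes["county_id"]) - set(pops.index)
    if missing:
        raise ValueError(f"population missing for counties: {sorted(missing)[:5]}")
    w = pops.loc[county_saes["county_id"]].to_numpy(dtype=float)
    est = county_saes["estimate"].to_numpy(dtype=float)
    return float(np.sum(w * est) / np.sum(w))


def weighted_correlation(x, y, w) -> float:
    """Weighted Pearson correlation with weighted means and variances."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (len(x) == len(y) == len(w)) or len(x) < 3:
        raise ValueError("x, y, w must have equal length >= 3")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance: correlation undefined")
    return float(cov / np.sqrt(vx * vy))


def summarize_counties(county_saes: pd.DataFrame) -> pd.DataFrame:
    """Seven-number summary (percent scale) of county estimates per outcome.

    Quantiles use linear interpolation between order statistics.
    """
    if len(county_saes) == 0:
        raise ValueError("no county estimates to summarize")
    rec = []
    for outcome, sub in county_saes.groupby("outcome"):
        e = 100.0 * sub["estimate"].to_numpy(dtype=float)
        q25, q50, q75 = np.percentile(e, [25, 50, 75])
        rec.append({
            "outcome": outcome,
            "min": float(e.min()), "q25": q25, "median": q50, "q75": q75,
            "max": float(e.max()), "mean": float(e.mean()),
            "sd": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
        })
    return pd.DataFrame(rec)
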