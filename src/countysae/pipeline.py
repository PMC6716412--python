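"""End-to-end pipeline: simulate -> direct -> transform -> fit -> compose -> validate.

A single flat seed is expanded into per-stage substreams, so any stage can
be rerun in isolation and identical config + seed gives byte-identical
output CSVs.  Every output file carries a ``# seed=...`` header comment.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compose as compose_mod
from . import direct as direct_mod
from . import synthetic
from .model import DualSurveySAE, Priors
from .transform import assemble_level1
from .validate import (ValidationReport, aggregate_national, funnel_ratios,
                       funnel_summary, summarize_counties)

__all__ = ["RunConfig", "run_all", "write_csv", "read_csv"]

log = logging.getLogger("countysae")


@dataclass
class RunConfig:
    """Flat run configuration for the full pipeline."""

    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    outcome: str = "current_smoking"
    n_iter: int = 3000
    n_burnin: int = 1000
    n_chains: int = 2
    thin: int = 1
    priors: Priors = field(default_factory=Priors)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_kwargs = {k[len("generator_"):]: v for k, v in raw.items()
                      if k.startswith("generator_")}
        pri_kwargs = {k[len("prior_"):]: v for k, v in raw.items()
                      if k.startswith("prior_")}
        top = {k: v for k, v in raw.items()
               if not k.startswith(("generator_", "prior_"))}
        seed = int(top.get("seed", 0))
        gen_kwargs.setdefault("seed", seed)
        return cls(
            generator=synthetic.GeneratorConfig(**gen_kwargs),
            priors=Priors(**pri_kwargs),
            **{k: v for k, v in top.items()
               if k in ("outcome", "n_iter", "n_burnin", "n_chains",
                        "thin", "seed")},
        )

    def to_yaml(self, path) -> None:
        flat: dict = {
            "outcome": self.outcome, "n_iter": self.n_iter,
            "n_burnin": self.n_burnin, "n_chains": self.n_chains,
            "thin": self.thin, "seed": self.seed,
        }
        for k, v in dataclasses.asdict(self.generator).items():
            if isinstance(v, np.ndarray):
                v = v.tolist()
            flat[f"generator_{k}"] = v
        for k, v in dataclasses.asdict(self.priors).items():
            if isinstance(v, np.ndarray):
                v = v.tolist()
            flat[f"prior_{k}"] = v
        with open(path, "w") as fh:
            yaml.safe_dump(flat, fh, sort_keys=True)


def write_csv(df: pd.DataFrame, path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_all(config: RunConfig, outdir) -> tuple[ValidationReport, pd.DataFrame]:
    """Execute every pipeline stage, writing all intermediates under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def stage(name):
        log.info("stage %s starting", name)
        return time.time()

    t = stage("simulate")
    gen = dataclasses.replace(config.generator, seed=seed)
    counties = synthetic.generate_counties(gen)
    truth = synthetic.counties_to_frame(counties)
    nhis = synthetic.sample_nhis(counties, gen)
    brfss = synthetic.sample_brfss(counties, gen)
    write_csv(truth, outdir / "counties.csv", seed)
    nhis.to_csv(outdir / "nhis.csv", seed=seed)
    brfss.to_csv(outdir / "brfss.csv", seed=seed)
    log.info("stage simulate done in %.1fs", time.time() - t)

    t = stage("direct")
    nhis_direct = direct_mod.direct_estimates(nhis)
    brfss_direct = direct_mod.direct_estimates(brfss)
    write_csv(nhis_direct, outdir / "nhis_direct.csv", seed)
    write_csv(brfss_direct, outdir / "brfss_direct.csv", seed)
    log.info("stage direct done in %.1fs", time.time() - t)

    t = stage("transform")
    level1 = assemble_level1(nhis_direct, brfss_direct)
    write_csv(level1.to_frame(), outdir / "level1.csv", seed)
    log.info("stage transform done in %.1fs (%d counties, %d excluded)",
             time.time() - t, len(level1), len(level1.excluded))

    t = stage("fit")
    xcols = [c for c in truth.columns if c.startswith("x")]
    cov = truth.set_index("county_id").loc[level1.county_ids, xcols]
    model = DualSurveySAE(level1, cov.to_numpy(), priors=config.priors)
    results = model.fit(n_iter=config.n_iter, n_burnin=config.n_burnin,
                        n_chains=config.n_chains, thin=config.thin, seed=seed)
    write_csv(results.summary(), outdir / "posterior_summary.csv", seed)
    write_csv(results.draws_frame(), outdir / "draws.csv", seed)
    log.info("stage fit done in %.1fs", time.time() - t)

    t = stage("compose")
    counts = compose_mod.phone_counts(nhis)
    comps = compose_mod.smooth_phone_composition(
        counts, truth[["county_id"] + xcols])
    phi_df = compose_mod.compositions_to_frame(comps)
    write_csv(phi_df, outdir / "phone_composition.csv", seed)
    saes = results.county_estimates(phi_df, outcome=config.outcome)
    release = saes.assign(
        estimate_pct=100 * saes["estimate"],
        ci_lower_pct=100 * saes["ci_lower"],
        ci_upper_pct=100 * saes["ci_upper"],
    )[["county_id", "outcome", "estimate_pct", "ci_lower_pct", "ci_upper_pct"]]
    write_csv(release, outdir / "saes.csv", seed)
    log.info("stage compose done in %.1fs", time.time() - t)

    t = stage("validate")
    lambda_hat = float(np.mean(results.lambda_draws))
    prev = results.modeled_prevalence()
    modeled_landline = pd.DataFrame({
        "county_id": prev["county_id"], "modeled": prev["mean"][:, 0]})
    funnel = funnel_ratios(brfss_direct, lambda_hat, modeled_landline)
    fbins = funnel_summary(funnel)
    pops = truth[["county_id", "population"]]
    agg = aggregate_national(saes, pops)
    nat = pd.DataFrame([{
        "outcome": config.outcome,
        "aggregated_sae": agg,
        "nhis_national_direct": float(
            nhis_direct.query("county_id == @direct_mod.NATIONAL_ID and stratum == 'all'")
            ["p_hat"].iloc[0]),
        "brfss_national_direct": float(
            brfss_direct.query("county_id == @direct_mod.NATIONAL_ID and stratum == 'all'")
            ["p_hat"].iloc[0]),
    }])
    summaries = summarize_counties(saes)
    report = ValidationReport(funnel=funnel, funnel_bins=fbins,
                              national_check=nat, summaries=summaries)
    write_csv(funnel, outdir / "funnel.csv", seed)
    write_csv(fbins, outdir / "funnel_bins.csv", seed)
    write_csv(nat, outdir / "national_check.csv", seed)
    write_csv(summaries, outdir / "county_summaries.csv", seed)
    log.info("stage validate done in %.1fs", time.time() - t)

    return report, saes
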