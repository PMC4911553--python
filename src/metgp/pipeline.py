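"""Config-driven pipeline: simulate/read → site analysis → FA → prediction.

A :class:`RunConfig` (YAML-loadable) names either input files or a simulation
block, the traits, models and schemes to run, and the MCMC settings.  One
master seed deterministically spawns per-stage seeds so a whole run is
reproducible end to end.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as metio
from .data import DataBundle
from .evaluate import SCHEMES, make_cv_plan, run_scheme, summarize_reports
from .kernels import MODEL_TERMS
from .mcmc import McmcSettings
from .multisite import biplot_coordinates, fit_factor_analytic, fit_single_site, genetic_correlations
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger("metgp")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = np.random.default_rng([master_seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(h.integers(2**31))


@dataclass
class RunConfig:
    output_dir: str = "results/run"
    seed: int = 0
    traits: list[str] = field(default_factory=lambda: ["grain_yield"])
    models: list[str] = field(default_factory=lambda: ["E+W+G", "E+W+G+A"])
    schemes: list[str] = field(default_factory=lambda: ["CV1"])
    n_replicates: int = 5
    test_fraction: float = 0.2
    inputs: Optional[dict] = None        # paths: phenotypes/markers/pedigree/covariables
    simulation: Optional[dict] = None    # SimConfig fields
    mcmc: dict = field(default_factory=dict)
    maf_filter: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.traits or not self.models or not self.schemes:
            raise ValueError("need at least one trait, model and scheme")
        bad = [m for m in self.models if m not in MODEL_TERMS]
        if bad:
            raise ValueError(f"unknown models {bad}; valid: {list(MODEL_TERMS)}")
        bad = [s for s in self.schemes if s not in SCHEMES]
        if bad:
            raise ValueError(f"unknown schemes {bad}; valid: {list(SCHEMES)}")
        if self.inputs is None and self.simulation is None:
            raise ValueError("config needs either an 'inputs' or a 'simulation' block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def mcmc_settings(self, seed: int) -> McmcSettings:
        kw = dict(self.mcmc)
        kw["seed"] = seed
        return McmcSettings(**kw)


def read_inputs(config: RunConfig, trait: Optional[str] = None) -> tuple[DataBundle, dict]:
    """Load and cross-validate the configured inputs (or simulate them)."""
    if config.inputs is not None:
        paths = config.inputs
        missing = [p for p in paths.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"configured input files not found: {missing}")
        bundle, report = metio.read_bundle(
            phenotypes=paths["phenotypes"],
            markers=paths.get("markers"),
            pedigree=paths.get("pedigree"),
            covariables=paths.get("covariables"),
            trait=trait,
            maf_filter=config.maf_filter,
        )
        if report.get("n_imputed"):
            log.info("mean-imputed %d missing marker codes", report["n_imputed"])
        return bundle, report
    sim_kw = dict(config.simulation or {})
    sim_kw.setdefault("seed", stage_seed(config.seed, "simulate"))
    sim = SimConfig(**sim_kw)
    bundle, truth = simulate_dataset(sim)
    return bundle, {"simulated": True, "truth": truth}


def _check_model_requirements(config: RunConfig, bundle: DataBundle) -> None:
    for m in config.models:
        terms = MODEL_TERMS[m]
        if ("G" in terms or "GE" in terms) and bundle.markers is None:
            raise ValueError(f"model '{m}' requires a marker file")
        if ("A" in terms or "AE" in terms) and bundle.pedigree is None:
            raise ValueError(f"model '{m}' requires a pedigree file")
        if "W" in terms and bundle.env_covariates is None:
            raise ValueError(f"model '{m}' requires a covariable file")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages for every trait; write tables under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        for trait in config.traits:
            t_start = time.time()
            stage = f"read-inputs[{trait}]"
            try:
                bundle, _ = read_inputs(config, trait=trait)
                _check_model_requirements(config, bundle)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            log.info("%s done in %.1fs (%d records)", stage, time.time() - t_start,
                     len(bundle.phenotypes))
            tdir = out / trait
            tdir.mkdir(exist_ok=True)

            stage = f"analyze-sites[{trait}]"
            t0 = time.time()
            try:
                site_rows = []
                for site in bundle.phenotypes.sites:
                    ss = fit_single_site(bundle.phenotypes, site)
                    site_rows.append({
                        "trait": trait, "site": site, "H2": ss.h2,
                        "sigma2_line": ss.variance_components["line"],
                        "sigma2_block": ss.variance_components["block"],
                        "sigma2_residual": ss.variance_components["residual"],
                        "mean_replication": ss.mean_replication, "n_obs": ss.n_obs,
                    })
                pd.DataFrame(site_rows).to_csv(tdir / "site_analysis.csv", index=False)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            log.info("%s done in %.1fs", stage, time.time() - t0)

            stage = f"factor-analytic[{trait}]"
            t0 = time.time()
            try:
                if bundle.markers is not None and len(bundle.phenotypes.sites) >= 3:
                    fa = fit_factor_analytic(bundle.phenotypes, bundle.markers,
                                             seed=stage_seed(config.seed, stage))
                    genetic_correlations(fa).to_csv(tdir / "genetic_correlations.csv")
                    site_xy, line_xy = biplot_coordinates(fa)
                    site_xy.to_csv(tdir / "biplot_sites.csv")
                    line_xy.to_csv(tdir / "biplot_lines.csv")
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            log.info("%s done in %.1fs", stage, time.time() - t0)

            reports = []
            for scheme in config.schemes:
                stage = f"predict[{trait},{scheme}]"
                t0 = time.time()
                try:
                    plan = make_cv_plan(
                        scheme, bundle.phenotypes, config.test_fraction,
                        n_replicates=config.n_replicates,
                        seed=stage_seed(config.seed, stage),
                    )
                    for model in config.models:
                        settings = config.mcmc_settings(
                            stage_seed(config.seed, f"{stage}:{model}"))
                        rep = run_scheme(model, bundle, plan, settings)
                        rep.correlations.to_csv(
                            tdir / f"accuracy_{scheme}_{model.replace('+', '')}.csv",
                            index=False)
                        reports.append(rep)
                except Exception as exc:
                    raise RuntimeError(f"stage {stage} failed: {exc}") from exc
                log.info("%s done in %.1fs", stage, time.time() - t0)

            if reports:
                tables = summarize_reports(reports)
                tables["long"].to_csv(tdir / "accuracy_summary.csv", index=False)
                for scheme, wide in tables["wide"].items():
                    wide.to_csv(tdir / f"accuracy_wide_{scheme}.csv")
                tables["scheme_averages"].to_csv(tdir / "scheme_averages.csv", index=False)
            log.info("trait %s finished in %.1fs", trait, time.time() - t_start)
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
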