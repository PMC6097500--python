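"""Configuration, CLI and end-to-end orchestration.

``run_pipeline`` executes prepare -> local scan -> selection -> effect
sizes -> population scan -> final fits -> carrying capacities -> impacts ->
sensitivity, writing every table plus the config, seed, filter report,
per-stage timings and (on failure) a machine-readable error manifest into
the run directory.
"""

from __future__ import annotations

import json
import sys
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_prep, impacts, model_selection, synthetic
from ._mcmc import MCMCConfig
from .local_model import LocalModelSpec, fit_local, r2_observational
from .model_selection import (
    fit_predictor_family,
    model_average,
    predictor_weights,
    scan_local_models,
    scan_population_models,
    scan_table,
    variable_importance,
)
from .population_model import PopModelSpec, carrying_capacity, fit_population

__all__ = ["RunConfig", "run_pipeline", "cli"]


@dataclass
class RunConfig:
    lek_counts: str = "lek_counts.csv"
    lek_sites: str = "lek_sites.csv"
    well_pads: str = "well_pads.csv"
    pdo_monthly: str = "pdo_monthly.csv"
    out_dir: str = "run"
    distances_km: tuple = (0.8, 1.6, 3.2, 6.4)
    area_lags: tuple = (1, 2, 3, 4)
    pdo_lags: tuple = (1, 2, 3, 4)
    window_start: tuple = (4, 1)
    window_end: tuple = (5, 7)
    unknown_frac: float = 0.05
    collapse_stat: str = "mean"
    start_year: int = 1985
    engine: str = "ml"  # "ml" or "bayes" (Bayesian final fits, ML scans)
    mcmc_chains: int = 3
    mcmc_iterations: int = 1000
    seed: int = 1
    sensitivity: bool = True

    def validate(self):
        if self.collapse_stat not in ("mean", "max"):
            raise ValueError(f"collapse_stat must be mean|max, got {self.collapse_stat!r}")
        if self.engine not in ("ml", "bayes"):
            raise ValueError(f"engine must be ml|bayes, got {self.engine!r}")
        if not 0 < self.unknown_frac <= 1:
            raise ValueError("unknown_frac must be in (0, 1]")
        for d in self.distances_km:
            if not 0.06 < d < 100:
                raise ValueError(f"distance {d} km out of plausible range")
        for lag in (*self.area_lags, *self.pdo_lags):
            if not 1 <= lag <= 4:
                raise ValueError(f"lag {lag} outside configured range 1-4")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("distances_km", "area_lags", "pdo_lags", "window_start", "window_end"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    @property
    def distances_m(self):
        return tuple(1000.0 * d for d in self.distances_km)

    @property
    def window(self):
        return data_prep.DateWindow(tuple(self.window_start), tuple(self.window_end))

    def mcmc_config(self, seed_offset=0):
        return MCMCConfig(
            n_chains=self.mcmc_chains,
            n_iter=self.mcmc_iterations,
            seed=self.seed + seed_offset,
        )


class _Log:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "run.log"
        self.timings = {}

    def stage(self, name):
        return _Stage(self, name)

    def write(self, msg):
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        print(line, file=sys.stderr)
        with open(self.path, "a") as fh:
            fh.write(line + "\n")


class _Stage:
    def __init__(self, log, name):
        self.log, self.name = log, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.log.write(f"stage {self.name}: start")
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.log.timings[self.name] = dt
        status = "FAILED" if exc_type else "done"
        self.log.write(f"stage {self.name}: {status} in {dt:.1f}s")
        return False


def _select_level(scan, extract):
    return variable_importance(scan, extract).iloc[0]["level"]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full two-scale analysis; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    log = _Log(out)
    try:
        return _run_pipeline(config, out, log)
    except Exception as exc:
        manifest = {
            "error": str(exc),
            "type": type(exc).__name__,
            "traceback": traceback.format_exc(),
            "timings": log.timings,
        }
        (out / "error.json").write_text(json.dumps(manifest, indent=2))
        raise


def _run_pipeline(config: RunConfig, out: Path, log: _Log) -> Path:
    with log.stage("prepare"):
        records = pd.read_csv(config.lek_counts)
        sites = pd.read_csv(config.lek_sites)
        pads = pd.read_csv(config.well_pads)
        monthly = pd.read_csv(config.pdo_monthly)

        filtered, report = data_prep.filter_records(
            records, window=config.window, unknown_frac=config.unknown_frac,
            start_year=config.start_year,
        )
        (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        lek_years = data_prep.collapse_counts(filtered, stat=config.collapse_stat)
        pdo_annual = data_prep.annualize_pdo(monthly)
        max_lag = max(max(config.area_lags), max(config.pdo_lags))
        years = range(
            int(lek_years["year"].min()) - max_lag, int(lek_years["year"].max()) + 1
        )
        disturbance = data_prep.disturbance_series(
            sites, pads, config.distances_m, years
        )
        gdist = data_prep.group_disturbance(disturbance, sites)
        densities = data_prep.group_density(lek_years)
        lek_years.to_csv(out / "lek_years.csv", index=False)
        disturbance.to_csv(out / "disturbance.csv", index=False)
        densities.to_csv(out / "group_density.csv", index=False)

    with log.stage("scan_local"):
        scan = scan_local_models(
            lek_years, disturbance, pdo_annual,
            distances_m=config.distances_m,
            area_lags=config.area_lags, pdo_lags=config.pdo_lags,
        )
        scan_table(scan).to_csv(out / "scan_local.csv", index=False)
        for name, extract in (
            ("importance_distance", lambda s: s.radius_m),
            ("importance_area_lag", lambda s: s.area_lag),
            ("importance_pdo_lag", lambda s: s.pdo_lag),
        ):
            variable_importance(scan, extract).to_csv(out / f"{name}.csv", index=False)
        local_spec = LocalModelSpec(
            radius_m=float(_select_level(scan, lambda s: s.radius_m)),
            area_lag=int(_select_level(scan, lambda s: s.area_lag)),
            pdo_lag=int(_select_level(scan, lambda s: s.pdo_lag)),
        )
        log.write(f"selected local spec: {local_spec.label()}")

    with log.stage("local_effects"):
        design, consts = data_prep.build_local_design(
            lek_years, disturbance, pdo_annual,
            local_spec.radius_m, local_spec.area_lag, local_spec.pdo_lag,
        )
        family = fit_predictor_family(local_spec, design, consts, family="local")
        weights = predictor_weights(family)
        full = family[(True, True)]
        r2_marg, r2_cond = r2_observational(full, design)
        eff_rows = []
        for pred, coef in (("area", "betaA"), ("pdo", "betaP")):
            b = getattr(full, coef)
            se = full.se(coef)
            e = model_selection.effect_size(b, b - 1.96 * se, b + 1.96 * se, pred)
            eff_rows.append({"predictor": pred, "engine": "ml", "averaged": False,
                             "percent": e.percent, "lower": e.lower, "upper": e.upper,
                             "weight": weights[pred]})
            avg = model_average(family, pred)
            eff_rows.append({"predictor": pred, "engine": "ml", "averaged": True,
                             "percent": avg.percent, "lower": avg.lower,
                             "upper": avg.upper, "weight": weights[pred]})
        local_bayes = None
        if config.engine == "bayes":
            local_bayes = fit_local(
                local_spec, design, engine="bayes",
                mcmc=config.mcmc_config(seed_offset=11), constants=consts,
            )
            for pred, coef in (("area", "betaA"), ("pdo", "betaP")):
                d = local_bayes.draws[coef]
                e = model_selection.effect_size(
                    float(np.median(d)), float(np.percentile(d, 2.5)),
                    float(np.percentile(d, 97.5)), pred,
                )
                eff_rows.append({"predictor": pred, "engine": "bayes",
                                 "averaged": False, "percent": e.percent,
                                 "lower": e.lower, "upper": e.upper,
                                 "weight": weights[pred]})
            local_bayes.draws.to_csv(out / "local_posterior.csv", index=False)
        eff = pd.DataFrame(eff_rows)
        eff["spec"] = local_spec.label()
        eff.to_csv(out / "effects_local.csv", index=False)
        (out / "fit_local.json").write_text(full.to_json())
        (out / "r2_local.json").write_text(
            json.dumps({"marginal": r2_marg, "conditional": r2_cond}, indent=2)
        )

    with log.stage("scan_population"):
        pscan = scan_population_models(
            densities, gdist, pdo_annual, local_spec.radius_m,
            area_lags=config.area_lags, pdo_lags=config.pdo_lags,
        )
        scan_table(pscan).to_csv(out / "scan_population.csv", index=False)
        variable_importance(pscan, lambda s: s.area_lag).to_csv(
            out / "importance_pop_area_lag.csv", index=False
        )
        variable_importance(pscan, lambda s: s.pdo_lag).to_csv(
            out / "importance_pop_pdo_lag.csv", index=False
        )
        pop_spec = PopModelSpec(
            radius_m=local_spec.radius_m,
            area_lag=int(_select_level(pscan, lambda s: s.area_lag)),
            pdo_lag=int(_select_level(pscan, lambda s: s.pdo_lag)),
        )
        log.write(f"selected population spec: {pop_spec.label()}")

    with log.stage("population_fit"):
        pdesign, pconsts = data_prep.build_pop_design(
            densities, gdist, pdo_annual,
            pop_spec.radius_m, pop_spec.area_lag, pop_spec.pdo_lag,
        )
        pfamily = fit_predictor_family(pop_spec, pdesign, pconsts, family="population")
        pweights = predictor_weights(pfamily)
        pop_full = pfamily[(True, True)]
        pop_bayes = None
        if config.engine == "bayes":
            pop_bayes = fit_population(
                pop_spec, pdesign, engine="bayes",
                mcmc=config.mcmc_config(seed_offset=23), constants=pconsts,
            )
            pop_bayes.draws.to_csv(out / "population_posterior.csv", index=False)
        peff_rows = []
        for pred, coef in (("area", "betaA"), ("pdo", "betaP")):
            b = getattr(pop_full, coef)
            se = pop_full.se(coef)
            e = model_selection.effect_size(b, b - 1.96 * se, b + 1.96 * se, pred)
            peff_rows.append({"predictor": pred, "engine": "ml", "averaged": False,
                              "percent": e.percent, "lower": e.lower,
                              "upper": e.upper, "weight": pweights[pred]})
            avg = model_average(pfamily, pred)
            peff_rows.append({"predictor": pred, "engine": "ml", "averaged": True,
                              "percent": avg.percent, "lower": avg.lower,
                              "upper": avg.upper, "weight": pweights[pred]})
        peff = pd.DataFrame(peff_rows)
        peff["spec"] = pop_spec.label()
        peff.to_csv(out / "effects_population.csv", index=False)
        (out / "fit_population.json").write_text(pop_full.to_json())

        cc_fit = pop_bayes if pop_bayes is not None else pop_full
        cc_rows = []
        for gid in [None, *cc_fit.group_slopes.index]:
            cc = carrying_capacity(cc_fit, 0.0, 0.0, group_id=gid)
            cc_rows.append({"group_id": "typical" if gid is None else gid,
                            "value": cc.value, "lower": cc.lower, "upper": cc.upper,
                            "spec": pop_spec.label()})
        pd.DataFrame(cc_rows).to_csv(out / "carrying_capacity.csv", index=False)

    with log.stage("impacts"):
        final_year = int(lek_years["year"].max())
        dist_sel = disturbance.loc[
            (disturbance["radius_m"] == local_spec.radius_m)
            & (disturbance["year"] == final_year)
        ].set_index("lek_id")["proportion"]
        group_of = sites.set_index("lek_id")["group_id"]
        lfit = local_bayes if local_bayes is not None else full
        pfit = pop_bayes if pop_bayes is not None else pop_full
        rows = []
        gdist_sel = gdist.loc[
            (gdist["radius_m"] == local_spec.radius_m) & (gdist["year"] == final_year)
        ].set_index("group_id")["proportion"]
        for gid in sorted(densities["group_id"].unique()):
            leks = group_of.index[group_of == gid]
            dl = dist_sel.reindex(leks).dropna()
            if len(dl):
                rows.append(impacts.local_population_impact(
                    lfit, dl, design=design if lfit.draws is not None else None,
                    group_id=gid, year=final_year,
                ))
            if gid in gdist_sel.index:
                rows.append(impacts.carrying_capacity_impact(
                    pfit, float(gdist_sel.loc[gid]), group_id=gid, year=final_year,
                ))
        impacts.impact_table(rows).to_csv(out / "impacts.csv", index=False)

    if config.sensitivity:
        with log.stage("sensitivity"):
            sens = impacts.sensitivity_suite(
                records, sites, pads, monthly, pop_spec,
                start_years=(config.start_year, 1997, 2005),
                reference=(config.collapse_stat, config.start_year),
                window=config.window, unknown_frac=config.unknown_frac,
            )
            impacts.sensitivity_table(sens).to_csv(out / "sensitivity.csv", index=False)

    (out / "timings.json").write_text(json.dumps(log.timings, indent=2))
    log.write("pipeline complete")
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

import click  # noqa: E402


@click.group()
def cli():
    """Two-scale lek-count and population-dynamics analysis."""


@cli.command()
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--groups", type=int, default=8, show_default=True)
@click.option("--leks-per-group", type=int, default=40, show_default=True)
@click.option("--years", type=int, default=32, show_default=True)
def simulate(seed, out_dir, groups, leks_per_group, years):
    """Write a synthetic toy study in the raw input formats."""
    synthetic.make_fixture(
        seed, out_dir, n_groups=groups, leks_per_group=leks_per_group, n_years=years
    )
    click.echo(f"fixture written to {out_dir}")


def _load_config(config_path, **overrides):
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, v)
    return cfg.validate()


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default=None)
@click.option("--engine", type=click.Choice(["ml", "bayes"]), default=None)
@click.option("--seed", type=int, default=None)
def run_all(config_path, out_dir, engine, seed):
    """Run the full pipeline from raw CSVs to impact tables."""
    cfg = _load_config(config_path, out_dir=out_dir, engine=engine, seed=seed)
    run_pipeline(cfg)
    click.echo(f"run complete: {cfg.out_dir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default=None)
def prepare(config_path, out_dir):
    """Data preparation only (filter, collapse, covariates, densities)."""
    cfg = _load_config(config_path, out_dir=out_dir, sensitivity=False)
    _partial(cfg, stop_after="prepare")
    click.echo(f"prepared tables in {cfg.out_dir}")


@cli.command("scan-local")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default=None)
def scan_local(config_path, out_dir):
    """Data prep plus the local distance x lag model scan."""
    cfg = _load_config(config_path, out_dir=out_dir, sensitivity=False)
    _partial(cfg, stop_after="scan_local")
    click.echo(f"local scan written in {cfg.out_dir}")


@cli.command("scan-pop")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default=None)
def scan_pop(config_path, out_dir):
    """Everything through the population lag scan."""
    cfg = _load_config(config_path, out_dir=out_dir, sensitivity=False)
    _partial(cfg, stop_after="scan_population")
    click.echo(f"population scan written in {cfg.out_dir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default=None)
@click.option("--engine", type=click.Choice(["ml", "bayes"]), default=None)
def fit(config_path, out_dir, engine):
    """Everything through the final model fits."""
    cfg = _load_config(config_path, out_dir=out_dir, engine=engine, sensitivity=False)
    _partial(cfg, stop_after="population_fit")
    click.echo(f"fits written in {cfg.out_dir}")


@cli.command("impacts")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default=None)
@click.option("--engine", type=click.Choice(["ml", "bayes"]), default=None)
def impacts_cmd(config_path, out_dir, engine):
    """Everything through the impact tables (no sensitivity suite)."""
    cfg = _load_config(config_path, out_dir=out_dir, engine=engine, sensitivity=False)
    run_pipeline(cfg)
    click.echo(f"impacts written in {cfg.out_dir}")


@cli.command("sensitivity")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default=None)
def sensitivity_cmd(config_path, out_dir):
    """Full pipeline including the sensitivity suite."""
    cfg = _load_config(config_path, out_dir=out_dir, sensitivity=True)
    run_pipeline(cfg)
    click.echo(f"sensitivity grid written in {cfg.out_dir}")


class _StopPipeline(Exception):
    pass


def _partial(config: RunConfig, stop_after: str):
    """Run the pipeline but stop (successfully) after a named stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out)
    orig_exit = _Stage.__exit__

    def patched_exit(self, exc_type, exc, tb):
        orig_exit(self, exc_type, exc, tb)
        if exc_type is None and self.name == stop_after:
            raise _StopPipeline
        return False

    _Stage.__exit__ = patched_exit
    try:
        _run_pipeline(config, out, log)
    except _StopPipeline:
        (out / "timings.json").write_text(json.dumps(log.timings, indent=2))
    finally:
        _Stage.__exit__ = orig_exit
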