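"""Propagate fitted effects into population-level impact estimates.

Two bases: the percent change in the summed expected lek counts of a
working group (local model), and the percent change in the group's
carrying capacity (population model), each comparing observed disturbance
against the raw-zero counterfactual.  "No disturbance" always means raw
AREA = 0, standardized with the fitted constants — not standardized 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import data_prep
from .local_model import LocalFit, conditional_ranef
from .model_selection import effect_size
from .population_model import PopFit, PopModelSpec, fit_population

__all__ = [
    "ImpactEstimate",
    "SensitivityResult",
    "local_population_impact",
    "carrying_capacity_impact",
    "sensitivity_suite",
]


@dataclass
class ImpactEstimate:
    group_id: object
    basis: str  # "local_sum" | "carrying_capacity"
    percent: float
    lower: float = np.nan
    upper: float = np.nan
    year: object = None


@dataclass
class SensitivityResult:
    stat: str
    start_year: int
    effects: dict = field(default_factory=dict)  # predictor -> EffectSize
    sd_adjustment: dict = field(default_factory=dict)
    failed: bool = False
    error: str = ""


def _std_area(fit, raw):
    if fit.constants is None or "area" not in fit.constants:
        raise ValueError("fit carries no standardization constants")
    return fit.constants["area"].apply(raw)


def local_population_impact(
    fit: LocalFit,
    lek_disturbance_raw: pd.Series,
    pdo_std: float = 0.0,
    year_effect: float = 0.0,
    design: pd.DataFrame | None = None,
    group_id=None,
    year=None,
    level: float = 0.95,
) -> ImpactEstimate:
    """Percent change in the summed expected counts of a set of leks under
    their observed disturbance versus none.

    ``lek_disturbance_raw`` maps lek_id to the raw (proportion) disturbance
    in the evaluation year.  Lek identity is preserved through each lek's
    conditional mode (ML) or per-draw conditional modes (Bayes, requires
    ``design``); the interval comes from the posterior draws.
    """
    leks = lek_disturbance_raw.index.to_numpy()
    raw = lek_disturbance_raw.to_numpy(dtype=float)
    a_obs = _std_area(fit, raw)
    a_zero = _std_area(fit, np.zeros_like(raw))

    def pct(betaA, beta0, betaP, lek_eff):
        base = beta0 + betaP * pdo_std + year_effect + lek_eff
        s_obs = np.sum(np.exp(base + betaA * a_obs))
        s_zero = np.sum(np.exp(base + betaA * a_zero))
        return 100.0 * (s_obs - s_zero) / s_zero

    modes = fit.ranef_modes["lek"].reindex(leks).fillna(0.0).to_numpy()
    point = pct(fit.betaA, fit.beta0, fit.betaP, modes)
    lower = upper = np.nan
    if fit.draws is not None:
        vals = []
        u0 = None
        for _, row in fit.draws.iterrows():
            params = {
                "beta0": row["beta0"],
                "betaA": row.get("betaA", 0.0),
                "betaP": row.get("betaP", 0.0),
                "sigmaL": row["sigmaL"],
                "sigmaY": row["sigmaY"],
                "phi": row["phi"],
            }
            if design is not None:
                ranef = conditional_ranef(params, design, u0=u0)
                lek_eff = ranef["lek"].reindex(leks).fillna(0.0).to_numpy()
            else:
                lek_eff = modes
            vals.append(
                pct(params["betaA"], params["beta0"], params["betaP"], lek_eff)
            )
        q = 100 * (1 - level) / 2
        point = float(np.median(vals))
        lower = float(np.percentile(vals, q))
        upper = float(np.percentile(vals, 100 - q))
    return ImpactEstimate(
        group_id=group_id, basis="local_sum", percent=float(point),
        lower=lower, upper=upper, year=year,
    )


def carrying_capacity_impact(
    fit: PopFit,
    group_area_raw: float,
    pdo_std: float = 0.0,
    group_id=None,
    year=None,
    level: float = 0.95,
) -> ImpactEstimate:
    """Percent change in a group's carrying capacity under observed versus
    zero disturbance:  ``100 * (exp(-betaA * dA / (betaD + alphaG)) - 1)``
    where ``dA`` is the standardized-scale difference from raw zero."""
    a_obs = _std_area(fit, group_area_raw)
    a_zero = _std_area(fit, 0.0)
    delta = float(a_obs - a_zero)
    alpha_g = 0.0
    if group_id is not None and fit.group_slopes is not None:
        if group_id in fit.group_slopes.index:
            alpha_g = float(fit.group_slopes.loc[group_id])
    denom = fit.betaD + alpha_g
    if denom == 0:
        raise ZeroDivisionError("betaD + alphaG = 0: carrying capacity undefined")
    point = 100.0 * float(np.expm1(-fit.betaA * delta / denom))
    lower = upper = np.nan
    if fit.draws is not None:
        d = fit.draws
        betaA = d["betaA"] if "betaA" in d else pd.Series(0.0, index=d.index)
        vals = 100.0 * np.expm1(-betaA * delta / (d["betaD"] + alpha_g))
        q = 100 * (1 - level) / 2
        point = float(np.median(vals))
        lower = float(np.percentile(vals, q))
        upper = float(np.percentile(vals, 100 - q))
    return ImpactEstimate(
        group_id=group_id, basis="carrying_capacity", percent=point,
        lower=lower, upper=upper, year=year,
    )


def sensitivity_suite(
    raw_records: pd.DataFrame,
    sites: pd.DataFrame,
    pads: pd.DataFrame,
    pdo_monthly: pd.DataFrame,
    spec: PopModelSpec,
    stats_=("mean", "max"),
    start_years=(1985, 1997, 2005),
    reference=("mean", 1985),
    window: data_prep.DateWindow = data_prep.DateWindow(),
    unknown_frac: float = 0.05,
) -> list[SensitivityResult]:
    """Re-run prepare -> population fit -> effect sizes for each variant of
    {collapse stat} x {start year}.

    Each variant's per-SD effect is rescaled to the reference variant's
    predictor scale (multiplied by reference-SD / variant-SD) so effects
    are comparable; the factors are reported in ``sd_adjustment``.
    A variant that cannot be fitted is reported as failed and the suite
    continues.
    """
    pdo_annual = data_prep.annualize_pdo(pdo_monthly)
    years = _coverage_years(raw_records, spec)
    dist = data_prep.disturbance_series(sites, pads, (spec.radius_m,), years)
    gdist = data_prep.group_disturbance(dist, sites)

    ref_consts = None
    results = []
    variants = [(s, y) for s in stats_ for y in start_years]
    # make sure the reference variant is computed first
    variants.sort(key=lambda v: v != tuple(reference))
    for stat, start_year in variants:
        try:
            filtered, _ = data_prep.filter_records(
                raw_records, window=window, unknown_frac=unknown_frac,
                start_year=start_year,
            )
            lek_years = data_prep.collapse_counts(filtered, stat=stat)
            densities = data_prep.group_density(lek_years)
            design, consts = data_prep.build_pop_design(
                densities, gdist, pdo_annual, spec.radius_m,
                spec.area_lag, spec.pdo_lag,
            )
            fit = fit_population(spec, design, engine="ml", constants=consts)
            if (stat, start_year) == tuple(reference):
                ref_consts = consts
            adj = {}
            effects = {}
            for pred, coef in (("area", "betaA"), ("pdo", "betaP")):
                factor = 1.0
                if ref_consts is not None:
                    factor = ref_consts[pred].sd / consts[pred].sd
                adj[pred] = factor
                b = getattr(fit, coef) * factor
                se = fit.se(coef) * factor
                effects[pred] = effect_size(
                    b, b - 1.959963984540054 * se, b + 1.959963984540054 * se,
                    predictor=pred,
                )
            results.append(
                SensitivityResult(
                    stat=stat, start_year=start_year,
                    effects=effects, sd_adjustment=adj,
                )
            )
        except (ValueError, RuntimeError, ZeroDivisionError) as exc:
            warnings.warn(f"sensitivity variant ({stat}, {start_year}) failed: {exc}",
                          stacklevel=2)
            results.append(
                SensitivityResult(stat=stat, start_year=start_year,
                                  failed=True, error=str(exc))
            )
    return results


def _coverage_years(raw_records: pd.DataFrame, spec) -> range:
    parsed = pd.to_datetime(raw_records["date"], errors="coerce", format="ISO8601")
    years = parsed.dt.year.dropna().astype(int)
    return range(int(years.min()) - max(spec.area_lag, 4), int(years.max()) + 1)


def impact_table(impacts: list[ImpactEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": i.group_id, "basis": i.basis, "year": i.year,
                "percent": i.percent, "lower": i.lower, "upper": i.upper,
            }
            for i in impacts
        ]
    )


def sensitivity_table(results: list[SensitivityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.failed:
            rows.append({"stat": r.stat, "start_year": r.start_year,
                         "failed": True, "error": r.error})
            continue
        for pred, e in r.effects.items():
            rows.append(
                {
                    "stat": r.stat, "start_year": r.start_year, "failed": False,
                    "predictor": pred, "percent": e.percent,
                    "lower": e.lower, "upper": e.upper,
                    "sd_adjustment": r.sd_adjustment[pred],
                }
            )
    return pd.DataFrame(rows)
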