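"""AICc, Akaike weights, scale/lag scans, variable importance, effect sizes
and model averaging."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import data_prep
from .local_model import LocalFit, LocalModelSpec, fit_local
from .population_model import PopFit, PopModelSpec, fit_population

__all__ = [
    "ModelScanResult",
    "EffectSize",
    "aicc",
    "akaike_weights",
    "scan_local_models",
    "scan_population_models",
    "variable_importance",
    "predictor_weights",
    "effect_size",
    "model_average",
    "fit_predictor_family",
]


@dataclass
class ModelScanResult:
    spec: object  # LocalModelSpec | PopModelSpec
    loglik: float
    n_params: int
    n_obs: int
    aicc: float
    weight: float = np.nan
    fit: object = None


@dataclass
class EffectSize:
    """Percent change in the expected response per +1 SD of a predictor."""

    predictor: str
    percent: float
    lower: float = np.nan
    upper: float = np.nan
    averaged: bool = False


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    ``k`` counts every estimated parameter (fixed effects, variance
    components, overdispersion).  Requires ``n > k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(values: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) weights normalized over the model set."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one criterion value")
    if not np.all(np.isfinite(v)):
        raise ValueError("criterion values must be finite")
    delta = v - v.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _finish_scan(results: list[ModelScanResult]) -> list[ModelScanResult]:
    w = akaike_weights([r.aicc for r in results])
    for r, wi in zip(results, w):
        r.weight = float(wi)
    return results


def scan_local_models(
    lek_years: pd.DataFrame,
    disturbance: pd.DataFrame,
    pdo_annual: pd.DataFrame,
    distances_m: Sequence[float] = data_prep.DEFAULT_RADII_M,
    area_lags: Sequence[int] = (1, 2, 3, 4),
    pdo_lags: Sequence[int] = (1, 2, 3, 4),
    keep_fits: bool = False,
) -> list[ModelScanResult]:
    """Fit the full distances x area-lags x PDO-lags grid by ML.

    All models are fit on the common rows available under the maximum lags
    so their AICc values are comparable.  Any non-converged member aborts
    the scan with its spec named.
    """
    common = _common_local_keys(lek_years, disturbance, pdo_annual, distances_m,
                                max(area_lags), max(pdo_lags))
    results = []
    for radius in distances_m:
        for alag in area_lags:
            for plag in pdo_lags:
                spec = LocalModelSpec(radius_m=radius, area_lag=alag, pdo_lag=plag)
                design, consts = data_prep.build_local_design(
                    lek_years, disturbance, pdo_annual, radius, alag, plag,
                    restrict_keys=common,
                )
                try:
                    fit = fit_local(spec, design, engine="ml", compute_vcov=False,
                                    constants=consts)
                except RuntimeError as exc:
                    raise RuntimeError(f"scan member {spec.label()} failed: {exc}")
                results.append(
                    ModelScanResult(
                        spec=spec, loglik=fit.loglik, n_params=fit.n_params,
                        n_obs=fit.n_obs,
                        aicc=aicc(fit.loglik, fit.n_params, fit.n_obs),
                        fit=fit if keep_fits else None,
                    )
                )
    return _finish_scan(results)


def _common_local_keys(lek_years, disturbance, pdo_annual, distances_m,
                       max_area_lag, max_pdo_lag):
    """Row keys (lek_id, year) available under the most restrictive lags at
    every distance."""
    common = None
    for radius in distances_m:
        design, _ = data_prep.build_local_design(
            lek_years, disturbance, pdo_annual, radius, max_area_lag, max_pdo_lag
        )
        keys = set(zip(design["lek_id"], design["year"]))
        common = keys if common is None else (common & keys)
    return common


def scan_population_models(
    densities: pd.DataFrame,
    group_dist: pd.DataFrame,
    pdo_annual: pd.DataFrame,
    radius_m: float,
    area_lags: Sequence[int] = (1, 2, 3, 4),
    pdo_lags: Sequence[int] = (1, 2, 3, 4),
    keep_fits: bool = False,
) -> list[ModelScanResult]:
    """Fit the area-lag x PDO-lag grid at the fixed (locally selected)
    spatial scale, on common transitions."""
    design_max, _ = data_prep.build_pop_design(
        densities, group_dist, pdo_annual, radius_m, max(area_lags), max(pdo_lags)
    )
    common = set(zip(design_max["group_id"], design_max["year"]))
    results = []
    for alag in area_lags:
        for plag in pdo_lags:
            spec = PopModelSpec(radius_m=radius_m, area_lag=alag, pdo_lag=plag)
            design, consts = data_prep.build_pop_design(
                densities, group_dist, pdo_annual, radius_m, alag, plag,
                restrict_keys=common,
            )
            try:
                fit = fit_population(spec, design, engine="ml", compute_vcov=False,
                                     constants=consts)
            except RuntimeError as exc:
                raise RuntimeError(f"scan member {spec.label()} failed: {exc}")
            results.append(
                ModelScanResult(
                    spec=spec, loglik=fit.loglik, n_params=fit.n_params,
                    n_obs=fit.n_obs,
                    aicc=aicc(fit.loglik, fit.n_params, fit.n_obs),
                    fit=fit if keep_fits else None,
                )
            )
    return _finish_scan(results)


def variable_importance(
    scan: list[ModelScanResult], level_of: Callable[[object], object]
) -> pd.DataFrame:
    """Summed Akaike weight per level of a model attribute.

    ``level_of`` maps a spec to its level (e.g. ``lambda s: s.radius_m``).
    The levels must partition the scan.  Returns a table with columns
    ``level``, ``n_models``, ``proportion``, ``weight`` sorted by weight.
    """
    rows = {}
    for r in scan:
        lvl = level_of(r.spec)
        rows.setdefault(lvl, [0, 0.0])
        rows[lvl][0] += 1
        rows[lvl][1] += r.weight
    n_total = sum(v[0] for v in rows.values())
    if n_total != len(scan):
        raise ValueError("levels do not partition the scan")
    df = pd.DataFrame(
        [
            {"level": lvl, "n_models": n, "proportion": n / n_total, "weight": w}
            for lvl, (n, w) in rows.items()
        ]
    )
    return df.sort_values("weight", ascending=False).reset_index(drop=True)


def fit_predictor_family(spec, design, constants, family: str = "local",
                         engine: str = "ml"):
    """Fit the full model and its three reduced variants (area-only,
    pdo-only, neither) on identical rows.  Returns a dict keyed by
    (include_area, include_pdo)."""
    fits = {}
    for inc_a in (True, False):
        for inc_p in (True, False):
            s = type(spec)(
                radius_m=spec.radius_m, area_lag=spec.area_lag,
                pdo_lag=spec.pdo_lag, include_area=inc_a, include_pdo=inc_p,
            )
            if family == "local":
                fits[(inc_a, inc_p)] = fit_local(s, design, engine=engine,
                                                 constants=constants)
            else:
                fits[(inc_a, inc_p)] = fit_population(s, design, engine=engine,
                                                      constants=constants)
    return fits


def predictor_weights(fits: dict) -> dict:
    """Akaike weight of each predictor over the four-model family.

    ``fits`` maps (include_area, include_pdo) to fitted models; the weight
    of a predictor is the summed weight of the two models containing it.
    """
    if set(fits) != {(True, True), (True, False), (False, True), (False, False)}:
        raise ValueError("family must be the four include_area x include_pdo models")
    keys = list(fits)
    vals = [aicc(fits[k].loglik, fits[k].n_params, fits[k].n_obs) for k in keys]
    w = akaike_weights(vals)
    by_key = dict(zip(keys, w))
    return {
        "area": float(sum(v for k, v in by_key.items() if k[0])),
        "pdo": float(sum(v for k, v in by_key.items() if k[1])),
        "model_weights": {k: float(v) for k, v in by_key.items()},
    }


def effect_size(beta: float, lower: float = np.nan, upper: float = np.nan,
                predictor: str = "", averaged: bool = False) -> EffectSize:
    """Percent change per +1 SD: ``100 * (exp(beta) - 1)``, interval
    endpoints transformed the same way."""
    return EffectSize(
        predictor=predictor,
        percent=100.0 * float(np.expm1(beta)),
        lower=100.0 * float(np.expm1(lower)),
        upper=100.0 * float(np.expm1(upper)),
        averaged=averaged,
    )


def model_average(fits: dict, predictor: str, level: float = 0.95) -> EffectSize:
    """Full-family model-averaged effect size for one predictor.

    Coefficients are averaged on the log scale over all four models with 0
    substituted where the predictor is absent; the unconditional variance
    follows the standard model-averaging formula
    ``(sum_i w_i * sqrt(var_i + (b_i - b_bar)^2))^2``.
    """
    pw = predictor_weights(fits)
    weights = pw["model_weights"]
    coef_name = {"area": "betaA", "pdo": "betaP"}[predictor]
    betas, variances, ws = [], [], []
    for key, w in weights.items():
        fit = fits[key]
        present = key[0] if predictor == "area" else key[1]
        if present:
            betas.append(getattr(fit, coef_name))
            if fit.draws is not None:
                variances.append(float(np.var(fit.draws[coef_name], ddof=1)))
            elif fit.vcov is not None:
                variances.append(fit.se(coef_name) ** 2)
            else:
                variances.append(0.0)
        else:
            betas.append(0.0)
            variances.append(0.0)
        ws.append(w)
    betas, variances, ws = map(np.asarray, (betas, variances, ws))
    b_bar = float(np.sum(ws * betas))
    se_bar = float(np.sum(ws * np.sqrt(variances + (betas - b_bar) ** 2)))
    z = stats.norm.ppf(0.5 + level / 2)
    return effect_size(
        b_bar, b_bar - z * se_bar, b_bar + z * se_bar,
        predictor=predictor, averaged=True,
    )


def scan_table(scan: list[ModelScanResult]) -> pd.DataFrame:
    """Flat table of a scan for CSV export."""
    rows = []
    for r in scan:
        s = r.spec
        rows.append(
            {
                "radius_m": s.radius_m,
                "area_lag": s.area_lag,
                "pdo_lag": s.pdo_lag,
                "include_area": s.include_area,
                "include_pdo": s.include_pdo,
                "loglik": r.loglik,
                "n_params": r.n_params,
                "n_obs": r.n_obs,
                "aicc": r.aicc,
                "weight": r.weight,
            }
        )
    return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
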