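"""Seed-reproducible synthetic datasets with the statistical structure the
analysis assumes.

Covariate series, lek-count panels and group density series can be drawn
directly (returning the simulation truth for recovery tests), and
:func:`make_fixture` writes a complete toy study in the CSV dialects
consumed by :mod:`lekscale.data_prep`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_prep

__all__ = [
    "LocalSimParams",
    "PopSimParams",
    "CovariateSimParams",
    "simulate_covariates",
    "simulate_lek_counts",
    "simulate_population_series",
    "simulate_local_study",
    "make_fixture",
]

START_YEAR = 1985


@dataclass
class LocalSimParams:
    n_leks: int = 100
    n_years: int = 32
    beta0: float = np.log(10.0)  # typical lek of ~10 males
    betaA: float = -0.2
    betaP: float = 0.15
    sigmaL: float = 0.7
    sigmaY: float = 0.2
    phi: float = 0.2
    seed: int = 1

    def __post_init__(self):
        if self.sigmaL < 0 or self.sigmaY < 0 or self.phi < 0:
            raise ValueError("sigmaL, sigmaY and phi must be >= 0")


@dataclass
class PopSimParams:
    n_groups: int = 8
    n_years: int = 32
    beta0: float = 0.38 * np.log(20.0)  # carrying capacity ~20 males/lek
    betaD: float = -0.38
    betaA: float = -0.05
    betaP: float = 0.08
    betaN: float = np.log(0.25)
    betaL: float = -0.1
    sigmaG: float = 0.03
    sigmaY: float = 0.1
    leks_per_group: tuple[int, int] = (10, 60)
    seed: int = 1

    def __post_init__(self):
        if self.sigmaG < 0 or self.sigmaY < 0:
            raise ValueError("sigmaG and sigmaY must be >= 0")
        if not -2 < self.betaD < 0:
            raise ValueError("betaD must lie in (-2, 0) for stationary dynamics")


@dataclass
class CovariateSimParams:
    pdo_rho: float = 0.5
    pdo_sd: float = 0.8
    n_pads_final: float = 20.0  # mean per-lek pad budget
    buildout_years: int = 20
    seed: int = 1

    def __post_init__(self):
        if not abs(self.pdo_rho) < 1:
            raise ValueError("|pdo_rho| must be < 1")
        if self.pdo_sd <= 0:
            raise ValueError("pdo_sd must be > 0")


def _simulate_pdo(rng, n_years, rho, sd, start_year=START_YEAR):
    x = np.empty(n_years)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_years):
        x[t] = rho * x[t - 1] + rng.normal(0.0, innov_sd)
    years = np.arange(start_year, start_year + n_years)
    return pd.DataFrame({"year": years, "value": x})


def _pad_budgets(rng, n_leks, mean_final):
    """Right-skewed per-lek pad totals: many near zero, a few large."""
    if mean_final <= 0:
        return np.zeros(n_leks, dtype=int)
    lam = rng.gamma(shape=0.5, scale=mean_final / 0.5, size=n_leks)
    return rng.poisson(lam)


def simulate_covariates(
    params: CovariateSimParams,
    n_leks: int,
    n_years: int,
    radius_m: float = 3200.0,
    start_year: int = START_YEAR,
):
    """Draw a stationary AR(1) climate index and per-lek disturbance
    trajectories (zero before buildout, then monotone non-decreasing,
    right-skewed across leks).  Identical seeds give identical output."""
    rng = np.random.default_rng(params.seed)
    pdo = _simulate_pdo(rng, n_years, params.pdo_rho, params.pdo_sd, start_year)

    years = np.arange(start_year, start_year + n_years)
    frac = (data_prep.PAD_RADIUS_M / radius_m) ** 2
    budgets = _pad_budgets(rng, n_leks, params.n_pads_final)
    rows = []
    for i in range(n_leks):
        start = rng.integers(0, max(1, n_years - params.buildout_years + 1))
        n_pads = budgets[i]
        if n_pads > 0:
            arrivals = np.sort(
                rng.integers(start, min(start + params.buildout_years, n_years),
                             size=n_pads)
            )
            counts = np.searchsorted(arrivals, np.arange(n_years), side="right")
        else:
            counts = np.zeros(n_years, dtype=int)
        rows.append(
            pd.DataFrame(
                {
                    "lek_id": f"L{i:04d}",
                    "year": years,
                    "radius_m": radius_m,
                    "proportion": np.minimum(1.0, counts * frac),
                }
            )
        )
    return pdo, pd.concat(rows, ignore_index=True)


def _draw_negbin(rng, mu, phi):
    """Gamma-Poisson mixture with gamma shape 1/phi: variance mu+phi*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def _standardize(x):
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x), float(np.mean(x)), 0.0
    return (x - np.mean(x)) / sd, float(np.mean(x)), float(sd)


def simulate_lek_counts(
    params: LocalSimParams, disturbance: pd.DataFrame, pdo: pd.DataFrame
):
    """Draw a lek-count panel from the lek-count model.

    Covariates are standardized over the panel rows before the fixed
    effects apply (so ``betaA``/``betaP`` are per-SD effects).  Returns the
    lek-year table and a truth dict with the random effects and
    standardization constants.
    """
    rng = np.random.default_rng(params.seed)
    lek_ids = np.array(sorted(disturbance["lek_id"].unique()))[: params.n_leks]
    if len(lek_ids) < params.n_leks:
        raise ValueError("disturbance does not cover n_leks leks")
    years = np.sort(pdo["year"].unique())[: params.n_years]
    if len(years) < params.n_years:
        raise ValueError("pdo does not cover n_years years")

    alpha_l = rng.normal(0.0, params.sigmaL, size=len(lek_ids))
    alpha_y = rng.normal(0.0, params.sigmaY, size=len(years))

    dist = disturbance.set_index(["lek_id", "year"])["proportion"]
    pdo_map = pdo.set_index("year")["value"]
    grid = pd.MultiIndex.from_product([lek_ids, years], names=["lek_id", "year"])
    area_raw = dist.reindex(grid).to_numpy()
    pdo_raw = pdo_map.reindex(grid.get_level_values("year")).to_numpy()
    if np.isnan(area_raw).any():
        raise ValueError("disturbance does not cover all lek-years")

    area_std, a_mean, a_sd = _standardize(area_raw)
    pdo_std, p_mean, p_sd = _standardize(pdo_raw)
    lek_pos = grid.get_level_values("lek_id").map(
        {l: j for j, l in enumerate(lek_ids)}
    )
    year_pos = grid.get_level_values("year").map({y: j for j, y in enumerate(years)})
    log_mu = (
        params.beta0
        + params.betaA * area_std
        + params.betaP * pdo_std
        + alpha_l[lek_pos]
        + alpha_y[year_pos]
    )
    counts = _draw_negbin(rng, np.exp(log_mu), params.phi)
    lek_years = pd.DataFrame(
        {
            "lek_id": grid.get_level_values("lek_id"),
            "group_id": "G1",
            "year": grid.get_level_values("year"),
            "count": counts,
            "n_repeats": 1,
            "area_raw": area_raw,
            "pdo_raw": pdo_raw,
        }
    )
    truth = {
        "params": asdict(params),
        "alpha_lek": dict(zip(lek_ids, alpha_l)),
        "alpha_year": dict(zip(map(int, years), alpha_y)),
        "area_standardization": {"mean": a_mean, "sd": a_sd},
        "pdo_standardization": {"mean": p_mean, "sd": p_sd},
    }
    return lek_years, truth


def simulate_population_series(
    params: PopSimParams,
    group_dist: pd.DataFrame | None,
    pdo: pd.DataFrame,
    init_density: np.ndarray | None = None,
):
    """Iterate the Gompertz map forward with process noise.

    ``group_dist`` (group_id, year, proportion) may be None for a
    no-disturbance world.  Returns the density table and a truth dict.
    """
    rng = np.random.default_rng(params.seed)
    years = np.sort(pdo["year"].unique())[: params.n_years]
    groups = [f"G{g + 1}" for g in range(params.n_groups)]

    alpha_g = rng.normal(0.0, params.sigmaG, size=len(groups))
    if np.any(params.betaD + alpha_g >= 0) or np.any(params.betaD + alpha_g <= -2):
        alpha_g = np.clip(alpha_g, -1.99 - params.betaD, -1e-3 - params.betaD)
    alpha_y = rng.normal(0.0, params.sigmaY, size=len(years))

    lo, hi = params.leks_per_group
    n_leks = rng.integers(lo, hi + 1, size=(len(groups), len(years)))

    if group_dist is not None:
        gd = group_dist.set_index(["group_id", "year"])["proportion"]
        area_raw = np.array(
            [[gd.get((g, y), 0.0) for y in years] for g in groups], dtype=float
        )
        flat, a_mean, a_sd = _standardize(area_raw.ravel())
        area_std = flat.reshape(area_raw.shape)
    else:
        area_raw = np.zeros((len(groups), len(years)))
        area_std = area_raw
        a_mean, a_sd = 0.0, 0.0
    pdo_std, p_mean, p_sd = _standardize(
        pdo.set_index("year")["value"].reindex(years).to_numpy()
    )

    k_typical = np.exp(-params.beta0 / params.betaD)
    log_d = np.empty((len(groups), len(years)))
    if init_density is None:
        init_density = k_typical * np.exp(rng.normal(0.0, 0.2, size=len(groups)))
    log_d[:, 0] = np.log(init_density)
    for t in range(1, len(years)):
        sd_eta = np.exp(params.betaN + params.betaL * np.log(n_leks[:, t]))
        log_mu = (
            params.beta0
            + (params.betaD + 1.0 + alpha_g) * log_d[:, t - 1]
            + params.betaA * area_std[:, t]
            + params.betaP * pdo_std[t]
            + alpha_y[t]
        )
        noise = rng.normal(0.0, 1.0, size=len(groups)) * sd_eta
        log_d[:, t] = log_mu + noise

    rows = []
    for gi, g in enumerate(groups):
        rows.append(
            pd.DataFrame(
                {
                    "group_id": g,
                    "year": years,
                    "density": np.exp(log_d[gi]),
                    "n_leks": n_leks[gi],
                }
            )
        )
    densities = pd.concat(rows, ignore_index=True)
    truth = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
        "alpha_group": dict(zip(groups, alpha_g)),
        "alpha_year": dict(zip(map(int, years), alpha_y)),
        "carrying_capacity": {
            g: float(np.exp(-params.beta0 / (params.betaD + a)))
            for g, a in zip(groups, alpha_g)
        },
        "area_standardization": {"mean": a_mean, "sd": a_sd},
        "pdo_standardization": {"mean": p_mean, "sd": p_sd},
    }
    return densities, truth


# ---------------------------------------------------------------------------
# Spatially explicit study generator
# ---------------------------------------------------------------------------

def _spatial_study(
    rng,
    n_groups,
    leks_per_group,
    n_years,
    mean_pads,
    buildout_years,
    pad_spread_m=6400.0,
    start_year=START_YEAR,
):
    """Lek sites on a sparse grid of group neighbourhoods plus well pads
    scattered in discs around leks, with staggered spud years."""
    sites, pads = [], []
    pad_counter = 0
    for g in range(n_groups):
        gx, gy = (g % 4) * 150_000.0, (g // 4) * 150_000.0
        for i in range(leks_per_group):
            lek_id = f"G{g + 1}L{i:03d}"
            x = gx + rng.uniform(0, 40_000.0)
            y = gy + rng.uniform(0, 40_000.0)
            sites.append(
                {"lek_id": lek_id, "group_id": f"G{g + 1}", "x_m": x, "y_m": y}
            )
            n_pads = _pad_budgets(rng, 1, mean_pads)[0]
            if n_pads == 0:
                continue
            build_start = int(rng.integers(0, max(1, n_years - buildout_years + 1)))
            angles = rng.uniform(0, 2 * np.pi, n_pads)
            radii = pad_spread_m * np.sqrt(rng.uniform(0, 1, n_pads))
            spud = rng.integers(
                build_start, min(build_start + buildout_years, n_years), n_pads
            )
            for a, r, s in zip(angles, radii, spud):
                pads.append(
                    {
                        "pad_id": f"P{pad_counter:06d}",
                        "x_m": x + r * np.cos(a),
                        "y_m": y + r * np.sin(a),
                        "spud_year": start_year + int(s),
                    }
                )
                pad_counter += 1
    return pd.DataFrame(sites), pd.DataFrame(pads)


def simulate_local_study(
    seed: int,
    n_leks: int = 60,
    n_years: int = 25,
    betaA: float = -0.25,
    betaP: float = 0.15,
    sigmaL: float = 0.6,
    sigmaY: float = 0.15,
    phi: float = 0.15,
    mean_pads: float = 25.0,
    true_radius_m: float = 3200.0,
    area_lag: int = 1,
    pdo_lag: int = 1,
    start_year: int = START_YEAR,
):
    """Generate a spatially explicit lek-count study whose counts respond to
    the disturbance at one true radius and lag.

    Returns ``(lek_years, disturbance, pdo_annual, truth)`` where the
    disturbance table covers all default radii, so scale/lag scans can
    attempt to recover the true combination.
    """
    rng = np.random.default_rng(seed)
    leks_per_group = n_leks
    sites, pads = _spatial_study(
        rng, 1, leks_per_group, n_years, mean_pads, buildout_years=max(5, n_years - 8),
        start_year=start_year,
    )
    years = range(start_year, start_year + n_years)
    dist = data_prep.disturbance_series(sites, pads, data_prep.DEFAULT_RADII_M, years)
    pdo = _simulate_pdo(rng, n_years, rho=0.4, sd=0.8, start_year=start_year)

    dtrue = dist.loc[dist["radius_m"] == true_radius_m].set_index(["lek_id", "year"])[
        "proportion"
    ]
    pdo_map = pdo.set_index("year")["value"]
    lek_ids = sites["lek_id"].to_numpy()
    alpha_l = rng.normal(0, sigmaL, len(lek_ids))
    alpha_y = rng.normal(0, sigmaY, n_years)

    rows = []
    year_list = list(years)
    # covariates at the true lag, standardized over the response rows
    resp_years = year_list[max(area_lag, pdo_lag):]
    area_raw = np.array(
        [[dtrue.loc[(l, y - area_lag)] for y in resp_years] for l in lek_ids]
    )
    pdo_raw = np.array([pdo_map.loc[y - pdo_lag] for y in resp_years])
    a_std = (area_raw - area_raw.mean()) / area_raw.std(ddof=1)
    p_std = (pdo_raw - pdo_raw.mean()) / pdo_raw.std(ddof=1)
    beta0 = np.log(10.0)
    for li, lek in enumerate(lek_ids):
        log_mu = (
            beta0
            + betaA * a_std[li]
            + betaP * p_std
            + alpha_l[li]
            + alpha_y[max(area_lag, pdo_lag):]
        )
        counts = _draw_negbin(rng, np.exp(log_mu), phi)
        rows.append(
            pd.DataFrame(
                {
                    "lek_id": lek,
                    "group_id": "G1",
                    "year": resp_years,
                    "count": counts,
                    "n_repeats": 1,
                }
            )
        )
    lek_years = pd.concat(rows, ignore_index=True)
    truth = {
        "beta0": beta0, "betaA": betaA, "betaP": betaP,
        "sigmaL": sigmaL, "sigmaY": sigmaY, "phi": phi,
        "true_radius_m": true_radius_m, "area_lag": area_lag, "pdo_lag": pdo_lag,
    }
    return lek_years, dist, pdo, truth


def make_fixture(
    seed: int,
    out_dir: str | Path | None = None,
    n_groups: int = 8,
    leks_per_group: int = 40,
    n_years: int = 32,
    start_year: int = START_YEAR,
    betaD: float = -0.38,
    k_range: tuple[float, float] = (13.0, 35.0),
    halving_disturbance_pct: float = 3.0,
    mean_pads: float = 15.0,
):
    """Write a complete toy study in the raw CSV dialects.

    Group carrying capacities are spread over ``k_range``; density dynamics
    follow the Gompertz map with ``betaD``; lek counts scatter around the
    group density with a per-lek disturbance response calibrated so that
    ``halving_disturbance_pct`` percent disturbance at 3.2 km halves the
    expected count.  Returns a dict of DataFrames plus a manifest of the
    true parameters; identical seeds give identical files.
    """
    rng = np.random.default_rng(seed)
    sites, pads = _spatial_study(
        rng, n_groups, leks_per_group, n_years, mean_pads,
        buildout_years=max(5, n_years - 10), start_year=start_year,
    )
    years = list(range(start_year, start_year + n_years))
    # disturbance at 3.2 km drives the truth; data_prep recomputes it later
    dist = data_prep.disturbance_series(sites, pads, (3200.0,), years)
    gdist = data_prep.group_disturbance(dist, sites)

    pdo = _simulate_pdo(rng, n_years, rho=0.5, sd=0.8, start_year=start_year)
    monthly = pd.DataFrame(
        [
            {"year": y, "month": m, "value": v}
            for y, v in zip(pdo["year"], pdo["value"])
            for m in range(1, 13)
        ]
    )

    # group dynamics around spread-out carrying capacities
    k_g = np.exp(
        np.linspace(np.log(k_range[0]), np.log(k_range[1]), n_groups)
    )
    rng.shuffle(k_g)
    beta0 = -betaD * float(np.mean(np.log(k_g)))
    alpha_g = -beta0 / np.log(k_g) - betaD
    groups = [f"G{g + 1}" for g in range(n_groups)]

    gd = gdist.loc[gdist["radius_m"] == 3200.0].set_index(["group_id", "year"])[
        "proportion"
    ]
    area_g = np.array([[gd.get((g, y), 0.0) for y in years] for g in groups])
    a_flat, _, a_sd = _standardize(area_g.ravel())
    area_g_std = a_flat.reshape(area_g.shape) if a_sd > 0 else area_g * 0.0
    pdo_std, _, _ = _standardize(pdo["value"].to_numpy())

    betaP_pop, betaA_pop = 0.08, -0.04
    sigmaY_pop, sd_eta = 0.08, 0.12
    alpha_y = rng.normal(0, sigmaY_pop, n_years)
    log_d = np.empty((n_groups, n_years))
    log_d[:, 0] = np.log(k_g) + rng.normal(0, 0.15, n_groups)
    for t in range(1, n_years):
        log_mu = (
            beta0
            + (betaD + 1 + alpha_g) * log_d[:, t - 1]
            + betaA_pop * area_g_std[:, t]
            + betaP_pop * pdo_std[t]
            + alpha_y[t]
        )
        log_d[:, t] = log_mu + rng.normal(0, sd_eta, n_groups)

    # lek counts scatter around the group density; disturbance deviation
    # from the group mean acts per raw percentage point
    b_pct = np.log(0.5) / halving_disturbance_pct
    sigmaL, phi = 0.55, 0.15
    alpha_l = {lek: rng.normal(0, sigmaL) for lek in sites["lek_id"]}
    dl = dist.set_index(["lek_id", "year"])["proportion"]
    window_days = [(4, d) for d in range(1, 31)] + [(5, d) for d in range(1, 8)]

    count_rows = []
    group_of = dict(zip(sites["lek_id"], sites["group_id"]))
    gindex = {g: i for i, g in enumerate(groups)}
    for lek in sites["lek_id"]:
        g = gindex[group_of[lek]]
        for t, y in enumerate(years):
            if t == 0:
                continue
            a_pct = 100.0 * float(dl.loc[(lek, y - 1)])
            a_pct_group = 100.0 * float(area_g[g, t - 1])
            log_mu = (
                log_d[g, t]
                + alpha_l[lek]
                - sigmaL**2 / 2.0
                + b_pct * (a_pct - a_pct_group)
            )
            n_visits = int(rng.integers(1, 4))
            visits = _draw_negbin(rng, np.full(n_visits, np.exp(log_mu)), phi)
            for v in visits:
                m, d = window_days[rng.integers(0, len(window_days))]
                count_rows.append(
                    {
                        "lek_id": lek,
                        "group_id": group_of[lek],
                        "date": f"{y:04d}-{m:02d}-{d:02d}",
                        "n_males": int(v),
                        "n_unknown": 0,
                        "is_ground": True,
                        "is_checked": True,
                        "in_survey": True,
                    }
                )
    lek_counts = pd.DataFrame(count_rows)

    manifest = {
        "seed": seed,
        "n_groups": n_groups,
        "leks_per_group": leks_per_group,
        "n_years": n_years,
        "start_year": start_year,
        "betaD": betaD,
        "beta0": beta0,
        "betaA_pop": betaA_pop,
        "betaP_pop": betaP_pop,
        "sigmaY_pop": sigmaY_pop,
        "sd_eta": sd_eta,
        "carrying_capacity": dict(zip(groups, map(float, k_g))),
        "alpha_group": dict(zip(groups, map(float, alpha_g))),
        "b_per_percent": b_pct,
        "sigmaL": sigmaL,
        "phi": phi,
    }
    tables = {
        "lek_counts": lek_counts,
        "lek_sites": sites,
        "well_pads": pads,
        "pdo_monthly": monthly,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables, manifest
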