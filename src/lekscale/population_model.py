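"""Hierarchical Gompertz population-dynamic model and carrying capacity.

The log of a group's density regresses on the previous year's log density:

    log(M[g,y]) ~ Normal(log(mu[g,y]), sd_eta[g,y])
    log(mu[g,y]) = beta0 + (betaD + 1 + alphaG_g) * log(M[g,y-1])
                   + betaA * AREA + betaP * PDO + alphaY_y
    log(sd_eta[g,y]) = betaN + betaL * log(LEKS[g,y])

with ``alphaG ~ N(0, sigmaG)`` on the density-dependence slope and
``alphaY ~ N(0, sigmaY)`` on the intercept.  Observer error is fixed at
exactly zero: all year-to-year variation is process error.  Because the
model is linear-Gaussian in the random effects, the Laplace-marginalized
likelihood is exact.

The carrying capacity is the fixed point of the deterministic map:

    log(N_inf) = -(beta0 + betaA * AREA + betaP * PDO) / (betaD + alphaG).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._laplace import GaussianFamily, RandomEffectBlock, laplace_marginal_nll
from ._mcmc import MCMCConfig, run_independence_mh
from .local_model import _numeric_hessian, _robust_inv

__all__ = [
    "PopModelSpec",
    "PopFit",
    "CarryingCapacity",
    "pop_loglik",
    "fit_population",
    "predict_next_density",
    "carrying_capacity",
]


@dataclass(frozen=True)
class PopModelSpec:
    radius_m: float = 3200.0
    area_lag: int = 1
    pdo_lag: int = 1
    include_area: bool = True
    include_pdo: bool = True

    def label(self) -> str:
        parts = [f"r{self.radius_m:g}", f"alag{self.area_lag}", f"plag{self.pdo_lag}"]
        parts.append("area" if self.include_area else "noarea")
        parts.append("pdo" if self.include_pdo else "nopdo")
        return "_".join(parts)


@dataclass
class PopFit:
    spec: PopModelSpec
    beta0: float
    betaD: float
    betaA: float
    betaP: float
    betaN: float
    betaL: float
    sigmaG: float
    sigmaY: float
    loglik: float
    n_params: int
    n_obs: int
    param_names: list[str] = field(default_factory=list)
    vcov: Optional[np.ndarray] = None
    group_slopes: Optional[pd.Series] = None  # alphaG conditional modes
    year_modes: Optional[pd.Series] = None
    draws: Optional[pd.DataFrame] = None
    diagnostics: dict = field(default_factory=dict)
    constants: Optional[dict] = None

    def se(self, name: str) -> float:
        j = self.param_names.index(name)
        return float(np.sqrt(self.vcov[j, j]))

    def to_json(self) -> str:
        payload = {
            "spec": self.spec.__dict__,
            "estimates": {
                k: getattr(self, k)
                for k in (
                    "beta0",
                    "betaD",
                    "betaA",
                    "betaP",
                    "betaN",
                    "betaL",
                    "sigmaG",
                    "sigmaY",
                )
            },
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "param_names": self.param_names,
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "diagnostics": self.diagnostics,
        }
        return json.dumps(payload, indent=2)


@dataclass
class CarryingCapacity:
    group_id: object
    area_std: float
    pdo_std: float
    value: float
    lower: float = np.nan
    upper: float = np.nan


def _design_arrays(design: pd.DataFrame):
    z = design["log_density"].to_numpy(dtype=float)
    x = design["log_prev_density"].to_numpy(dtype=float)
    area = design["area"].to_numpy(dtype=float)
    pdo = design["pdo"].to_numpy(dtype=float)
    log_leks = np.log(design["n_leks"].to_numpy(dtype=float))
    group_levels, group_idx = np.unique(design["group_id"], return_inverse=True)
    year_levels, year_idx = np.unique(design["year"], return_inverse=True)
    return z, x, area, pdo, log_leks, group_idx, group_levels, year_idx, year_levels


def pop_loglik(params: dict, design: pd.DataFrame, u0=None):
    """Marginal log-likelihood of the population model (exact: the model is
    linear-Gaussian in the random effects).  Returns ``(loglik, u_hat)``."""
    (z, x, area, pdo, log_leks, group_idx, group_levels, year_idx, year_levels) = (
        _design_arrays(design)
    )
    sd = np.exp(params["betaN"] + params["betaL"] * log_leks)
    eta0 = (
        params["beta0"]
        + (params["betaD"] + 1.0) * x
        + params.get("betaA", 0.0) * area
        + params.get("betaP", 0.0) * pdo
    )
    fam = GaussianFamily(z, sd)
    blocks = [
        RandomEffectBlock(group_idx, x, params["sigmaG"], len(group_levels)),
        RandomEffectBlock(year_idx, np.ones_like(z), params["sigmaY"], len(year_levels)),
    ]
    nll, u_hat = laplace_marginal_nll(fam, eta0, blocks, u0=u0)
    if not np.isfinite(nll):
        raise FloatingPointError(f"non-finite log-likelihood at {params}")
    return -nll, u_hat


def _theta_names(spec: PopModelSpec) -> list[str]:
    names = ["beta0", "betaD"]
    if spec.include_area:
        names.append("betaA")
    if spec.include_pdo:
        names.append("betaP")
    names += ["betaN", "betaL", "log_sigmaG", "log_sigmaY"]
    return names


def _theta_to_params(theta, names):
    d = dict(zip(names, theta))
    return {
        "beta0": d["beta0"],
        "betaD": d["betaD"],
        "betaA": d.get("betaA", 0.0),
        "betaP": d.get("betaP", 0.0),
        "betaN": d["betaN"],
        "betaL": d["betaL"],
        "sigmaG": float(np.exp(d["log_sigmaG"])),
        "sigmaY": float(np.exp(d["log_sigmaY"])),
    }


class _NllClosure:
    def __init__(self, design, names):
        self.design = design
        self.names = names
        self.u0 = None

    def __call__(self, theta):
        try:
            ll, u_hat = pop_loglik(_theta_to_params(theta, self.names), self.design, self.u0)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e10
        self.u0 = u_hat
        return -ll


def fit_population(
    spec: PopModelSpec,
    design: pd.DataFrame,
    engine: str = "ml",
    mcmc: MCMCConfig | None = None,
    compute_vcov: bool = True,
    constants: dict | None = None,
) -> PopFit:
    """Fit the population model by ML or MCMC (same conventions as
    :func:`lekscale.local_model.fit_local`).

    ``betaD`` is unconstrained; if the fitted ``betaD + alphaG`` falls
    outside (-2, 0) for any group a non-stationarity warning is issued.
    """
    if engine not in ("ml", "bayes"):
        raise ValueError(f"unknown engine {engine!r}")
    if len(design) < 2:
        raise ValueError("need at least two transitions to fit")
    names = _theta_names(spec)
    nll = _NllClosure(design, names)
    z = design["log_density"].to_numpy(float)
    dz = np.diff(z)
    theta_start = {
        "beta0": 0.3 * float(np.mean(z)),
        "betaD": -0.3,
        "betaA": 0.0,
        "betaP": 0.0,
        "betaN": float(np.log(max(np.std(dz), 0.05))),
        "betaL": 0.0,
        "log_sigmaG": np.log(0.1),
        "log_sigmaY": np.log(0.1),
    }
    theta0 = np.array([theta_start[n] for n in names])
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-2:
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-10}
        )
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            raise RuntimeError(f"ML optimization did not converge: {res.message}")
    theta_hat = res.x

    if engine == "bayes":
        mcmc = mcmc or MCMCConfig()

        def log_post(theta):
            v = -nll(theta)
            if v <= -1e9:
                return -np.inf
            return v + float(np.sum(stats.norm.logpdf(theta, 0.0, 5.0)))

        def neg_log_post(theta):
            lp = log_post(theta)
            return 1e10 if not np.isfinite(lp) else -lp

        map_res = optimize.minimize(
            neg_log_post, theta_hat, method="L-BFGS-B", options={"maxiter": 300}
        )
        H = _numeric_hessian(neg_log_post, map_res.x)
        sample = run_independence_mh(log_post, map_res.x, _robust_inv(H), names, mcmc)
        draws = pd.DataFrame(sample.draws, columns=names)
        draws["sigmaG"] = np.exp(draws.pop("log_sigmaG"))
        draws["sigmaY"] = np.exp(draws.pop("log_sigmaY"))
        med = draws.median()
        params = {
            k: float(med[k]) if k in med else 0.0
            for k in ("beta0", "betaD", "betaA", "betaP", "betaN", "betaL", "sigmaG", "sigmaY")
        }
        ll, u_hat = pop_loglik(params, design, u0=nll.u0)
        diagnostics = dict(sample.diagnostics)
        diagnostics["accept_rate"] = sample.accept_rate
        vcov = np.cov(sample.draws.T)
    else:
        params = _theta_to_params(theta_hat, names)
        ll, u_hat = pop_loglik(params, design, u0=nll.u0)
        draws = None
        diagnostics = {"grad_norm": float(np.max(np.abs(getattr(res, "jac", 0.0))))}
        vcov = _robust_inv(_numeric_hessian(nll, theta_hat)) if compute_vcov else None

    group_levels = np.unique(design["group_id"])
    year_levels = np.unique(design["year"])
    n_g = len(group_levels)
    slopes = pd.Series(u_hat[:n_g], index=group_levels)
    year_modes = pd.Series(u_hat[n_g : n_g + len(year_levels)], index=year_levels)

    dd = params["betaD"] + slopes
    if (dd >= 0).any() or (dd <= -2).any():
        warnings.warn(
            "non-stationary dynamics: betaD + alphaG outside (-2, 0) for "
            f"group(s) {list(slopes.index[(dd >= 0) | (dd <= -2)])}",
            stacklevel=2,
        )

    return PopFit(
        spec=spec,
        beta0=params["beta0"],
        betaD=params["betaD"],
        betaA=params["betaA"],
        betaP=params["betaP"],
        betaN=params["betaN"],
        betaL=params["betaL"],
        sigmaG=params["sigmaG"],
        sigmaY=params["sigmaY"],
        loglik=float(ll),
        n_params=len(names),
        n_obs=len(design),
        param_names=names,
        vcov=vcov,
        group_slopes=slopes,
        year_modes=year_modes,
        draws=draws,
        diagnostics=diagnostics,
        constants=constants,
    )


def predict_next_density(
    fit_or_params,
    prev_density: float,
    area_std: float = 0.0,
    pdo_std: float = 0.0,
    group_effect: float = 0.0,
    year_effect: float = 0.0,
) -> float:
    """Expected density next year given this year's density (Gompertz map)."""
    p = _as_params(fit_or_params)
    if prev_density <= 0:
        raise ValueError("prev_density must be positive")
    return float(
        np.exp(
            p["beta0"]
            + (p["betaD"] + 1.0 + group_effect) * np.log(prev_density)
            + p["betaA"] * area_std
            + p["betaP"] * pdo_std
            + year_effect
        )
    )


def _as_params(fit_or_params) -> dict:
    if isinstance(fit_or_params, dict):
        return fit_or_params
    f = fit_or_params
    return {
        "beta0": f.beta0,
        "betaD": f.betaD,
        "betaA": f.betaA,
        "betaP": f.betaP,
    }


def carrying_capacity(
    fit: PopFit,
    area_std: float = 0.0,
    pdo_std: float = 0.0,
    group_id=None,
    level: float = 0.95,
) -> CarryingCapacity:
    """Long-term expected density at the given covariate values.

    ``group_id=None`` gives the typical group (``alphaG = 0``).  Intervals
    come from posterior draws when present, else from the delta method on
    the log carrying capacity (``alphaG`` treated as fixed at its mode).
    """
    alpha_g = 0.0
    if group_id is not None:
        alpha_g = float(fit.group_slopes.loc[group_id])
    denom = fit.betaD + alpha_g
    if denom == 0:
        raise ZeroDivisionError("betaD + alphaG = 0: no finite carrying capacity")
    s = fit.beta0 + fit.betaA * area_std + fit.betaP * pdo_std
    value = float(np.exp(-s / denom))

    lower = upper = np.nan
    if fit.draws is not None:
        d = fit.draws
        s_d = (
            d["beta0"]
            + d.get("betaA", 0.0) * area_std
            + d.get("betaP", 0.0) * pdo_std
        )
        log_k = -(s_d) / (d["betaD"] + alpha_g)
        q = 100 * (1 - level) / 2
        lower = float(np.exp(np.percentile(log_k, q)))
        upper = float(np.exp(np.percentile(log_k, 100 - q)))
        value = float(np.exp(np.median(log_k)))
    elif fit.vcov is not None:
        grad = np.zeros(len(fit.param_names))
        cov_terms = {"beta0": 1.0, "betaA": area_std, "betaP": pdo_std}
        for name, mult in cov_terms.items():
            if name in fit.param_names:
                grad[fit.param_names.index(name)] = -mult / denom
        grad[fit.param_names.index("betaD")] = s / denom**2
        var_log_k = float(grad @ fit.vcov @ grad)
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(max(var_log_k, 0.0))
        lower = float(np.exp(np.log(value) - half))
        upper = float(np.exp(np.log(value) + half))
    return CarryingCapacity(
        group_id=group_id, area_std=area_std, pdo_std=pdo_std,
        value=value, lower=lower, upper=upper,
    )
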