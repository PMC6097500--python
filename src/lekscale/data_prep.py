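"""Ingest, filter and transform lek counts, well pads and the monthly
climate index into model-ready design tables.

All tabular data are pandas DataFrames with documented column contracts:

``lek_counts``      lek_id, group_id, date (ISO-8601), n_males, n_unknown,
                    is_ground, is_checked, in_survey
``lek_sites``       lek_id, group_id, x_m, y_m
``well_pads``       pad_id, x_m, y_m, spud_year
``pdo_monthly``     year, month, value
``lek_years``       lek_id, group_id, year, count, n_repeats
``disturbance``     lek_id, year, radius_m, proportion
``group_density``   group_id, year, density, n_leks
``design`` (local)  lek_id, group_id, year, count, area_raw, pdo_raw,
                    area, pdo
``design`` (pop)    group_id, year, density, log_density, log_prev_density,
                    n_leks, area_raw, pdo_raw, area, pdo

Coordinates must already be planar metres in a single projected CRS; no
reprojection is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DateWindow",
    "FilterReport",
    "Standardization",
    "filter_records",
    "collapse_counts",
    "annualize_pdo",
    "areal_disturbance",
    "disturbance_series",
    "group_disturbance",
    "group_density",
    "build_local_design",
    "build_pop_design",
    "DEFAULT_RADII_M",
    "PAD_RADIUS_M",
]

#: Buffer radii (m) at which areal disturbance is evaluated by default.
DEFAULT_RADII_M = (800.0, 1600.0, 3200.0, 6400.0)

#: Radius (m) of the disc of disturbance attributed to a single well pad.
PAD_RADIUS_M = 60.0


@dataclass(frozen=True)
class DateWindow:
    """Inclusive month-day window applied within every year."""

    start: tuple[int, int] = (4, 1)  # April 1
    end: tuple[int, int] = (5, 7)  # May 7

    def contains(self, month: int, day: int) -> bool:
        return self.start <= (month, day) <= self.end


@dataclass
class FilterReport:
    """Counts of records dropped per rule, in order of application."""

    n_input: int = 0
    malformed_date: int = 0
    before_start_year: int = 0
    unreliable_method: int = 0  # not ground / not checked / not in survey
    outside_window: int = 0
    unknown_sex: int = 0
    n_output: int = 0

    def dropped(self) -> int:
        return (
            self.malformed_date
            + self.before_start_year
            + self.unreliable_method
            + self.outside_window
            + self.unknown_sex
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Standardization:
    """Centering/scaling constants so raw-scale effects are recoverable."""

    mean: float
    sd: float

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def to_dict(self):
        return {"mean": self.mean, "sd": self.sd}


def filter_records(
    records: pd.DataFrame,
    window: DateWindow = DateWindow(),
    unknown_frac: float = 0.05,
    start_year: int = 1985,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the reliability filters to raw lek-count records.

    Retains records with a parseable date, ``year >= start_year``, all three
    reliability flags set, a date inside the inclusive month-day window, and
    ``n_unknown < unknown_frac * n_males``.  A record with zero males and
    zero unknowns is retained (the unknown-sex rule is vacuous there).
    Returns the retained records (with ``year``, ``month``, ``day`` columns
    added) and a :class:`FilterReport` of drops per rule.
    """
    if not 0 < unknown_frac <= 1:
        raise ValueError("unknown_frac must be in (0, 1]")
    report = FilterReport(n_input=len(records))
    df = records.copy()
    if len(df) == 0:
        report.n_output = 0
        return df, report

    parsed = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = parsed.isna()
    report.malformed_date = int(bad.sum())
    df = df.loc[~bad].copy()
    parsed = parsed.loc[~bad]
    df["year"] = parsed.dt.year
    df["month"] = parsed.dt.month
    df["day"] = parsed.dt.day

    early = df["year"] < start_year
    report.before_start_year = int(early.sum())
    df = df.loc[~early]

    reliable = (
        df["is_ground"].astype(bool)
        & df["is_checked"].astype(bool)
        & df["in_survey"].astype(bool)
    )
    report.unreliable_method = int((~reliable).sum())
    df = df.loc[reliable]

    in_window = [window.contains(m, d) for m, d in zip(df["month"], df["day"])]
    in_window = np.asarray(in_window, dtype=bool)
    report.outside_window = int((~in_window).sum())
    df = df.loc[in_window]

    males = df["n_males"].astype(float)
    unknown = df["n_unknown"].astype(float)
    zero_zero = (males == 0) & (unknown == 0)
    keep = (unknown < unknown_frac * males) | zero_zero
    report.unknown_sex = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)

    report.n_output = len(df)
    return df, report


def collapse_counts(records: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """Collapse repeated within-year counts to one row per (lek, year).

    ``stat="mean"`` takes the arithmetic mean of ``n_males`` rounded
    half-to-even; ``stat="max"`` takes the maximum.  ``n_repeats`` records
    how many visits were collapsed.
    """
    if stat not in ("mean", "max"):
        raise ValueError(f"stat must be 'mean' or 'max', got {stat!r}")
    if "year" not in records.columns:
        raise ValueError("records must carry a 'year' column (run filter_records)")
    grouped = records.groupby(["lek_id", "group_id", "year"], sort=True)["n_males"]
    if stat == "mean":
        # np.round implements round-half-to-even
        count = np.round(grouped.mean()).astype(int)
    else:
        count = grouped.max().astype(int)
    out = count.rename("count").reset_index()
    out["n_repeats"] = grouped.size().values
    return out


def annualize_pdo(monthly: pd.DataFrame, require_complete: bool = False) -> pd.DataFrame:
    """Collapse a monthly index to calendar-year means.

    Returns columns ``year``, ``value``, ``n_months``, ``complete``.  Years
    with fewer than 12 months are flagged ``complete=False`` (and dropped if
    ``require_complete``).  Duplicate (year, month) pairs raise.
    """
    df = monthly.copy()
    if df.duplicated(subset=["year", "month"]).any():
        dups = df[df.duplicated(subset=["year", "month"], keep=False)]
        raise ValueError(
            f"duplicate (year, month) entries in monthly index: "
            f"{sorted(set(map(tuple, dups[['year', 'month']].values)))[:5]}"
        )
    g = df.groupby("year")["value"]
    out = pd.DataFrame(
        {"year": g.mean().index, "value": g.mean().values, "n_months": g.size().values}
    )
    out["complete"] = out["n_months"] == 12
    if require_complete:
        out = out.loc[out["complete"]].reset_index(drop=True)
    return out


def areal_disturbance(
    site_xy: tuple[float, float],
    pads: pd.DataFrame,
    radius_m: float,
    year: int,
    pad_radius_m: float = PAD_RADIUS_M,
) -> float:
    """Proportional areal disturbance around one site in one year.

    Counts pads with ``spud_year <= year`` whose centre lies within
    ``radius_m`` (Euclidean) of the site; each contributes the full area of
    a ``pad_radius_m`` disc.  No boundary clipping or overlap subtraction;
    the proportion is capped at 1.
    """
    if radius_m <= pad_radius_m:
        raise ValueError("radius_m must exceed pad_radius_m")
    if len(pads) == 0:
        return 0.0
    dx = pads["x_m"].to_numpy(dtype=float) - site_xy[0]
    dy = pads["y_m"].to_numpy(dtype=float) - site_xy[1]
    within = dx * dx + dy * dy <= radius_m * radius_m
    built = pads["spud_year"].to_numpy() <= year
    n = int(np.sum(within & built))
    return min(1.0, n * (pad_radius_m / radius_m) ** 2)


def disturbance_series(
    sites: pd.DataFrame,
    pads: pd.DataFrame,
    radii_m=DEFAULT_RADII_M,
    years=None,
    pad_radius_m: float = PAD_RADIUS_M,
) -> pd.DataFrame:
    """Annual per-lek disturbance at each radius, as a long table.

    ``years`` defaults to the span of pad spud years through their maximum;
    pass an explicit range covering the analysis years (including lag
    years).  Pads persist: once constructed they contribute every later
    year, so each series is non-decreasing in year.
    """
    if years is None:
        if len(pads) == 0:
            raise ValueError("years must be given when there are no pads")
        years = range(int(pads["spud_year"].min()), int(pads["spud_year"].max()) + 1)
    years = np.asarray(list(years), dtype=int)
    xs = sites["x_m"].to_numpy(dtype=float)
    ys = sites["y_m"].to_numpy(dtype=float)
    out = []
    px = pads["x_m"].to_numpy(dtype=float) if len(pads) else np.empty(0)
    py = pads["y_m"].to_numpy(dtype=float) if len(pads) else np.empty(0)
    pyear = pads["spud_year"].to_numpy(dtype=int) if len(pads) else np.empty(0, int)
    for radius in radii_m:
        if radius <= pad_radius_m:
            raise ValueError("radius must exceed pad_radius_m")
        frac = (pad_radius_m / radius) ** 2
        for lek_id, x, y in zip(sites["lek_id"], xs, ys):
            d2 = (px - x) ** 2 + (py - y) ** 2
            in_range = pyear[d2 <= radius * radius]
            # cumulative count of pads built by each year
            counts = np.searchsorted(np.sort(in_range), years, side="right")
            props = np.minimum(1.0, counts * frac)
            out.append(
                pd.DataFrame(
                    {
                        "lek_id": lek_id,
                        "year": years,
                        "radius_m": radius,
                        "proportion": props,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def group_disturbance(disturbance: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Average the per-lek disturbance over each working group's leks."""
    merged = disturbance.merge(sites[["lek_id", "group_id"]], on="lek_id")
    out = (
        merged.groupby(["group_id", "year", "radius_m"], sort=True)["proportion"]
        .mean()
        .reset_index()
    )
    return out


def group_density(lek_years: pd.DataFrame) -> pd.DataFrame:
    """Mean males per lek for each working group in each year.

    The density is the unweighted mean of the collapsed lek counts over the
    leks counted in that group-year; group-years with no counted leks are
    simply absent.
    """
    g = lek_years.groupby(["group_id", "year"], sort=True)["count"]
    out = pd.DataFrame(
        {
            "group_id": g.mean().index.get_level_values(0),
            "year": g.mean().index.get_level_values(1),
            "density": g.mean().values,
            "n_leks": g.size().values,
        }
    )
    return out


def _standardize(design: pd.DataFrame, raw_col: str, out_col: str) -> Standardization:
    x = design[raw_col].to_numpy(dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError(f"predictor {raw_col!r} has zero variance; cannot standardize")
    design[out_col] = (x - mean) / sd
    return Standardization(mean=mean, sd=sd)


def build_local_design(
    lek_years: pd.DataFrame,
    disturbance: pd.DataFrame,
    pdo_annual: pd.DataFrame,
    radius_m: float,
    area_lag: int = 1,
    pdo_lag: int = 1,
    restrict_keys=None,
) -> tuple[pd.DataFrame, dict]:
    """Join lek-years to lagged covariates and standardize.

    ``restrict_keys`` is an optional set of (lek_id, year) pairs the design
    is limited to (used by model scans to keep rows identical across lag
    choices).  Returns the design and a constants dict holding the
    :class:`Standardization` for each predictor plus the spec of the join.
    Rows lacking a lagged covariate are dropped; the count is recorded under
    ``constants["n_dropped"]``.
    """
    dist = disturbance.loc[disturbance["radius_m"] == radius_m]
    if len(dist) == 0:
        raise ValueError(f"no disturbance rows at radius {radius_m}")
    df = lek_years.copy()
    df["_area_year"] = df["year"] - area_lag
    df = df.merge(
        dist[["lek_id", "year", "proportion"]].rename(
            columns={"year": "_area_year", "proportion": "area_raw"}
        ),
        on=["lek_id", "_area_year"],
        how="left",
    )
    df["_pdo_year"] = df["year"] - pdo_lag
    df = df.merge(
        pdo_annual[["year", "value"]].rename(
            columns={"year": "_pdo_year", "value": "pdo_raw"}
        ),
        on="_pdo_year",
        how="left",
    )
    n_before = len(df)
    df = df.dropna(subset=["area_raw", "pdo_raw"])
    if restrict_keys is not None:
        keys = list(zip(df["lek_id"], df["year"]))
        df = df.loc[[k in restrict_keys for k in keys]]
    df = df.drop(columns=["_area_year", "_pdo_year"]).reset_index(drop=True)
    constants = {
        "radius_m": radius_m,
        "area_lag": area_lag,
        "pdo_lag": pdo_lag,
        "n_dropped": n_before - len(df) if restrict_keys is None else None,
    }
    constants["area"] = _standardize(df, "area_raw", "area")
    constants["pdo"] = _standardize(df, "pdo_raw", "pdo")
    return df, constants


def build_pop_design(
    densities: pd.DataFrame,
    group_dist: pd.DataFrame,
    pdo_annual: pd.DataFrame,
    radius_m: float,
    area_lag: int = 1,
    pdo_lag: int = 1,
    restrict_keys=None,
) -> tuple[pd.DataFrame, dict]:
    """Build the transition table for the population model.

    A row is a one-year transition: group-year ``y`` with an observed
    density in year ``y - 1`` of the same group.  Gaps break the chain.
    Rows whose density (either year) is zero are excluded with a warning
    since the log is undefined.
    """
    df = densities.copy().sort_values(["group_id", "year"])
    prev = df.rename(
        columns={"year": "_prev_year", "density": "prev_density"}
    )[["group_id", "_prev_year", "prev_density"]]
    df["_prev_year"] = df["year"] - 1
    df = df.merge(prev, on=["group_id", "_prev_year"], how="inner")

    zero = (df["density"] <= 0) | (df["prev_density"] <= 0)
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} transition(s) with zero density "
            "(log undefined)",
            stacklevel=2,
        )
        df = df.loc[~zero]

    dist = group_dist.loc[group_dist["radius_m"] == radius_m]
    if len(dist) == 0:
        raise ValueError(f"no group disturbance rows at radius {radius_m}")
    df["_area_year"] = df["year"] - area_lag
    df = df.merge(
        dist[["group_id", "year", "proportion"]].rename(
            columns={"year": "_area_year", "proportion": "area_raw"}
        ),
        on=["group_id", "_area_year"],
        how="left",
    )
    df["_pdo_year"] = df["year"] - pdo_lag
    df = df.merge(
        pdo_annual[["year", "value"]].rename(
            columns={"year": "_pdo_year", "value": "pdo_raw"}
        ),
        on="_pdo_year",
        how="left",
    )
    n_before = len(df)
    df = df.dropna(subset=["area_raw", "pdo_raw"])
    if restrict_keys is not None:
        keys = list(zip(df["group_id"], df["year"]))
        df = df.loc[[k in restrict_keys for k in keys]]
    df["log_density"] = np.log(df["density"].to_numpy(dtype=float))
    df["log_prev_density"] = np.log(df["prev_density"].to_numpy(dtype=float))
    df = df.drop(columns=["_prev_year", "_area_year", "_pdo_year"]).reset_index(
        drop=True
    )
    constants = {
        "radius_m": radius_m,
        "area_lag": area_lag,
        "pdo_lag": pdo_lag,
        "n_dropped": n_before - len(df) if restrict_keys is None else None,
    }
    constants["area"] = _standardize(df, "area_raw", "area")
    constants["pdo"] = _standardize(df, "pdo_raw", "pdo")
    return df, constants
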