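import warnings

import numpy as np
import pandas as pd
import pytest

from lekscale import data_prep, synthetic

warnings.filterwarnings("ignore", message="excluding .* transition")


@pytest.fixture(scope="session")
def local_sim():
    """Moderate simulated lek-count panel with known truth."""
    cov = synthetic.CovariateSimParams(seed=3)
    pdo, dist = synthetic.simulate_covariates(cov, n_leks=80, n_years=20)
    params = synthetic.LocalSimParams(n_leks=80, n_years=20, seed=4)
    lek_years, truth = synthetic.simulate_lek_counts(params, dist, pdo)
    return {"lek_years": lek_years, "truth": truth, "params": params,
            "pdo": pdo, "disturbance": dist}


@pytest.fixture(scope="session")
def local_design(local_sim):
    """Design built directly from the simulated raw covariates (no lag join:
    the simulation already paired covariates with response years)."""
    design = local_sim["lek_years"].copy()
    for raw, out in (("area_raw", "area"), ("pdo_raw", "pdo")):
        x = design[raw].to_numpy(float)
        design[out] = (x - x.mean()) / x.std(ddof=1)
    return design


@pytest.fixture(scope="session")
def local_fit(local_design):
    from lekscale.local_model import LocalModelSpec, fit_local

    return fit_local(LocalModelSpec(), local_design, engine="ml")


@pytest.fixture(scope="session")
def pop_sim():
    """Simulated group density series with disturbance and known truth."""
    rng = np.random.default_rng(2)
    cov = synthetic.CovariateSimParams(seed=9)
    pdo, dist = synthetic.simulate_covariates(cov, n_leks=30, n_years=45,
                                              start_year=1970)
    dist = dist.assign(
        group_id="G" + (dist["lek_id"].str[1:].astype(int) + 1).astype(str)
    )
    gdist = dist[["group_id", "year", "radius_m", "proportion"]]
    params = synthetic.PopSimParams(n_groups=30, n_years=45, seed=7)
    dens, truth = synthetic.simulate_population_series(params, gdist, pdo)
    return {"densities": dens, "truth": truth, "params": params,
            "pdo": pdo, "group_dist": gdist}


@pytest.fixture(scope="session")
def pop_design(pop_sim):
    design, consts = data_prep.build_pop_design(
        pop_sim["densities"], pop_sim["group_dist"], pop_sim["pdo"], 3200.0, 1, 1
    )
    return design, consts


@pytest.fixture(scope="session")
def pop_fit(pop_design):
    from lekscale.population_model import PopModelSpec, fit_population

    design, consts = pop_design
    return fit_population(PopModelSpec(), design, engine="ml", constants=consts)


@pytest.fixture(scope="session")
def fixture_tables(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    tables, manifest = synthetic.make_fixture(
        11, out, n_groups=4, leks_per_group=12, n_years=18
    )
    return {"tables": tables, "manifest": manifest, "dir": out}


@pytest.fixture()
def raw_counts():
    """Hand-built raw records covering every filter rule."""
    rows = [
        # retained
        dict(lek_id="A", group_id="G", date="2000-04-15", n_males=10, n_unknown=0,
             is_ground=True, is_checked=True, in_survey=True),
        # outside window
        dict(lek_id="A", group_id="G", date="2000-05-20", n_males=10, n_unknown=0,
             is_ground=True, is_checked=True, in_survey=True),
        # unknown-sex rule: 1/10 = 10% >= 5%
        dict(lek_id="B", group_id="G", date="2000-04-20", n_males=10, n_unknown=1,
             is_ground=True, is_checked=True, in_survey=True),
        # aerial count
        dict(lek_id="C", group_id="G", date="2000-04-20", n_males=5, n_unknown=0,
             is_ground=False, is_checked=True, in_survey=True),
        # pre-1985
        dict(lek_id="D", group_id="G", date="1984-04-20", n_males=5, n_unknown=0,
             is_ground=True, is_checked=True, in_survey=True),
        # malformed date
        dict(lek_id="E", group_id="G", date="not-a-date", n_males=5, n_unknown=0,
             is_ground=True, is_checked=True, in_survey=True),
        # zero males, zero unknown: retained
        dict(lek_id="F", group_id="G", date="2000-04-10", n_males=0, n_unknown=0,
             is_ground=True, is_checked=True, in_survey=True),
    ]
    return pd.DataFrame(rows)
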