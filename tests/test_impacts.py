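import numpy as np
import pandas as pd
import pytest

from lekscale.data_prep import Standardization
from lekscale.impacts import (
    carrying_capacity_impact,
    local_population_impact,
    sensitivity_suite,
    sensitivity_table,
)
from lekscale.local_model import LocalFit, LocalModelSpec
from lekscale.model_selection import effect_size
from lekscale.population_model import PopFit, PopModelSpec


def _local_fit(betaA=-0.3, sd=0.01, mean=0.005, lek_modes=None):
    fit = LocalFit(
        spec=LocalModelSpec(), beta0=np.log(10), betaA=betaA, betaP=0.1,
        sigmaL=0.5, sigmaY=0.2, phi=0.2, loglik=0.0, n_params=6, n_obs=0,
        constants={"area": Standardization(mean=mean, sd=sd)},
    )
    leks = ["a", "b", "c"] if lek_modes is None else list(lek_modes)
    modes = pd.Series(0.0, index=leks) if lek_modes is None else pd.Series(lek_modes)
    fit.ranef_modes = {"lek": modes, "year": pd.Series(dtype=float)}
    return fit


def _pop_fit(betaA=-0.1, betaD=-0.5, sd=0.002, slopes=None):
    return PopFit(
        spec=PopModelSpec(), beta0=1.5, betaD=betaD, betaA=betaA, betaP=0.05,
        betaN=np.log(0.2), betaL=0.0, sigmaG=0.05, sigmaY=0.1, loglik=0.0,
        n_params=8, n_obs=0,
        group_slopes=slopes if slopes is not None else pd.Series(dtype=float),
        constants={"area": Standardization(mean=0.001, sd=sd)},
    )


class TestLocalPopulationImpact:
    def test_zero_disturbance_zero_impact(self):
        fit = _local_fit()
        dist = pd.Series([0.0, 0.0, 0.0], index=["a", "b", "c"])
        est = local_population_impact(fit, dist)
        assert est.percent == 0.0

    def test_single_lek_halving(self):
        """One lek whose effect multiplier is 0.5 -> -50%."""
        sd = 0.01
        raw = 0.02
        betaA = np.log(0.5) / (raw / sd)  # per-SD slope so raw doubles to 0.5x
        fit = _local_fit(betaA=betaA, sd=sd, mean=0.0)
        est = local_population_impact(fit, pd.Series([raw], index=["a"]))
        assert est.percent == pytest.approx(-50.0, abs=1e-9)

    def test_two_leks_weighted(self):
        """Equal expected counts, multipliers {0.5, 1} -> -25%."""
        sd = 0.01
        raw = 0.02
        betaA = np.log(0.5) / (raw / sd)
        fit = _local_fit(betaA=betaA, sd=sd, mean=0.0,
                         lek_modes={"a": 0.0, "b": 0.0})
        est = local_population_impact(fit, pd.Series([raw, 0.0], index=["a", "b"]))
        assert est.percent == pytest.approx(-25.0, abs=1e-9)

    def test_scale_invariance(self):
        """Common rescaling of all leks' expected counts cancels."""
        sd = 0.01
        fit1 = _local_fit(sd=sd, mean=0.0, lek_modes={"a": 0.1, "b": -0.4})
        fit2 = _local_fit(sd=sd, mean=0.0,
                          lek_modes={"a": 0.1 + 2.0, "b": -0.4 + 2.0})
        dist = pd.Series([0.02, 0.005], index=["a", "b"])
        e1 = local_population_impact(fit1, dist)
        e2 = local_population_impact(fit2, dist)
        assert e1.percent == pytest.approx(e2.percent, abs=1e-9)

    def test_single_lek_equals_effect_size_pathway(self):
        """For one lek the impact matches effect_size evaluated at that
        lek's standardized disturbance."""
        fit = _local_fit(betaA=-0.25, sd=0.008, mean=0.002)
        raw = 0.015
        est = local_population_impact(fit, pd.Series([raw], index=["a"]))
        delta_std = raw / fit.constants["area"].sd
        expect = effect_size(fit.betaA * delta_std).percent
        assert est.percent == pytest.approx(expect, abs=1e-9)


class TestCarryingCapacityImpact:
    def test_zero_disturbance(self):
        est = carrying_capacity_impact(_pop_fit(), 0.0)
        assert est.percent == 0.0

    def test_closed_form_amplification(self):
        """betaA*dA = -0.1 with betaD = -0.5 amplifies to exp(-0.2)-1."""
        sd = 0.002
        raw = 0.004  # dA_std = 2
        betaA = -0.05  # betaA * dA_std = -0.1
        est = carrying_capacity_impact(_pop_fit(betaA=betaA, sd=sd), raw)
        assert est.percent == pytest.approx(100 * (np.exp(-0.2) - 1), abs=1e-9)
        assert est.percent == pytest.approx(-18.126924, abs=1e-4)

    def test_sign_matches_betaA(self):
        assert carrying_capacity_impact(_pop_fit(betaA=-0.1), 0.01).percent < 0
        assert carrying_capacity_impact(_pop_fit(betaA=+0.1), 0.01).percent > 0

    def test_group_slope_used(self):
        slopes = pd.Series({"G1": -0.2})
        fit = _pop_fit(betaA=-0.05, slopes=slopes)
        est_typ = carrying_capacity_impact(fit, 0.004)
        est_g = carrying_capacity_impact(fit, 0.004, group_id="G1")
        assert est_g.percent != pytest.approx(est_typ.percent)

    def test_zero_denominator(self):
        fit = _pop_fit(betaD=0.0)
        with pytest.raises(ZeroDivisionError):
            carrying_capacity_impact(fit, 0.01)

    def test_sign_agreement_between_bases(self, pop_fit, local_fit, local_sim):
        """Both fits on data simulated with negative disturbance effects
        give negative impacts (qualitative cross-basis agreement)."""
        # attach constants to the session fits
        lfit = local_fit
        if lfit.constants is None:
            lfit.constants = {"area": Standardization(mean=0.0, sd=0.01)}
        est_l = local_population_impact(
            lfit, pd.Series([0.02], index=[lfit.ranef_modes["lek"].index[0]])
        )
        pfit = pop_fit
        if pfit.constants is None:
            pfit.constants = {"area": Standardization(mean=0.0, sd=0.01)}
        est_p = carrying_capacity_impact(pfit, 0.02)
        assert np.sign(est_l.percent) == np.sign(est_p.percent)


@pytest.fixture(scope="module")
def suite(fixture_tables):
    t = fixture_tables["tables"]
    spec = PopModelSpec(radius_m=3200.0, area_lag=1, pdo_lag=1)
    return sensitivity_suite(
        t["lek_counts"], t["lek_sites"], t["well_pads"], t["pdo_monthly"],
        spec, start_years=(1985, 1990), reference=("mean", 1985),
    )


class TestSensitivitySuite:
    def test_all_variants_present(self, suite):
        assert {(r.stat, r.start_year) for r in suite} == {
            ("mean", 1985), ("mean", 1990), ("max", 1985), ("max", 1990)
        }

    def test_reference_unadjusted(self, suite):
        ref = next(r for r in suite if (r.stat, r.start_year) == ("mean", 1985))
        assert not ref.failed
        assert ref.sd_adjustment["area"] == pytest.approx(1.0)

    def test_table_export(self, suite):
        tbl = sensitivity_table(suite)
        ok = tbl[~tbl["failed"]]
        assert {"percent", "lower", "upper", "sd_adjustment"} <= set(ok.columns)
        assert len(ok) >= 2

    def test_deterministic(self, fixture_tables, suite):
        t = fixture_tables["tables"]
        spec = PopModelSpec(radius_m=3200.0, area_lag=1, pdo_lag=1)
        again = sensitivity_suite(
            t["lek_counts"], t["lek_sites"], t["well_pads"], t["pdo_monthly"],
            spec, start_years=(1985, 1990), reference=("mean", 1985),
        )
        for a, b in zip(suite, again):
            if not a.failed:
                assert a.effects["area"].percent == pytest.approx(
                    b.effects["area"].percent, abs=1e-9
                )

    def test_max_counts_dominate_mean(self, fixture_tables):
        from lekscale import data_prep

        counts = fixture_tables["tables"]["lek_counts"]
        filtered, _ = data_prep.filter_records(counts)
        mean = data_prep.collapse_counts(filtered, "mean").set_index(
            ["lek_id", "year"])["count"]
        mx = data_prep.collapse_counts(filtered, "max").set_index(
            ["lek_id", "year"])["count"]
        assert (mx >= mean).all()


@pytest.fixture(scope="module")
def bayes_fits(local_sim, pop_design):
    """Short unchecked chains: enough to exercise the draw-based paths."""
    from lekscale._mcmc import MCMCConfig
    from lekscale.local_model import fit_local
    from lekscale.population_model import fit_population

    design = local_sim["lek_years"].copy()
    design = design[design["lek_id"].isin(sorted(design["lek_id"].unique())[:25])]
    for raw, out in (("area_raw", "area"), ("pdo_raw", "pdo")):
        x = design[raw].to_numpy(float)
        design[out] = (x - x.mean()) / x.std(ddof=1)
    cfg = MCMCConfig(n_iter=160, seed=3, check=False)
    lfit = fit_local(LocalModelSpec(), design, engine="bayes", mcmc=cfg,
                     constants={"area": Standardization(mean=0.0, sd=0.01)})
    pdesign, pconsts = pop_design
    pfit = fit_population(PopModelSpec(), pdesign, engine="bayes",
                          mcmc=cfg, constants=pconsts)
    return lfit, design, pfit


class TestBayesianImpactPaths:
    def test_local_impact_interval_from_draws(self, bayes_fits):
        lfit, design, _ = bayes_fits
        leks = lfit.ranef_modes["lek"].index[:4]
        dist = pd.Series([0.02, 0.0, 0.01, 0.005], index=leks)
        est = local_population_impact(lfit, dist, design=design)
        assert np.isfinite(est.lower) and np.isfinite(est.upper)
        assert est.lower <= est.percent <= est.upper

    def test_cc_impact_interval_from_draws(self, bayes_fits):
        _, _, pfit = bayes_fits
        est = carrying_capacity_impact(pfit, 0.004)
        assert est.lower <= est.percent <= est.upper

    def test_cc_interval_from_draws(self, bayes_fits):
        from lekscale.population_model import carrying_capacity

        _, _, pfit = bayes_fits
        cc = carrying_capacity(pfit)
        assert cc.lower < cc.value < cc.upper
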