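import numpy as np
import pandas as pd
import pytest

from lekscale import data_prep, synthetic
from lekscale.synthetic import (
    CovariateSimParams,
    LocalSimParams,
    PopSimParams,
    _draw_negbin,
    make_fixture,
    simulate_covariates,
    simulate_lek_counts,
    simulate_population_series,
)


class TestSimulateCovariates:
    def test_seed_determinism(self):
        p = CovariateSimParams(seed=42)
        a = simulate_covariates(p, 20, 15)
        b = simulate_covariates(p, 20, 15)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_white_noise_when_rho_zero(self):
        n = 4000
        pdo, _ = simulate_covariates(CovariateSimParams(pdo_rho=0.0, seed=5,
                                                        n_pads_final=0), 1, n)
        x = pdo["value"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(n)

    def test_marginal_sd(self):
        pdo, _ = simulate_covariates(CovariateSimParams(pdo_rho=0.5, pdo_sd=0.8,
                                                        seed=6, n_pads_final=0),
                                     1, 5000)
        assert pdo["value"].std() == pytest.approx(0.8, rel=0.1)

    def test_zero_pad_budget(self):
        _, dist = simulate_covariates(CovariateSimParams(n_pads_final=0, seed=1),
                                      30, 20)
        assert (dist["proportion"] == 0).all()

    def test_disturbance_monotone_nondecreasing(self):
        _, dist = simulate_covariates(CovariateSimParams(seed=2), 40, 25)
        for _, g in dist.groupby("lek_id"):
            v = g.sort_values("year")["proportion"].to_numpy()
            assert np.all(np.diff(v) >= 0)

    def test_right_skew_across_leks(self):
        _, dist = simulate_covariates(CovariateSimParams(seed=3), 200, 25)
        finals = dist.groupby("lek_id")["proportion"].max()
        assert finals.mean() > finals.median()  # right-skewed


class TestNegBinDraws:
    def test_moments_match_variance_function(self):
        rng = np.random.default_rng(0)
        mu, phi, n = 10.0, 0.5, 100_000
        draws = _draw_negbin(rng, np.full(n, mu), phi)
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.std() == pytest.approx(np.sqrt(mu + phi * mu**2), rel=0.02)
        # spec'd closed form: SD = sqrt(60) at mu=10, phi=0.5
        assert np.sqrt(mu + phi * mu**2) == pytest.approx(7.745966, abs=1e-6)

    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        draws = _draw_negbin(rng, np.full(50_000, 4.0), 0.0)
        assert draws.var() == pytest.approx(4.0, rel=0.05)


class TestSimulateLekCounts:
    def test_mean_count_ten(self):
        """No effects, no noise, beta0=log(10): mean count ~ 10."""
        cov = CovariateSimParams(seed=11)
        pdo, dist = simulate_covariates(cov, 100, 50)
        p = LocalSimParams(n_leks=100, n_years=50, beta0=np.log(10), betaA=0,
                           betaP=0, sigmaL=0, sigmaY=0, phi=1e-8, seed=12)
        ly, _ = simulate_lek_counts(p, dist, pdo)
        assert ly["count"].mean() == pytest.approx(10.0, rel=0.02)

    def test_between_lek_variance(self):
        cov = CovariateSimParams(seed=13, n_pads_final=5)
        pdo, dist = simulate_covariates(cov, 400, 40)
        sigmaL = 0.8
        p = LocalSimParams(n_leks=400, n_years=40, betaA=0, betaP=0,
                           sigmaL=sigmaL, sigmaY=0, phi=1e-9, seed=14)
        ly, truth = simulate_lek_counts(p, dist, pdo)
        log_means = np.log(ly.groupby("lek_id")["count"].mean())
        assert log_means.var() == pytest.approx(sigmaL**2, rel=0.25)

    def test_truth_returned(self, local_sim):
        truth = local_sim["truth"]
        assert len(truth["alpha_lek"]) == 80
        assert len(truth["alpha_year"]) == 20
        assert "sd" in truth["area_standardization"]

    def test_determinism(self):
        cov = CovariateSimParams(seed=3)
        pdo, dist = simulate_covariates(cov, 20, 10)
        p = LocalSimParams(n_leks=20, n_years=10, seed=9)
        a, _ = simulate_lek_counts(p, dist, pdo)
        b, _ = simulate_lek_counts(p, dist, pdo)
        pd.testing.assert_frame_equal(a, b)


class TestSimulatePopulationSeries:
    def _pdo(self, n):
        return pd.DataFrame({"year": range(1985, 1985 + n),
                             "value": np.zeros(n)})

    def test_full_compensation_one_step(self):
        """betaD=-1: next density is the carrying capacity regardless of
        the start."""
        p = PopSimParams(n_groups=1, n_years=3, betaD=-1.0, beta0=np.log(20),
                        betaA=0, betaP=0, betaN=np.log(1e-12), betaL=0,
                        sigmaG=0, sigmaY=0, seed=1)
        dens, truth = simulate_population_series(p, None, self._pdo(3),
                                                 init_density=np.array([3.0]))
        k = np.exp(-p.beta0 / p.betaD)
        assert dens["density"].iloc[1] == pytest.approx(k, rel=1e-6)

    def test_converges_to_fixed_point(self):
        p = PopSimParams(n_groups=1, n_years=60, betaD=-0.4, beta0=0.4 * np.log(25),
                        betaA=0, betaP=0, betaN=np.log(1e-12), betaL=0,
                        sigmaG=0, sigmaY=0, seed=2)
        dens, truth = simulate_population_series(p, None, self._pdo(60),
                                                 init_density=np.array([2.0]))
        k = truth["carrying_capacity"]["G1"]
        assert dens["density"].iloc[-1] == pytest.approx(k, rel=1e-4)
        # monotone convergence in |log density - log K|
        gap = np.abs(np.log(dens["density"].to_numpy()) - np.log(k))
        assert np.all(np.diff(gap) <= 1e-12)

    def test_process_sd_decreases_with_leks_when_betaL_negative(self):
        betaN, betaL = np.log(0.3), -0.4
        sd_small = np.exp(betaN + betaL * np.log(2))
        sd_large = np.exp(betaN + betaL * np.log(100))
        assert sd_large < sd_small

    def test_truth_and_determinism(self, pop_sim):
        t = pop_sim["truth"]
        assert len(t["carrying_capacity"]) == 30
        dens2, _ = simulate_population_series(
            pop_sim["params"], pop_sim["group_dist"], pop_sim["pdo"]
        )
        pd.testing.assert_frame_equal(pop_sim["densities"], dens2)


class TestMakeFixture:
    def test_same_seed_identical_files(self, tmp_path):
        a, ma = make_fixture(7, tmp_path / "a", n_groups=2, leks_per_group=5,
                             n_years=10)
        b, mb = make_fixture(7, tmp_path / "b", n_groups=2, leks_per_group=5,
                             n_years=10)
        for k in a:
            pd.testing.assert_frame_equal(a[k], b[k])
        assert ma == mb
        assert (tmp_path / "a" / "manifest.json").exists()

    def test_passes_filter_with_zero_drops(self, fixture_tables):
        counts = fixture_tables["tables"]["lek_counts"]
        _, report = data_prep.filter_records(counts)
        assert report.dropped() == 0

    def test_group_densities_positive(self, fixture_tables):
        counts = fixture_tables["tables"]["lek_counts"]
        filtered, _ = data_prep.filter_records(counts)
        ly = data_prep.collapse_counts(filtered)
        dens = data_prep.group_density(ly)
        assert (dens["density"] > 0).all()

    def test_carrying_capacities_in_range(self, fixture_tables):
        ks = fixture_tables["manifest"]["carrying_capacity"].values()
        assert all(12.9 <= k <= 35.1 for k in ks)

    def test_readable_by_data_prep_formats(self, fixture_tables):
        d = fixture_tables["dir"]
        counts = pd.read_csv(d / "lek_counts.csv")
        sites = pd.read_csv(d / "lek_sites.csv")
        pads = pd.read_csv(d / "well_pads.csv")
        monthly = pd.read_csv(d / "pdo_monthly.csv")
        assert {"lek_id", "group_id", "date", "n_males", "n_unknown",
                "is_ground", "is_checked", "in_survey"} <= set(counts.columns)
        assert {"lek_id", "group_id", "x_m", "y_m"} <= set(sites.columns)
        assert {"pad_id", "x_m", "y_m", "spud_year"} <= set(pads.columns)
        annual = data_prep.annualize_pdo(monthly)
        assert annual["complete"].all()
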