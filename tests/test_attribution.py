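"""Attribution checks: design construction, GLS oracle, selection, freezing."""

import numpy as np
import pandas as pd
import pytest

import foliartrends as ft
from foliartrends.attribution import (
    _frozen_frame,
    build_attribution_design,
    fit_glmm_arma,
    r2_glmm,
    stepwise_select,
    temporal_contributions,
)
from foliartrends.lmm import LmmError
from foliartrends.synthetic import SimulationConfig
from foliartrends.trends import TrendEstimate

from oracles import dense_gls, dense_marginal_cov


def small_scenario(seed=0, **overrides):
    kw = dict(
        n_countries=4, plots_per_country=3, species_pool=("sp1", "sp2"),
        sigma_country=0.8, sigma_plot=1.0, sigma_species=0.8,
        sigma_resid=0.8, phi=0.4, seed=seed,
        beta={e: ({"co2": -0.023} if e == "N" else {}) for e in ft.ELEMENTS},
        driver_noise_sd={"co2": 0.3, "mat": 0.5, "map": 80.0,
                         "ndep_ox": 0.5, "ndep_red": 0.5, "sdep": 0.8},
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="module")
def small_data():
    cfg = small_scenario(seed=21)
    sites = ft.make_sites(cfg)
    drivers = ft.generate_drivers(cfg, sites)
    panel = ft.generate_panel(cfg, drivers, sites)
    return cfg, sites, drivers, panel


class TestDesign:
    def test_anomalies_mean_zero_per_site(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N")
        for d in design.drivers:
            site_means = design.data.groupby("site_id")[f"{d}_anom"].mean()
            assert np.allclose(site_means, 0.0, atol=1e-9)

    def test_two_year_mean_anomaly_arithmetic(self):
        panel = pd.DataFrame(
            {
                "country": ["C0"] * 2, "plot": ["P0"] * 2, "species": ["S"] * 2,
                "tree": ["T0"] * 2, "latitude": [50.0] * 2, "longitude": [5.0] * 2,
                "year": [2000, 2001], "N": [20.0, 19.0], "dbh": [30.0, 30.4],
            }
        )
        drivers = pd.DataFrame(
            {
                "site_id": ["C0_P0"] * 2, "year": [2000, 2001],
                "co2": [10.0, 14.0], "mat": [8.0, 8.0], "map": [700.0, 700.0],
                "ndep_ox": [5.0, 5.0], "ndep_red": [5.0, 5.0], "sdep": [8.0, 8.0],
            }
        )
        design = build_attribution_design(panel, drivers, "N")
        assert design.data["co2_mean"].tolist() == [12.0, 12.0]
        assert design.data["co2_anom"].tolist() == [-2.0, 2.0]
        # constant driver -> all-zero anomaly column
        assert design.data["mat_anom"].tolist() == [0.0, 0.0]

    def test_missing_driver_record_errors(self, small_data):
        _, _, drivers, panel = small_data
        trimmed = drivers[drivers.year != 2005]
        with pytest.raises(ValueError, match="2005"):
            build_attribution_design(panel, trimmed, "N")

    def test_combined_nitrogen_mode(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N", combine_nitrogen=True)
        assert "ndep" in design.drivers and "ndep_ox" not in design.drivers
        expected = (
            design.data["ndep_ox"] + design.data["ndep_red"]
        )
        assert np.allclose(design.data["ndep"], expected, atol=1e-12)
        assert "ndep_anom" in design.data.columns
        table = ft.attribute_element(
            panel, drivers, "N", terms="mains", stepwise=False, combine_nitrogen=True
        )
        assert {e.predictor for e in table.entries} == {
            "co2", "mat", "map", "ndep", "sdep"
        }
        assert abs(table.total - table.observed_trend.slope) < 1e-9

    def test_growth_column_is_dbh_increment(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N", include_growth=True)
        g = design.data[design.data["site_id"] == design.data["site_id"].iloc[0]]
        one = g[(g.species == g.species.iloc[0]) & (g.tree == g.tree.iloc[0])].sort_values("year")
        inc = np.diff(one["dbh"]) / np.diff(one["year"])
        assert np.allclose(one["growth"].to_numpy()[1:], inc, atol=1e-9)


class TestFitGlmmArma:
    def test_noiseless_anomaly_coefficient_exact(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N")
        df = design.data.copy()
        df["N"] = 3.0 + 0.2 * df["co2_anom"]
        fit = fit_glmm_arma(ft.AttributionDesign(df, "N"), ["co2_anom"])
        assert fit.fixed_effects["co2_anom"][0] == pytest.approx(0.2, abs=1e-6)
        assert fit.fixed_effects["intercept"][0] == pytest.approx(3.0, abs=1e-6)

    def test_collinear_column_rejected_by_name(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N")
        design.data["zeros"] = 0.0
        with pytest.raises(LmmError, match="zeros"):
            fit_glmm_arma(design, ["co2_anom", "zeros"])

    def test_gls_oracle_small_design(self):
        # <= 40 rows: fixed effects at fixed variance parameters match dense GLS
        cfg = small_scenario(
            seed=33, n_countries=1, plots_per_country=2,
            species_pool=("sp1",), year_start=2000, year_end=2009,
        )
        sites = ft.make_sites(cfg)
        drivers = ft.generate_drivers(cfg, sites)
        panel = ft.generate_panel(cfg, drivers, sites)
        assert len(panel) <= 40
        design = build_attribution_design(panel, drivers, "N")
        lambdas = {"plot": 1.2, "species": 0.7}
        fit = fit_glmm_arma(
            design, ["co2_anom", "mat_anom"], fixed_phi=0.35, fixed_lambdas=lambdas
        )
        df = design.data
        series = (df["site_id"] + "/" + df["species"]).to_numpy()
        sigma_e = fit.variance_components["residual"]
        factors = {"plot": df["site_id"].to_numpy(), "species": series}
        sds = {k: np.sqrt(v) * sigma_e for k, v in lambdas.items()}
        V = dense_marginal_cov(series, df["year"].to_numpy(float), sds, 0.35, sigma_e, factors)
        X = np.column_stack(
            [np.ones(len(df)), df["co2_anom"].to_numpy(), df["mat_anom"].to_numpy()]
        )
        beta = dense_gls(df["N"].to_numpy(float), X, V)
        est = [fit.fixed_effects[nm][0] for nm in ["intercept", "co2_anom", "mat_anom"]]
        assert np.allclose(est, beta, atol=1e-6)


class TestStepwise:
    def test_single_significant_term_kept(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N")
        fit = stepwise_select(design, ["co2_anom"])
        assert "co2_anom" in fit.x_names

    def test_true_driver_selected_and_spurious_dropped(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N")
        fit = stepwise_select(design, design.anomaly_terms)
        assert "co2_anom" in fit.x_names

    def test_null_panel_returns_year_model_with_warning(self):
        cfg = small_scenario(seed=55, beta={e: {} for e in ft.ELEMENTS})
        sites = ft.make_sites(cfg)
        drivers = ft.generate_drivers(cfg, sites)
        panel = ft.generate_panel(cfg, drivers, sites)
        design = build_attribution_design(panel, drivers, "N")
        with pytest.warns(UserWarning, match="null model"):
            fit = stepwise_select(design, ["map_anom"], alpha=1e-6)
        assert "_year_c" in fit.x_names


class TestR2:
    def test_noiseless_fixed_only_r2_is_one(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N")
        df = design.data.copy()
        df["N"] = 1.0 + 0.5 * df["co2_anom"]
        d2 = ft.AttributionDesign(df, "N")
        fit = fit_glmm_arma(d2, ["co2_anom"])
        marg, cond = r2_glmm(fit)
        assert marg == pytest.approx(1.0, abs=1e-6)
        assert cond == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_marginal_near_zero(self, small_data):
        _, _, drivers, panel = small_data
        rng = np.random.default_rng(2)
        design = build_attribution_design(panel, drivers, "N")
        df = design.data.copy()
        df["N"] = rng.normal(size=len(df))
        d2 = ft.AttributionDesign(df, "N")
        fit = fit_glmm_arma(d2, ["co2_anom"])
        marg, cond = r2_glmm(fit)
        assert marg < 0.02

    def test_random_intercept_only_closed_form(self):
        # conditional ~= sigma_r^2 / (sigma_r^2 + sigma_e^2), marginal ~= 0
        cfg = small_scenario(
            seed=77, beta={e: {} for e in ft.ELEMENTS},
            n_countries=8, plots_per_country=6,
            sigma_country=0.0, sigma_plot=2.0, sigma_species=0.0,
            sigma_resid=1.0, phi=0.0,
        )
        sites = ft.make_sites(cfg)
        drivers = ft.generate_drivers(cfg, sites)
        panel = ft.generate_panel(cfg, drivers, sites)
        design = build_attribution_design(panel, drivers, "N")
        fit = fit_glmm_arma(design, ["co2_anom"])
        marg, cond = r2_glmm(fit)
        assert marg < 0.02
        assert cond == pytest.approx(4.0 / 5.0, abs=0.1)

    def test_marginal_le_conditional(self, small_data):
        _, _, drivers, panel = small_data
        design = build_attribution_design(panel, drivers, "N")
        fit = fit_glmm_arma(design, design.anomaly_terms)
        marg, cond = r2_glmm(fit)
        assert 0.0 <= marg <= cond <= 1.0


class TestContributions:
    def test_decomposition_identity_exact(self, small_data):
        _, _, drivers, panel = small_data
        table = ft.attribute_element(panel, drivers, "N", terms="mains", stepwise=False)
        assert table.total - table.observed_trend.slope == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generator_truth(self, small_data):
        # single-seed sanity bound (3 SE); frequency coverage is checked
        # over many panels in the acceptance suite
        cfg, _, drivers, panel = small_data
        table = ft.attribute_element(panel, drivers, "N", terms="mains")
        truth = ft.true_contributions(cfg, drivers, "N").set_index("predictor")
        co2 = next(e for e in table.entries if e.predictor == "co2")
        assert co2.contribution < 0
        assert abs(co2.contribution - truth.loc["co2", "contribution"]) <= 3 * co2.se

    def test_zero_trend_predictor_contributes_nothing(self):
        cfg = small_scenario(
            seed=88,
            beta={e: ({"co2": -0.023, "mat": 0.3} if e == "N" else {}) for e in ft.ELEMENTS},
            mat_trend_by_region={"north": 0.0, "central": 0.0, "south": 0.0},
        )
        sites = ft.make_sites(cfg)
        drivers = ft.generate_drivers(cfg, sites)
        panel = ft.generate_panel(cfg, drivers, sites)
        table = ft.attribute_element(
            panel, drivers, "N", terms=["co2_anom", "mat_anom"], stepwise=False
        )
        mat = next(e for e in table.entries if e.predictor == "mat")
        # mat varies interannually but has no trend: tiny contribution
        assert abs(mat.contribution) <= 3 * mat.se + 1e-3

    def test_freezing_constant_predictor_is_noop(self, small_data):
        _, _, drivers, panel = small_data
        import itertools

        design = build_attribution_design(panel, drivers, "N")
        df = design.data.copy()
        df["mat_anom"] = 0.0
        df["mat_mean_x_anom"] = df["mat_mean"] * df["mat_anom"]
        for a, b in itertools.combinations(design.drivers, 2):
            if "mat" in (a, b):
                df[f"{a}_anom_x_{b}_anom"] = df[f"{a}_anom"] * df[f"{b}_anom"]
        frozen = _frozen_frame(df, design.drivers, "mat")
        pd.testing.assert_frame_equal(frozen, df)

    def test_unselected_predictor_reported_as_exact_zero(self, small_data):
        _, _, drivers, panel = small_data
        table = ft.attribute_element(panel, drivers, "N", terms="mains")
        for e in table.entries:
            if e.predictor not in {
                d for d in table.provenance.get("selected_terms", [])
            } and f"{e.predictor}_anom" not in table.provenance.get("selected_terms", []):
                assert e.contribution == 0.0
                assert e.se == 0.0

    def test_noiseless_closure_recovers_truth_exactly(self):
        # generator -> estimator closure: on a noiseless panel the estimated
        # CO2 contribution equals beta * (CO2 trend) to 1e-6
        cfg = small_scenario(
            seed=0, sigma_country=0.0, sigma_plot=0.0, sigma_species=0.0,
            sigma_resid=0.0, phi=0.0, driver_noise_sd={},
            beta={e: ({"co2": -0.004} if e == "N" else {}) for e in ft.ELEMENTS},
        )
        sites = ft.make_sites(cfg)
        drivers = ft.generate_drivers(cfg, sites)
        panel = ft.generate_panel(cfg, drivers, sites)
        table = ft.attribute_element(
            panel, drivers, "N", terms=["co2_anom"], stepwise=False
        )
        truth = ft.true_contributions(cfg, drivers, "N").set_index("predictor")
        co2 = next(e for e in table.entries if e.predictor == "co2")
        assert co2.contribution == pytest.approx(
            truth.loc["co2", "contribution"], abs=1e-6
        )
        assert co2.contribution == pytest.approx(-0.004 * 50.0 / 26.0, abs=1e-6)
        assert abs(table.unknown) < 1e-6

    def test_null_betas_leave_everything_unknown(self):
        cfg = small_scenario(seed=99, beta={e: {} for e in ft.ELEMENTS})
        sites = ft.make_sites(cfg)
        drivers = ft.generate_drivers(cfg, sites)
        panel = ft.generate_panel(cfg, drivers, sites)
        table = ft.attribute_element(panel, drivers, "N", terms="mains")
        total_attr = sum(abs(e.contribution) for e in table.entries)
        assert abs(table.unknown - table.observed_trend.slope) == pytest.approx(
            total_attr, abs=1e-9
        )
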