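import numpy as np
import pandas as pd
import pytest

import foliartrends as ft


@pytest.fixture(scope="session")
def scenario():
    """Canonical study conditions with a fixed seed."""
    return ft.default_scenario(seed=42)


@pytest.fixture(scope="session")
def scenario_data(scenario):
    sites = ft.make_sites(scenario)
    drivers = ft.generate_drivers(scenario, sites)
    panel = ft.generate_panel(scenario, drivers, sites)
    return scenario, sites, drivers, panel


def tiny_panel(
    n_plots=3,
    n_years=8,
    slope=-0.5,
    sigma_plot=0.0,
    sigma_resid=0.0,
    phi=0.0,
    baseline=20.0,
    seed=0,
    n_species=1,
):
    """Small hand-rolled panel: element 'N' linear in year plus noise."""
    rng = np.random.default_rng(seed)
    rows = []
    years = np.arange(2000, 2000 + n_years)
    for p in range(n_plots):
        u_p = rng.normal(0, sigma_plot) if sigma_plot else 0.0
        for s in range(n_species):
            e = np.zeros(n_years)
            if sigma_resid:
                e[0] = rng.normal(0, sigma_resid)
                for i in range(1, n_years):
                    e[i] = phi * e[i - 1] + rng.normal(
                        0, sigma_resid * np.sqrt(1 - phi**2)
                    )
            for i, yr in enumerate(years):
                rows.append(
                    {
                        "country": "C0",
                        "plot": f"P{p}",
                        "species": f"SP{s}",
                        "tree": "T0",
                        "latitude": 50.0,
                        "longitude": 10.0,
                        "year": int(yr),
                        "N": baseline + slope * (yr - years[0]) + u_p + e[i],
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def make_tiny_panel():
    return tiny_panel
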