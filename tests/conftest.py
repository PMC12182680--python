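import numpy as np
import pandas as pd
import pytest

from forestcarbon.grids import Grid
from forestcarbon.growth import GrowthFit
from forestcarbon.synthetic import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 20x20 world shared by read-only tests."""
    return generate_world(SyntheticConfig(seed=7, grid_rows=20, grid_cols=20))


@pytest.fixture(scope="session")
def default_world():
    """The 50x50 default-condition world (generated once per session)."""
    return generate_world(SyntheticConfig(seed=11))


@pytest.fixture
def grid4():
    return Grid(rows=4, cols=4, cell_size=0.1, lat_origin=30.0)


@pytest.fixture
def mm_fit():
    return GrowthFit(family="MM", mu=80.0, k=200.0, a=1.0, b=0.5, d=2.0)


def random_scene(seed, rows=8, cols=8, n_types=3):
    """A random small world-state for scenario-engine audits.

    Returns (grid, types, age, prob, mtss, fits, climate_now, climate_future).
    Drawn broadly (uniform suitability, varied thresholds) to exercise all
    remain/replace/lose branches.
    """
    rng = np.random.default_rng(seed)
    grid = Grid(rows=rows, cols=cols, cell_size=0.1,
                lat_origin=float(rng.uniform(-50, 50)))
    codes = list(range(1, n_types + 1))
    types = rng.choice([0] + codes, size=(rows, cols),
                       p=[0.3] + [0.7 / n_types] * n_types)
    age = np.where(types > 0, rng.integers(1, 140, (rows, cols)).astype(float),
                   np.nan)
    prob = {c: rng.random((rows, cols)) for c in codes}
    mtss = {c: float(rng.uniform(0.2, 0.8)) for c in codes}
    fits = {}
    for c in codes:
        fam = ("MM", "MO", "L")[c % 3]
        kw = dict(mu=float(rng.uniform(40, 200)), a=float(rng.uniform(-2, 4)),
                  b=float(rng.uniform(-0.05, 0.08)), d=float(rng.uniform(-30, 30)))
        if fam == "MM":
            fits[c] = GrowthFit(family="MM", k=float(rng.uniform(30, 400)), **kw)
        else:
            fits[c] = GrowthFit(family=fam, c=float(rng.uniform(1, 30)),
                                alpha=float(rng.uniform(0.01, 0.5)), **kw)
    clim_now = {"mat": rng.uniform(5, 25, (rows, cols)),
                "map": rng.uniform(300, 1600, (rows, cols))}
    clim_fut = {"mat": clim_now["mat"] + rng.uniform(0.5, 4.0),
                "map": clim_now["map"] + rng.uniform(-50, 120)}
    return grid, types, age, prob, mtss, fits, clim_now, clim_fut


def survey_from(family, params, a, b, d, n, noise_sd, seed):
    """Draw a survey table from a known growth law (test-side generator)."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(1, 150, n)
    mat = rng.uniform(12, 26, n)
    map_mm = rng.uniform(400, 1500, n)
    if family == "MM":
        f = params["mu"] * t / (params["k"] + t)
    elif family == "MO":
        f = params["mu"] * (1 - params["c"] * np.exp(-params["alpha"] * t))
    else:
        f = params["mu"] / (1 + params["c"] * np.exp(-params["alpha"] * t))
    agb = f + a * mat + b * map_mm + d + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"type": 1, "t": t, "agb": agb, "mat": mat, "map": map_mm})
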