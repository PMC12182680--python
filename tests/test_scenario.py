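import numpy as np
import pandas as pd
import pytest

from forestcarbon.errors import ConfigError, DataError, FitError
from forestcarbon.grids import cell_area_ha
from forestcarbon.growth import GrowthFit
from forestcarbon.habitat import SuitabilityStack
from forestcarbon.scenario import (FLAG_LOST, FLAG_PLANTED, FLAG_REMAINED,
                                   FLAG_REPLACED, ForestState, ScenarioSpec,
                                   allocate_afforestation, baseline_state,
                                   fit_area_targets, required_afforestation,
                                   run_ensemble, step_nature)

from _oracles import afforestation_oracle, nature_oracle
from conftest import random_scene


def _nature(seed, **spec_kw):
    grid, types, age, prob, mtss, fits, now, fut = random_scene(seed)
    spec = ScenarioSpec(period="2050s", ssp="ssp245", **spec_kw)
    base = baseline_state(grid, types, age, fits, now)
    stack = SuitabilityStack(prob=prob, mtss=mtss)
    out = step_nature(base, stack, now, fut, fits, F=1.1, spec=spec)
    return grid, types, age, prob, mtss, fits, now, fut, spec, base, stack, out


# --- nature scenario --------------------------------------------------------


def test_remain_rule_extends_age_by_N():
    grid, types, age, *_ , spec, base, stack, out = _nature(1)
    remained = out.flags == FLAG_REMAINED
    if remained.any():
        assert np.array_equal(out.types[remained], types[remained])
        assert np.allclose(out.age[remained], age[remained] + spec.n_years)


def test_replaced_pixels_get_half_age_and_qualifying_other_type():
    for seed in range(8):
        grid, types, age, prob, mtss, *_ , spec, base, stack, out = _nature(seed)
        replaced = out.flags == FLAG_REPLACED
        for r, c in zip(*np.nonzero(replaced)):
            new = out.types[r, c]
            assert new != types[r, c]
            assert prob[new][r, c] > mtss[new]
            assert out.age[r, c] == spec.half_age


def test_partition_remained_replaced_lost_is_exact():
    for seed in range(10):
        grid, types, *_ , out = _nature(seed)
        n_forest0 = int((types > 0).sum())
        n_outcomes = sum(int((out.flags == f).sum()) for f in
                         (FLAG_REMAINED, FLAG_REPLACED, FLAG_LOST))
        assert n_outcomes == n_forest0


def test_nature_never_creates_forest():
    for seed in range(10):
        grid, types, *_ , out = _nature(seed)
        assert not (out.forest & (types == 0)).any()


def test_additivity_and_nonforest_zero_components():
    grid, *_ , out = _nature(2)
    assert np.allclose(out.c_total, out.c_age + out.c_climate + out.c_co2,
                       rtol=1e-12, atol=1e-12)
    nonforest = ~out.forest
    assert np.all(out.c_age[nonforest] == 0)
    assert np.all(out.c_total[nonforest] == 0)
    assert np.isnan(out.age[nonforest]).all()


def test_missing_suitability_layer_is_config_error():
    grid, types, age, prob, mtss, fits, now, fut = random_scene(3)
    base = baseline_state(grid, types, age, fits, now)
    del prob[1], mtss[1]
    stack = SuitabilityStack(prob=prob, mtss=mtss)
    if (types == 1).any():
        with pytest.raises(ConfigError):
            step_nature(base, stack, now, fut, fits, 1.0,
                        ScenarioSpec(period="2050s", ssp="ssp245"))


def test_nature_engine_matches_literal_oracle():
    for seed in range(25):
        grid, types, age, prob, mtss, fits, now, fut, spec, base, stack, out = \
            _nature(seed)
        want = nature_oracle(types, age, prob, mtss, fits, now["mat"],
                             now["map"], fut["mat"], fut["map"], 1.1,
                             spec.n_years, spec.half_age)
        assert np.array_equal(out.types, want["types"])
        assert np.array_equal(out.flags, want["flag"])
        assert np.allclose(out.age, want["age"], equal_nan=True)
        for k in ("c_age", "c_climate", "c_co2"):
            assert np.allclose(getattr(out, k), want[k], atol=1e-10)


# --- area targets -----------------------------------------------------------


def test_two_point_line_and_prediction():
    model = fit_area_targets(pd.DataFrame({"year": [2025, 2035],
                                           "area_mha": [200.0, 210.0]}))
    assert model.slope == pytest.approx(1.0)
    assert model.predict(2050) == pytest.approx(225.0)
    assert model.r2 == pytest.approx(1.0)
    assert model.rmse == pytest.approx(0.0, abs=1e-9)


def test_noisy_series_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    years = np.arange(2020, 2071, 5).astype(float)
    area = 180 + 2.0 * (years - 2020) + rng.normal(0, 2.5, len(years))
    model = fit_area_targets(pd.DataFrame({"year": years, "area_mha": area}))
    X = np.column_stack([years, np.ones_like(years)])
    beta = np.linalg.solve(X.T @ X, X.T @ area)
    assert model.slope == pytest.approx(beta[0], rel=1e-10)
    assert model.intercept == pytest.approx(beta[1], rel=1e-10)


def test_degenerate_series_raises():
    with pytest.raises(FitError):
        fit_area_targets(pd.DataFrame({"year": [2020], "area_mha": [100.0]}))
    with pytest.raises(FitError):
        fit_area_targets(pd.DataFrame({"year": [2020, 2020],
                                       "area_mha": [100.0, 110.0]}))


def test_required_afforestation_clips_at_zero():
    assert required_afforestation(100.0, 80.0) == 20.0
    assert required_afforestation(100.0, 120.0) == 0.0
    with pytest.raises(DataError):
        required_afforestation(-1.0, 0.0)


# --- afforestation allocation ----------------------------------------------


def _aff_inputs(seed):
    grid, types, age, prob, mtss, fits, now, fut = random_scene(seed)
    spec = ScenarioSpec(period="2050s", ssp="ssp245")
    base = baseline_state(grid, types, age, fits, now)
    stack = SuitabilityStack(prob=prob, mtss=mtss)
    nat = step_nature(base, stack, now, fut, fits, 1.1, spec)
    return grid, prob, mtss, fits, now, fut, spec, stack, nat


def test_zero_demand_is_identity():
    grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(4)
    out = allocate_afforestation(nat, stack, 0.0, fits, now, fut, 1.1, spec, seed=0)
    assert np.array_equal(out.types, nat.types)
    assert np.array_equal(out.flags, nat.flags)


def test_full_demand_plants_every_candidate():
    grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(5)
    from forestcarbon.habitat import best_type_grid
    best, _ = best_type_grid(stack)
    candidates = (~nat.forest) & (best > 0)
    total = float(cell_area_ha(grid)[candidates].sum() / 1e6)
    out = allocate_afforestation(nat, stack, total, fits, now, fut, 1.1, spec, 0)
    assert int((out.flags == FLAG_PLANTED).sum()) == int(candidates.sum())


def test_allocation_determinism_and_demand_bookkeeping():
    grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(6)
    areas = cell_area_ha(grid) / 1e6
    demand = float(areas.mean() * 5)  # ~5 pixels worth
    a = allocate_afforestation(nat, stack, demand, fits, now, fut, 1.1, spec, 42)
    b = allocate_afforestation(nat, stack, demand, fits, now, fut, 1.1, spec, 42)
    assert np.array_equal(a.types, b.types)
    planted = a.flags == FLAG_PLANTED
    got = float(areas[planted].sum())
    assert got >= demand                      # demand met ...
    assert got - demand <= areas.max() + 1e-12  # ... within one pixel-area


def test_monotone_demand_never_plants_fewer():
    grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(7)
    areas = cell_area_ha(grid) / 1e6
    planted_counts = []
    for k in (1, 3, 6, 10):
        out = allocate_afforestation(nat, stack, float(areas.mean() * k),
                                     fits, now, fut, 1.1, spec, seed=9)
        planted_counts.append(int((out.flags == FLAG_PLANTED).sum()))
    assert planted_counts == sorted(planted_counts)


def test_planted_pixels_satisfy_mtss_and_half_age():
    grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(8)
    areas = cell_area_ha(grid) / 1e6
    out = allocate_afforestation(nat, stack, float(areas.mean() * 8),
                                 fits, now, fut, 1.1, spec, seed=1)
    for r, c in zip(*np.nonzero(out.flags == FLAG_PLANTED)):
        code = out.types[r, c]
        assert prob[code][r, c] > mtss[code]
        assert out.age[r, c] == spec.half_age


def test_afforestation_engine_matches_literal_oracle():
    for seed in range(15):
        grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(seed)
        areas = cell_area_ha(grid) / 1e6
        demand = float(areas.mean() * (seed % 7 + 1))
        out = allocate_afforestation(nat, stack, demand, fits, now, fut, 1.1,
                                     spec, seed=seed * 13)
        nat_dict = {"types": nat.types, "age": nat.age, "c_age": nat.c_age,
                    "c_climate": nat.c_climate, "c_co2": nat.c_co2}
        want = afforestation_oracle(nat_dict, prob, mtss, fits, now["mat"],
                                    now["map"], fut["mat"], fut["map"], 1.1,
                                    demand, areas, spec.half_age, seed * 13)
        assert np.array_equal(out.types, want["types"])
        assert np.allclose(out.age, want["age"], equal_nan=True)
        for k in ("c_age", "c_climate", "c_co2"):
            assert np.allclose(getattr(out, k), want[k], atol=1e-10)
        assert np.array_equal(out.flags == FLAG_PLANTED, want["planted"])


# --- ensembles --------------------------------------------------------------


def test_ensemble_mean_equals_explicit_average():
    grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(9)
    areas = cell_area_ha(grid) / 1e6
    demand = float(areas.mean() * 4)
    spec.seeds = tuple(range(10))
    states, table = run_ensemble(nat, stack, demand, fits, now, fut, 1.1, spec)
    reps = table[~table["seed"].isin(["mean", "sd"])]
    mean_row = table[table["seed"] == "mean"].iloc[0]
    assert len(states) == 10
    assert mean_row["total_agb_pgc"] == pytest.approx(
        reps["total_agb_pgc"].mean(), rel=1e-12)


def test_single_seed_ensemble_mean_is_that_run():
    grid, prob, mtss, fits, now, fut, spec, stack, nat = _aff_inputs(10)
    spec.seeds = (3,)
    areas = cell_area_ha(grid) / 1e6
    states, table = run_ensemble(nat, stack, float(areas.mean() * 2), fits,
                                 now, fut, 1.1, spec)
    rep = table.iloc[0]
    mean_row = table[table["seed"] == "mean"].iloc[0]
    sd_row = table[table["seed"] == "sd"].iloc[0]
    assert mean_row["total_agb_pgc"] == pytest.approx(rep["total_agb_pgc"])
    assert sd_row["total_agb_pgc"] == pytest.approx(0.0, abs=1e-15)


def test_zero_candidates_all_replicates_identical():
    grid, types, age, prob, mtss, fits, now, fut = random_scene(11)
    # make every pixel unsuitable for every type
    mtss = {c: 0.99 for c in mtss}
    prob = {c: np.minimum(p, 0.9) for c, p in prob.items()}
    stack = SuitabilityStack(prob=prob, mtss=mtss)
    base = baseline_state(grid, types, age, fits, now)
    spec = ScenarioSpec(period="2050s", ssp="ssp245", seeds=tuple(range(5)))
    nat = step_nature(base, stack, now, fut, fits, 1.1, spec)
    states, table = run_ensemble(nat, stack, 5.0, fits, now, fut, 1.1, spec)
    sd_row = table[table["seed"] == "sd"].iloc[0]
    assert sd_row["total_agb_pgc"] == pytest.approx(0.0, abs=1e-15)


def test_spec_validation():
    with pytest.raises(ConfigError):
        ScenarioSpec(period="2090s", ssp="ssp245")
    with pytest.raises(ConfigError):
        ScenarioSpec(period="2050s", ssp="ssp245", n_years=0)
    assert ScenarioSpec(period="2070s", ssp="ssp585").n_years == 50
    assert ScenarioSpec(period="2050s", ssp="ssp245", n_years=25).half_age == 12
    assert ScenarioSpec(period="2050s", ssp="ssp245", n_years=25,
                        round_half_age=False).half_age == 12.5
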