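"""Per-pixel forest projection: nature and afforestation scenarios.

Nature scenario (no human intervention, no disturbances), per 2020 forest
pixel of type A with stand age t, projected N years:

  (i)  if the pixel's future suitability for A exceeds A's MTSS, the stand
       remains: age becomes t + N and biomass components are recomputed
       (age component at future age with 2020 climate; climate component
       as the future-climate minus baseline-climate difference; CO2
       component as (F - 1) times the age component);
  (ii) otherwise the most-suitable *other* qualifying type B replaces it
       at stand age N/2;
  (iii) otherwise the pixel is lost (becomes non-forest).

Non-forest pixels never gain forest under the nature scenario.

Afforestation scenario: a linear regression of policy area targets gives
the period's target; the shortfall versus the nature-scenario remaining
area is planted on uniformly random suitable non-forest pixels (the
most-suitable type, age N/2), repeated over an ensemble of seeds and
averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, FitError, ShapeError
from .grids import Grid, cell_area_ha
from .growth import GrowthFit, age_component, climate_component, eval_age_climate
from .co2 import co2_component
from .habitat import SuitabilityStack, best_type_grid

log = logging.getLogger(__name__)

# pixel outcome flags
FLAG_NONE = 0
FLAG_REMAINED = 1
FLAG_REPLACED = 2
FLAG_LOST = 3
FLAG_PLANTED = 4

#: years elapsed since the 2020 baseline at each period's midpoint
DEFAULT_N_YEARS = {"2030s": 10, "2050s": 30, "2070s": 50}


@dataclass
class ScenarioSpec:
    period: str
    ssp: str
    n_years: int | None = None
    seeds: tuple[int, ...] = tuple(range(10))
    round_half_age: bool = True     # N/2 rounded to nearest whole year

    def __post_init__(self) -> None:
        if self.n_years is None:
            if self.period not in DEFAULT_N_YEARS:
                raise ConfigError(f"no default N for period {self.period!r}")
            self.n_years = DEFAULT_N_YEARS[self.period]
        if self.n_years <= 0:
            raise ConfigError("N (years elapsed) must be positive")

    @property
    def half_age(self) -> float:
        half = self.n_years / 2.0
        return float(round(half)) if self.round_half_age else half


@dataclass
class ForestState:
    """Per-pixel forest state: type, age, and AGB components (Mg/ha)."""

    grid: Grid
    types: np.ndarray          # int codes, 0 = non-forest
    age: np.ndarray            # float years, NaN where non-forest
    c_age: np.ndarray
    c_climate: np.ndarray
    c_co2: np.ndarray
    flags: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        for name in ("types", "age", "c_age", "c_climate", "c_co2"):
            self.grid.check(getattr(self, name), name)
        if self.flags is None:
            self.flags = np.zeros(self.grid.shape, dtype=np.uint8)

    @property
    def c_total(self) -> np.ndarray:
        return self.c_age + self.c_climate + self.c_co2

    @property
    def forest(self) -> np.ndarray:
        return self.types > 0

    def copy(self) -> "ForestState":
        return ForestState(grid=self.grid, types=self.types.copy(),
                           age=self.age.copy(), c_age=self.c_age.copy(),
                           c_climate=self.c_climate.copy(),
                           c_co2=self.c_co2.copy(), flags=self.flags.copy())


def _components_for(fit: GrowthFit, t, mat0, map0, mat_f, map_f, F: float):
    """Age / climate / CO2 components for stands of one type."""
    c_age = age_component(fit, t, mat0, map0)
    c_ac = eval_age_climate(fit, t, mat_f, map_f)
    c_cl = climate_component(c_ac, c_age)
    c_co2 = co2_component(F, c_age)
    return c_age, c_cl, c_co2


def baseline_state(grid: Grid, types: np.ndarray, age: np.ndarray,
                   fits: dict[int, GrowthFit], climate_now: dict,
                   F_baseline: float = 1.0) -> ForestState:
    """2020 baseline: components from each type's fit at current age/climate."""
    types = grid.check(np.asarray(types, int), "types")
    age = grid.check(np.asarray(age, float), "age")
    c_age = np.zeros(grid.shape)
    c_cl = np.zeros(grid.shape)
    c_co2 = np.zeros(grid.shape)
    mat0, map0 = climate_now["mat"], climate_now["map"]
    for code, fit in fits.items():
        sel = types == code
        if not sel.any():
            continue
        ca, cc, co = _components_for(fit, age[sel], mat0[sel], map0[sel],
                                     mat0[sel], map0[sel], F_baseline)
        c_age[sel], c_cl[sel], c_co2[sel] = ca, cc, co
    age_out = np.where(types > 0, age, np.nan)
    return ForestState(grid=grid, types=types, age=age_out,
                       c_age=c_age, c_climate=c_cl, c_co2=c_co2)


def step_nature(state2020: ForestState, suit: SuitabilityStack,
                climate_now: dict, climate_future: dict,
                fits: dict[int, GrowthFit], F: float,
                spec: ScenarioSpec) -> ForestState:
    """Project the 2020 state N years forward under the nature scenario."""
    grid = state2020.grid
    for arr in (climate_future["mat"], climate_future["map"]):
        grid.check(arr, "future climate")
    occupied = sorted(np.unique(state2020.types[state2020.forest]))
    missing = [c for c in occupied if c not in suit.prob]
    if missing:
        raise ConfigError(f"no suitability layer for occupied types {missing}")
    missing_fits = [c for c in occupied if c not in fits]
    if missing_fits:
        raise ConfigError(f"no growth fit for occupied types {missing_fits}")

    types0 = state2020.types
    forest0 = state2020.forest
    remain = np.zeros(grid.shape, bool)
    for code in occupied:
        remain |= forest0 & (types0 == code) & suit.suitable_mask(code)

    # replacement candidates: best *other* qualifying type
    repl_code, _ = best_type_grid(suit, exclude=types0)
    replaced = forest0 & ~remain & (repl_code > 0)
    lost = forest0 & ~remain & ~replaced

    new_types = np.zeros(grid.shape, int)
    new_types[remain] = types0[remain]
    new_types[replaced] = repl_code[replaced]

    new_age = np.full(grid.shape, np.nan)
    new_age[remain] = state2020.age[remain] + spec.n_years
    new_age[replaced] = spec.half_age

    c_age = np.zeros(grid.shape)
    c_cl = np.zeros(grid.shape)
    c_co2 = np.zeros(grid.shape)
    mat0, map0 = climate_now["mat"], climate_now["map"]
    mat_f, map_f = climate_future["mat"], climate_future["map"]
    for code in sorted(np.unique(new_types[new_types > 0])):
        sel = new_types == code
        ca, cc, co = _components_for(fits[code], new_age[sel], mat0[sel],
                                     map0[sel], mat_f[sel], map_f[sel], F)
        c_age[sel], c_cl[sel], c_co2[sel] = ca, cc, co

    flags = np.zeros(grid.shape, np.uint8)
    flags[remain] = FLAG_REMAINED
    flags[replaced] = FLAG_REPLACED
    flags[lost] = FLAG_LOST
    return ForestState(grid=grid, types=new_types, age=new_age, c_age=c_age,
                       c_climate=c_cl, c_co2=c_co2, flags=flags)


# ---------------------------------------------------------------------------
# afforestation


@dataclass(frozen=True)
class AreaTargetModel:
    """First-order linear fit of policy forest-area targets over time."""

    slope: float       # Mha / year
    intercept: float   # Mha at year 0
    r2: float
    rmse: float
    n: int

    def predict(self, year: float) -> float:
        return self.slope * year + self.intercept


def fit_area_targets(series: pd.DataFrame) -> AreaTargetModel:
    """OLS line through (year, area_mha) points."""
    years = np.asarray(series["year"], float)
    area = np.asarray(series["area_mha"], float)
    if len(years) < 2 or np.ptp(years) == 0:
        raise FitError("area-target regression needs >= 2 distinct years")
    res = stats.linregress(years, area)
    pred = res.slope * years + res.intercept
    rmse = float(np.sqrt(np.mean((area - pred) ** 2)))
    tss = float(((area - area.mean()) ** 2).sum())
    r2 = 1.0 - float(((area - pred) ** 2).sum()) / tss if tss > 0 else 1.0
    return AreaTargetModel(slope=float(res.slope), intercept=float(res.intercept),
                           r2=r2, rmse=rmse, n=len(years))


def required_afforestation(target_mha: float, remaining_mha: float) -> float:
    """Planting demand: target minus what the nature scenario retains, >= 0."""
    if target_mha < 0 or remaining_mha < 0:
        raise DataError("areas must be non-negative")
    return max(target_mha - remaining_mha, 0.0)


def allocate_afforestation(state_nature: ForestState, suit: SuitabilityStack,
                           area_needed_mha: float, fits: dict[int, GrowthFit],
                           climate_now: dict, climate_future: dict, F: float,
                           spec: ScenarioSpec, seed: int) -> ForestState:
    """Plant the demand on uniformly random suitable non-forest pixels.

    Candidates are pixels non-forest in the nature-scenario result where at
    least one type qualifies (P > MTSS). Pixels are drawn without
    replacement until the cumulative spherical pixel area meets the demand
    or candidates run out (shortfall logged). Each planted pixel gets its
    most-suitable type at stand age N/2.
    """
    if area_needed_mha < 0:
        raise DataError("area_needed must be >= 0")
    out = state_nature.copy()
    if area_needed_mha == 0:
        return out
    grid = state_nature.grid
    best_code, _ = best_type_grid(suit)
    candidates = (~state_nature.forest) & (best_code > 0)
    idx = np.flatnonzero(candidates)
    if idx.size == 0:
        log.warning("afforestation: no suitable candidates at all")
        return out
    rng = np.random.default_rng(seed)
    order = rng.permutation(idx)
    areas_mha = cell_area_ha(grid).ravel()[order] / 1e6
    cum = np.cumsum(areas_mha)
    n_take = int(np.searchsorted(cum, area_needed_mha) + 1)
    if n_take > len(order):
        n_take = len(order)
        log.warning("afforestation shortfall: %.3f of %.3f Mha available",
                    cum[-1], area_needed_mha)
    chosen = order[:n_take]
    rows, cols = np.unravel_index(chosen, grid.shape)

    out.types[rows, cols] = best_code[rows, cols]
    out.age[rows, cols] = spec.half_age
    out.flags[rows, cols] = FLAG_PLANTED
    mat0, map0 = climate_now["mat"], climate_now["map"]
    mat_f, map_f = climate_future["mat"], climate_future["map"]
    for code in np.unique(best_code[rows, cols]):
        sel = (out.flags == FLAG_PLANTED) & (out.types == code)
        ca, cc, co = _components_for(fits[code], out.age[sel], mat0[sel],
                                     map0[sel], mat_f[sel], map_f[sel], F)
        out.c_age[sel], out.c_climate[sel], out.c_co2[sel] = ca, cc, co
    return out


def run_ensemble(state_nature: ForestState, suit: SuitabilityStack,
                 area_needed_mha: float, fits: dict[int, GrowthFit],
                 climate_now: dict, climate_future: dict, F: float,
                 spec: ScenarioSpec,
                 summarize=None) -> tuple[list[ForestState], pd.DataFrame]:
    """Repeat the random allocation once per seed; summarize each replicate.

    Returns the replicate states and a table with one row per replicate
    plus the across-replicate mean and standard deviation (ddof=0 for a
    single replicate, else ddof=1).
    """
    from .summaries import summarize_state
    summarize = summarize or summarize_state
    states, rows = [], []
    for seed in spec.seeds:
        st = allocate_afforestation(state_nature, suit, area_needed_mha, fits,
                                    climate_now, climate_future, F, spec, seed)
        states.append(st)
        row = summarize(st)
        row["seed"] = seed
        rows.append(row)
    table = pd.DataFrame(rows)
    numeric = table.drop(columns=["seed"]).select_dtypes("number")
    ddof = 1 if len(states) > 1 else 0
    mean = numeric.mean()
    sd = numeric.std(ddof=ddof)
    stat_rows = pd.DataFrame([mean, sd])
    stat_rows["seed"] = ["mean", "sd"]
    table = pd.concat([table, stat_rows], ignore_index=True)
    return states, table
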