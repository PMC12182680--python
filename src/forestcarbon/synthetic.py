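"""Synthetic world generator: every pipeline input, with known ground truth.

The generator fabricates, on one shared grid, the full data model the
projection pipeline consumes:

* a biomass-age survey table drawn from known growth laws plus a linear
  climate term and Gaussian noise;
* three partially discordant categorical cover products and a fractional
  tree-cover field;
* three stand-age products with controlled null fractions (the rank-3
  product is a 2010-vintage map, stored 10 years young);
* smooth MAT/MAP climate fields and per-period/SSP future deltas;
* per-type habitat-suitability surfaces (logistic in the squared
  standardized climate distance from a type-specific optimum) with MTSS
  thresholds set so a known fraction of cells qualifies;
* yearly CO2 trajectories per SSP, a 12-member ensemble of saturating
  cVeg-vs-CO2 curves, and a near-linear forest-area target series.

Everything is drawn from one seeded generator, so a (config, seed) pair
yields a bit-identical world.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import grids
from .co2 import CO2Trajectory, CVegCurve
from .errors import ConfigError
from .fusion import AgeProduct, CoverProduct, forest_mask
from .grids import Grid
from .habitat import SuitabilityStack
from .typology import Typology, default_typology

PERIODS = ("2030s", "2050s", "2070s")
SSPS = ("ssp245", "ssp585")

#: (dMAT degC, dMAP mm) applied to the baseline climate per period x SSP —
#: magnitudes in line with CMIP6 ensemble projections for East Asia
DEFAULT_CLIMATE_DELTA = {
    ("2030s", "ssp245"): (0.8, 20.0),
    ("2050s", "ssp245"): (1.5, 40.0),
    ("2070s", "ssp245"): (2.2, 60.0),
    ("2030s", "ssp585"): (1.0, 25.0),
    ("2050s", "ssp585"): (2.4, 55.0),
    ("2070s", "ssp585"): (3.8, 90.0),
}

#: quadratic ppm(year) coefficients (ppm2020, linear, quadratic in years
#: since 2020): moderate pathway flattens (~550 ppm by 2080), high pathway
#: accelerates (~750 ppm by 2080)
DEFAULT_CO2_PARAMS = {
    "ssp245": (415.0, 2.6, -0.0065),
    "ssp585": (415.0, 1.9, 0.062),
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    grid_rows: int = 50
    grid_cols: int = 50
    cell_size: float = 0.1          # degrees
    lat_origin: float = 25.0        # degrees N, south edge
    lon_origin: float = 100.0
    n_types: int = 5
    survey_n: int = 200             # records per forest type
    survey_noise_sd: float = 10.0   # Mg/ha
    survey_age_range: tuple[float, float] = (1.0, 150.0)
    product_disagreement_rate: float = 0.10   # expected pairwise rate
    age_null_fraction: tuple[float, float, float] = (0.15, 0.30, 0.0)
    age_noise_sd: float = 5.0       # years, rank-2 age product
    climate_delta: dict = field(default_factory=lambda: dict(DEFAULT_CLIMATE_DELTA))
    co2_baseline: float = 371.8     # ppm
    co2_params: dict = field(default_factory=lambda: dict(DEFAULT_CO2_PARAMS))
    n_cveg_curves: int = 12
    mtss_qualifying_fraction: float = 0.4   # cells above MTSS, current climate
    landuse_suppression: float = 0.45       # suitable land kept unforested by land use
    niche_breadth: float = 1.0              # climate niche sd as multiple of field sd
    area_target_series: list | None = None  # explicit (year, Mha); else generated
    area_target_growth: float = 0.01        # fractional area growth per year
    area_target_noise: float = 0.01         # sd as fraction of baseline area
    periods: tuple = PERIODS
    ssps: tuple = SSPS

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ConfigError("grid dimensions must be >= 2")
        if self.n_types < 2:
            raise ConfigError("need at least 2 forest types")
        if self.survey_n < 1:
            raise ConfigError("survey_n must be positive")
        if self.survey_noise_sd < 0 or self.age_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        fracs = [self.product_disagreement_rate, self.mtss_qualifying_fraction,
                 self.landuse_suppression, *self.age_null_fraction]
        if any(not (0 <= f <= 1) for f in fracs):
            raise ConfigError("all fractions must lie in [0, 1]")
        if len(self.age_null_fraction) != 3:
            raise ConfigError("age_null_fraction needs one entry per product")
        for key in ((p, s) for p in self.periods for s in self.ssps):
            if key not in self.climate_delta:
                raise ConfigError(f"climate_delta missing entry for {key}")
        for s in self.ssps:
            if s not in self.co2_params:
                raise ConfigError(f"co2_params missing entry for {s!r}")


@dataclass
class WorldBundle:
    """All pipeline inputs on one grid, plus the generating truth."""

    grid: Grid
    typology: Typology
    survey: pd.DataFrame
    cover_products: list[CoverProduct]
    tree_cover: np.ndarray
    age_products: list[AgeProduct]
    climate_now: dict[str, np.ndarray]                       # "mat", "map"
    climate_future: dict[tuple[str, str], dict[str, np.ndarray]]
    suitability_now: SuitabilityStack
    suitability_future: dict[tuple[str, str], SuitabilityStack]
    co2_trajectories: dict[str, CO2Trajectory]
    cveg_curves: list[CVegCurve]
    area_targets: pd.DataFrame                               # year, area_mha
    truth: dict


# ---------------------------------------------------------------------------
# field builders


def _climate_fields(grid: Grid) -> dict[str, np.ndarray]:
    """Smooth latitudinal gradient plus low-amplitude sinusoidal texture."""
    rows, cols = grid.shape
    y = np.linspace(0.0, 1.0, rows)[:, None]    # 0 = north
    x = np.linspace(0.0, 1.0, cols)[None, :]
    lat_span = grid.rows * grid.cell_size
    mat = (14.0 + 2.2 * lat_span * y            # warmer toward the south edge
           + 1.2 * np.sin(2 * np.pi * 3 * x) + 0.8 * np.sin(2 * np.pi * 2 * y))
    map_mm = (400.0 + 1100.0 * x                # wetter toward the east edge
              + 180.0 * np.sin(2 * np.pi * 2.5 * y) + 60.0 * np.sin(2 * np.pi * 4 * x))
    return {"mat": mat + np.zeros(grid.shape), "map": np.clip(map_mm, 0, None)}


def _suitability_link(mat, map_mm, optimum, scales, gamma=2.2, d0=1.5):
    """Logistic link on the squared standardized climate distance."""
    dist = (((mat - optimum[0]) / scales[0]) ** 2
            + ((map_mm - optimum[1]) / scales[1]) ** 2)
    return 1.0 / (1.0 + np.exp(gamma * (dist - d0)))


def _pairwise_flip_rate(target: float, n_alternatives: int) -> float:
    """Per-product flip rate eps so two independently perturbed copies
    disagree with probability exactly ``target``.

    P(disagree) = 1 - (1-eps)^2 - eps^2/n_alternatives.
    """
    if target <= 0:
        return 0.0
    g = lambda e: 1 - (1 - e) ** 2 - e**2 / n_alternatives - target
    hi = n_alternatives / (n_alternatives + 1)  # maximizer of the LHS
    if g(hi) < 0:
        raise ConfigError(f"pairwise disagreement rate {target} unattainable "
                          f"with {n_alternatives} alternative codes")
    return float(brentq(g, 0.0, hi))


def _growth_truth(code: int, family: str) -> dict:
    """Deterministic, type-indexed generating parameters.

    Asymptotes, half-saturation ages and climate coefficients sit in the
    range of published fits for Chinese forest types; half-saturation is
    kept well inside the survey age window so the curve saturates.
    """
    base = {
        "MM": {"mu": 100.0 + 10.0 * code, "k": 60.0 + 8.0 * code},
        "L": {"mu": 120.0 + 10.0 * code, "c": 15.0 + 2.0 * code, "alpha": 0.08},
        "MO": {"mu": 110.0 + 10.0 * code, "c": 1.0 + 0.1 * code, "alpha": 0.04},
    }[family]
    return {"family": family, "params": base,
            "a": 2.0, "b": 0.04, "d": 10.0}


# ---------------------------------------------------------------------------


def generate_world(config: SyntheticConfig) -> WorldBundle:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = Grid(rows=cfg.grid_rows, cols=cfg.grid_cols, cell_size=cfg.cell_size,
                lat_origin=cfg.lat_origin, lon_origin=cfg.lon_origin)
    typ = default_typology(cfg.n_types)
    climate = _climate_fields(grid)
    mat, map_mm = climate["mat"], climate["map"]

    # --- per-type climate optima spread across the realized climate range
    t_lo, t_hi = np.quantile(mat, [0.15, 0.85])
    p_lo, p_hi = np.quantile(map_mm, [0.15, 0.85])
    opt_t = np.linspace(t_lo, t_hi, cfg.n_types)
    opt_p = np.linspace(p_lo, p_hi, cfg.n_types)
    perm = rng.permutation(cfg.n_types)          # decouple T and P optima
    scales = (max(cfg.niche_breadth * mat.std(), 1e-6),
              max(cfg.niche_breadth * map_mm.std(), 1e-6))
    optima = {c: (float(opt_t[i]), float(opt_p[perm[i]]))
              for i, c in enumerate(typ.codes)}

    def stack_for(mat_f, map_f) -> dict[int, np.ndarray]:
        return {c: _suitability_link(mat_f, map_f, optima[c], scales)
                for c in typ.codes}

    prob_now = stack_for(mat, map_mm)
    # MTSS by quantile: exactly the configured fraction qualifies today
    mtss = {}
    for c, p in prob_now.items():
        thr = float(np.quantile(p, 1.0 - cfg.mtss_qualifying_fraction))
        mtss[c] = float(np.clip(thr, 0.01, 0.99))
    suit_now = SuitabilityStack(prob=prob_now, mtss=mtss)

    climate_future: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    suit_future: dict[tuple[str, str], SuitabilityStack] = {}
    for period in cfg.periods:
        for ssp in cfg.ssps:
            d_mat, d_map = cfg.climate_delta[(period, ssp)]
            fut = {"mat": mat + d_mat, "map": np.clip(map_mm + d_map, 0, None)}
            climate_future[(period, ssp)] = fut
            suit_future[(period, ssp)] = SuitabilityStack(
                prob=stack_for(fut["mat"], fut["map"]), mtss=dict(mtss))

    # --- true cover: forest where tree cover >= 20%, type = most suitable.
    # A land-use suppression field (cropland/pasture belts) keeps a share of
    # climatically suitable land unforested — these are the afforestation
    # candidates of the scenario stage.
    max_p = np.maximum.reduce(list(prob_now.values()))
    y2 = np.linspace(0, 1, grid.rows)[:, None]
    x2 = np.linspace(0, 1, grid.cols)[None, :]
    landuse = (np.sin(2 * np.pi * (1.7 * x2 + 0.9 * y2))
               + 0.8 * np.sin(2 * np.pi * (0.6 * x2 - 1.3 * y2))
               + rng.normal(0.0, 0.5, grid.shape))
    suppressed = landuse > np.quantile(landuse, 1.0 - cfg.landuse_suppression)
    texture = rng.normal(0.0, 0.08, grid.shape)
    tree_cover = np.clip(0.05 + 0.9 * max_p + texture, 0.0, 1.0)
    tree_cover[suppressed] *= 0.1
    fmask = forest_mask(tree_cover)
    type_truth = np.zeros(grid.shape, int)
    stacked = np.stack([prob_now[c] for c in typ.codes])
    type_truth[fmask] = np.asarray(typ.codes)[np.argmax(stacked, axis=0)][fmask]

    # --- three cover products perturbed at a solved per-product flip rate
    eps = _pairwise_flip_rate(cfg.product_disagreement_rate, cfg.n_types)
    all_codes = np.array(typ.all_codes)
    labels = ("rank1-fine30m", "rank2-class30m", "rank3-cci300m")
    cover_products = []
    for rank, label in enumerate(labels, start=1):
        codes = type_truth.copy()
        flip = rng.random(grid.shape) < eps
        # uniform over the n_types codes differing from the current one
        offset = rng.integers(1, len(all_codes), grid.shape)
        idx = (np.searchsorted(all_codes, codes) + offset) % len(all_codes)
        codes = np.where(flip, all_codes[idx], codes)
        cover_products.append(CoverProduct(codes=codes, rank=rank, label=label))

    # --- true stand age: smooth field, integer years in [1, 150]
    y = np.linspace(0, 1, grid.rows)[:, None]
    x = np.linspace(0, 1, grid.cols)[None, :]
    age_truth = np.round(60 + 40 * np.sin(2 * np.pi * (0.8 * x - 0.5 * y))
                         + rng.uniform(0, 20, grid.shape))
    age_truth = np.clip(age_truth, 1, 150).astype(float)

    age_products = []
    specs = [("rank1-domestic", 0.0, 0.0), ("rank2-annual", cfg.age_noise_sd, 0.0),
             ("rank3-global2010", 0.0, 10.0)]
    for rank, ((label, noise_sd, offset), nullfrac) in enumerate(
            zip(specs, cfg.age_null_fraction), start=1):
        ages = age_truth.copy()
        if noise_sd > 0:
            ages = np.clip(np.round(ages + rng.normal(0, noise_sd, grid.shape)), 0, None)
        if offset > 0:
            ages = np.clip(ages - offset, 0, None)   # stored young; +offset on use
        nulls = rng.random(grid.shape) < nullfrac
        ages[nulls] = np.nan
        age_products.append(AgeProduct(ages=ages, rank=rank, label=label,
                                       epoch_offset=offset))

    # --- survey records from known growth laws
    fam_cycle = ("MM", "L", "MO")
    truth_growth = {c: _growth_truth(c, fam_cycle[(c - 1) % 3]) for c in typ.codes}
    rows = []
    flat_idx = np.arange(grid.rows * grid.cols)
    for c in typ.codes:
        g = truth_growth[c]
        t = rng.uniform(*cfg.survey_age_range, cfg.survey_n)
        cells = rng.choice(flat_idx, cfg.survey_n, replace=True)
        m = mat.ravel()[cells]
        p = map_mm.ravel()[cells]
        from .growth import eval_growth
        f = eval_growth(g["family"], g["params"], t)
        noise = rng.normal(0.0, cfg.survey_noise_sd, cfg.survey_n) \
            if cfg.survey_noise_sd > 0 else np.zeros(cfg.survey_n)
        agb = f + g["a"] * m + g["b"] * p + g["d"] + noise
        rows.append(pd.DataFrame({"type": c, "t": t, "agb": agb, "mat": m, "map": p}))
    survey = pd.concat(rows, ignore_index=True)

    # --- CO2 trajectories and cVeg ensemble
    years = np.arange(2020, 2081)
    trajectories = {}
    for ssp in cfg.ssps:
        p0, lin, quad = cfg.co2_params[ssp]
        dy = years - 2020
        trajectories[ssp] = CO2Trajectory(ssp=ssp, years=years,
                                          ppm=p0 + lin * dy + quad * dy**2)
    ppm_grid = np.arange(280.0, 1201.0, 20.0)
    cveg_curves = []
    for j in range(cfg.n_cveg_curves):
        vmax = 20.0 * (1.0 + 0.1 * rng.standard_normal())
        half = 300.0 * (1.0 + 0.1 * rng.standard_normal())
        cveg_curves.append(CVegCurve(ppm=ppm_grid,
                                     cveg=abs(vmax) * ppm_grid / (abs(half) + ppm_grid),
                                     source=f"esm{j + 1:02d}"))

    # --- forest-area target series (near-linear policy targets)
    if cfg.area_target_series is not None:
        area_targets = pd.DataFrame(cfg.area_target_series, columns=["year", "area_mha"])
    else:
        a0 = grids.total_area_mha(fmask, grid)
        yrs = np.arange(2020, 2071, 5)
        tgt = a0 * (1.0 + cfg.area_target_growth * (yrs - 2020))
        tgt = tgt + rng.normal(0.0, cfg.area_target_noise * a0, len(yrs))
        area_targets = pd.DataFrame({"year": yrs, "area_mha": tgt})

    truth = {
        "config": asdict(cfg),
        "growth": {int(c): truth_growth[c] for c in typ.codes},
        "optima": {int(c): optima[c] for c in typ.codes},
        "climate_scales": scales,
        "flip_rate": eps,
        "type_truth": type_truth,
        "age_truth": age_truth,
        "forest_mask": fmask,
    }
    return WorldBundle(grid=grid, typology=typ, survey=survey,
                       cover_products=cover_products, tree_cover=tree_cover,
                       age_products=age_products, climate_now=climate,
                       climate_future=climate_future, suitability_now=suit_now,
                       suitability_future=suit_future,
                       co2_trajectories=trajectories, cveg_curves=cveg_curves,
                       area_targets=area_targets, truth=truth)


# ---------------------------------------------------------------------------
# serialization (plain-text artifacts)


def write_world(bundle: WorldBundle, out_dir: str | Path) -> Path:
    """Write the bundle as ASCII grids, CSV tables and a JSON truth file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = bundle.grid
    for prod in bundle.cover_products:
        grids.write_ascii(out / f"cover_rank{prod.rank}.asc", prod.codes, g)
    grids.write_ascii(out / "tree_cover.asc", bundle.tree_cover, g)
    for prod in bundle.age_products:
        grids.write_ascii(out / f"age_rank{prod.rank}.asc", prod.ages, g)
    grids.write_ascii(out / "mat_2020.asc", bundle.climate_now["mat"], g)
    grids.write_ascii(out / "map_2020.asc", bundle.climate_now["map"], g)
    for (period, ssp), clim in bundle.climate_future.items():
        grids.write_ascii(out / f"mat_{period}_{ssp}.asc", clim["mat"], g)
        grids.write_ascii(out / f"map_{period}_{ssp}.asc", clim["map"], g)
    manifest = []
    for (period, ssp), stack in bundle.suitability_future.items():
        for code, p in stack.prob.items():
            fname = f"suit_{period}_{ssp}_type{code}.asc"
            grids.write_ascii(out / fname, p, g)
            manifest.append({"type": code, "period": period, "ssp": ssp,
                             "mtss": stack.mtss[code], "path": fname})
    (out / "suitability_manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle.survey.to_csv(out / "survey.csv", index=False)
    bundle.area_targets.to_csv(out / "area_targets.csv", index=False)
    for ssp, traj in bundle.co2_trajectories.items():
        pd.DataFrame({"year": traj.years, "ppm": traj.ppm}).to_csv(
            out / f"co2_{ssp}.csv", index=False)
    pd.concat([pd.DataFrame({"source": cv.source, "ppm": cv.ppm, "cveg": cv.cveg})
               for cv in bundle.cveg_curves]).to_csv(out / "cveg_curves.csv", index=False)
    truth = {k: v for k, v in bundle.truth.items()
             if k not in ("type_truth", "age_truth", "forest_mask")}
    truth["optima"] = {k: list(v) for k, v in truth["optima"].items()}
    truth["climate_scales"] = list(truth["climate_scales"])
    cfg_dict = dict(truth["config"])
    cfg_dict["climate_delta"] = {f"{p}:{s}": list(v) for (p, s), v
                                 in cfg_dict["climate_delta"].items()}
    truth["config"] = cfg_dict
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return out
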