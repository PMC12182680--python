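"""Reported metrics: totals, densities, ages, rates, component shares.

Units follow the study's reporting conventions: densities in Mg/ha,
national totals in PgC, sequestration rates in TgC/yr, areas in Mha.
``carbon_fraction`` converts biomass density to carbon; the default 1.0
treats input densities as already in carbon units (set 0.5 for the
conventional IPCC biomass-to-carbon factor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .grids import cell_area_ha
from .scenario import FLAG_LOST, FLAG_PLANTED, FLAG_REPLACED, ForestState


def total_agb(state: ForestState, carbon_fraction: float = 1.0,
              density: np.ndarray | None = None) -> float:
    """Total stock in PgC: sum density (Mg/ha) x area (ha) x fraction x 1e-9."""
    if not (0 < carbon_fraction <= 1):
        raise DataError("carbon_fraction must lie in (0, 1]")
    dens = state.c_total if density is None else density
    areas = cell_area_ha(state.grid)
    return float((dens * areas).sum() * carbon_fraction * 1e-9)


def _weighted_stats(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    w = weights / weights.sum()
    mean = float((values * w).sum())
    var = float(((values - mean) ** 2 * w).sum())
    return mean, float(np.sqrt(var))


def mean_density(state: ForestState) -> tuple[float, float]:
    """Area-weighted mean AGB density (Mg/ha) over forested pixels, +/- spatial sd.

    (NaN, NaN) for a fully deforested state.
    """
    sel = state.forest
    if not sel.any():
        return (float("nan"), float("nan"))
    return _weighted_stats(state.c_total[sel], cell_area_ha(state.grid)[sel])


def mean_age(state: ForestState) -> tuple[float, float]:
    """Area-weighted mean stand age (years) over forested pixels, +/- spatial sd.

    (NaN, NaN) for a fully deforested state.
    """
    sel = state.forest
    if not sel.any():
        return (float("nan"), float("nan"))
    return _weighted_stats(state.age[sel], cell_area_ha(state.grid)[sel])


def forest_area_mha(state: ForestState) -> float:
    return float(cell_area_ha(state.grid)[state.forest].sum() / 1e6)


def rates(state_future: ForestState, state2020: ForestState) -> tuple[float, float]:
    """(forest-area-loss %, structural-change %) relative to the 2020 area.

    Loss counts pixels flagged lost; structural change counts pixels whose
    type was replaced. Both are area ratios against the 2020 forest area.
    """
    if state_future.grid != state2020.grid:
        raise DataError("states live on different grids")
    areas = cell_area_ha(state2020.grid)
    base = areas[state2020.forest].sum()
    if base == 0:
        raise DataError("zero baseline forest area: rates undefined")
    lost = areas[state_future.flags == FLAG_LOST].sum()
    changed = areas[state_future.flags == FLAG_REPLACED].sum()
    return float(lost / base * 100.0), float(changed / base * 100.0)


def sequestration_rate(agb_t1_pgc: float, agb_t0_pgc: float, years: float) -> float:
    """(delta PgC) x 1000 / years -> TgC/yr."""
    if years <= 0:
        raise DataError("years must be positive")
    return (agb_t1_pgc - agb_t0_pgc) * 1000.0 / years


def component_shares(state: ForestState, carbon_fraction: float = 1.0
                     ) -> dict[str, float]:
    """Percent contribution of the age/climate/CO2 components to total AGB."""
    tot = total_agb(state, carbon_fraction)
    if tot == 0:
        return {"age": 0.0, "climate": 0.0, "co2": 0.0}
    parts = {
        "age": total_agb(state, carbon_fraction, density=state.c_age),
        "climate": total_agb(state, carbon_fraction, density=state.c_climate),
        "co2": total_agb(state, carbon_fraction, density=state.c_co2),
    }
    return {k: v / tot * 100.0 for k, v in parts.items()}


def summarize_state(state: ForestState, baseline: ForestState | None = None,
                    carbon_fraction: float = 1.0) -> dict:
    """One summary row for a projected (or baseline) state."""
    dens_mean, dens_sd = mean_density(state)
    age_mean, age_sd = mean_age(state)
    shares = component_shares(state, carbon_fraction)
    row = {
        "total_agb_pgc": total_agb(state, carbon_fraction),
        "mean_density_mgha": dens_mean,
        "mean_density_sd": dens_sd,
        "mean_age_yr": age_mean,
        "mean_age_sd": age_sd,
        "area_mha": forest_area_mha(state),
        "planted_area_mha": float(
            cell_area_ha(state.grid)[state.flags == FLAG_PLANTED].sum() / 1e6),
        "share_age_pct": shares["age"],
        "share_climate_pct": shares["climate"],
        "share_co2_pct": shares["co2"],
    }
    if baseline is not None:
        loss, change = rates(state, baseline)
        row["loss_rate_pct"] = loss
        row["change_rate_pct"] = change
    return row


def per_region_summary(state: ForestState, regions: np.ndarray,
                       carbon_fraction: float = 1.0) -> pd.DataFrame:
    """Aggregate totals and mean density per region label raster."""
    regions = state.grid.check(np.asarray(regions), "regions")
    areas = cell_area_ha(state.grid)
    rows = []
    for label in np.unique(regions):
        sel = (regions == label) & state.forest
        if not sel.any():
            continue
        dens, dens_sd = _weighted_stats(state.c_total[sel], areas[sel])
        rows.append({
            "region": label,
            "total_agb_pgc": float((state.c_total[sel] * areas[sel]).sum()
                                   * carbon_fraction * 1e-9),
            "mean_density_mgha": dens,
            "mean_density_sd": dens_sd,
            "area_mha": float(areas[sel].sum() / 1e6),
        })
    return pd.DataFrame(rows)
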