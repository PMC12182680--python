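"""CO2-fertilization effect on AGB via the cVeg ratio method.

Earth-system-model 1pctCO2 experiments give vegetation carbon density
(cVeg) as a function of atmospheric CO2 concentration. The fertilization
ratio for year t is

    F = cVeg(ppm_t) / cVeg(ppm_baseline),    baseline = 371.8 ppm
        (the 1978-2020 mean concentration),

and the AGB component attributable to elevated CO2 is

    C^co2 = (F - 1) * C^age.

Period ratios are the arithmetic mean of yearly F over the period's years
(2030s = 2021-2040, 2050s = 2041-2060, 2070s = 2061-2080). When several
model curves are supplied, F is the mean of the per-curve ratios, keeping
each model self-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, DataError, ExtrapolationError

BASELINE_PPM = 371.8

PERIOD_YEARS = {
    "2030s": (2021, 2040),
    "2050s": (2041, 2060),
    "2070s": (2061, 2080),
}


@dataclass(frozen=True)
class CVegCurve:
    """Tabulated (ppm, cVeg) response of one model or ensemble."""

    ppm: np.ndarray
    cveg: np.ndarray
    source: str = "ensemble"

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, float)
        cveg = np.asarray(self.cveg, float)
        if ppm.ndim != 1 or ppm.shape != cveg.shape or len(ppm) < 2:
            raise DataError("cVeg curve needs matching 1-D ppm/cveg arrays, length >= 2")
        if not np.all(np.diff(ppm) > 0):
            raise DataError("cVeg curve ppm values must be strictly increasing")
        if np.any(cveg < 0):
            raise DataError("cVeg values must be non-negative")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "cveg", cveg)

    def __call__(self, ppm_t: float) -> float:
        if ppm_t < self.ppm[0] or ppm_t > self.ppm[-1]:
            raise ExtrapolationError(
                f"{self.source}: {ppm_t} ppm outside tabulated range "
                f"[{self.ppm[0]}, {self.ppm[-1]}]")
        return float(np.interp(ppm_t, self.ppm, self.cveg))


@dataclass(frozen=True)
class CO2Trajectory:
    """Yearly atmospheric CO2 concentration under one emission scenario."""

    ssp: str
    years: np.ndarray
    ppm: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, int)
        ppm = np.asarray(self.ppm, float)
        if years.shape != ppm.shape or years.ndim != 1:
            raise DataError("trajectory years/ppm must be matching 1-D arrays")
        if not np.all(np.diff(years) > 0):
            raise DataError("trajectory years must be strictly increasing")
        if np.any(ppm <= 0):
            raise DataError("trajectory ppm must be positive")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "ppm", ppm)

    def at(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if len(idx) == 0:
            raise CoverageError(f"trajectory {self.ssp} has no year {year}")
        return float(self.ppm[idx[0]])


def _as_curves(curve) -> list[CVegCurve]:
    return list(curve) if isinstance(curve, (list, tuple)) else [curve]


def compute_F(curve, ppm_t: float, ppm_baseline: float = BASELINE_PPM) -> float:
    """Fertilization ratio F = cVeg(ppm_t)/cVeg(baseline).

    ``curve`` may be one CVegCurve or a sequence; for a sequence F is the
    mean of per-curve ratios.
    """
    ratios = []
    for cv in _as_curves(curve):
        denom = cv(ppm_baseline)
        if denom == 0:
            raise DataError(f"{cv.source}: cVeg at baseline is zero")
        ratios.append(cv(ppm_t) / denom)
    return float(np.mean(ratios))


def period_mean_F(curve, trajectory: CO2Trajectory, period: str,
                  ppm_baseline: float = BASELINE_PPM) -> float:
    """Mean of yearly F over the period's years, inclusive bounds."""
    if period not in PERIOD_YEARS:
        raise DataError(f"unknown period {period!r}; expected one of {list(PERIOD_YEARS)}")
    y0, y1 = PERIOD_YEARS[period]
    vals = [compute_F(curve, trajectory.at(y), ppm_baseline)
            for y in range(y0, y1 + 1)]
    return float(np.mean(vals))


def co2_component(F: float, c_age) -> np.ndarray | float:
    """C^co2 = (F - 1) * C^age; negative when F < 1."""
    if F <= 0:
        raise DataError(f"F must be positive, got {F}")
    out = (F - 1.0) * np.asarray(c_age, float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV interfaces


def read_cveg_curves(path) -> list[CVegCurve]:
    """CSV with columns ppm,cveg[,source] -> one curve per source label."""
    df = pd.read_csv(path)
    if "source" not in df.columns:
        df["source"] = "ensemble"
    return [CVegCurve(g["ppm"].to_numpy(), g["cveg"].to_numpy(), source=str(s))
            for s, g in df.groupby("source")]


def read_trajectory(path, ssp: str = "") -> CO2Trajectory:
    df = pd.read_csv(path)
    return CO2Trajectory(ssp=ssp or str(df.get("ssp", pd.Series(["?"])).iloc[0]),
                         years=df["year"].to_numpy(), ppm=df["ppm"].to_numpy())
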