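"""Biomass-age growth curves with linear climate covariates.

Aboveground biomass (AGB) density of a stand of age ``t`` is modelled by one
of three saturating growth laws, each with asymptote ``mu`` (Mg/ha):

* Michaelis-Menten (MM):  AGB = mu * t / (k + t), ``k`` the half-saturation
  age (f(k) = mu/2);
* Monomolecular (MO):     AGB = mu * (1 - c * exp(-alpha * t)), c >= 1;
* Logistic (L):           AGB = mu / (1 + c * exp(-alpha * t)), c >= 1.

The climate-augmented model adds a linear term in mean annual temperature
(MAT, degC) and precipitation (MAP, mm):

    C(t, MAT, MAP) = f(t) + a*MAT + b*MAP + d

All parameters are estimated jointly per forest type by constrained
nonlinear least squares from a fixed multi-start grid, and the three fitted
families are compared by AIC (RMSE tie-break).

The fitted model is decomposed into an age component (future age, baseline
climate), a climate component (the difference made by the future climate)
and, downstream, a CO2-fertilization component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, SelectionError

log = logging.getLogger(__name__)

FAMILIES = ("MM", "MO", "L")

#: free parameters per family including (a, b, d)
N_PARAMS = {"MM": 5, "MO": 6, "L": 6}

#: tie-break preference order when AIC and RMSE both tie
FAMILY_ORDER = {"MM": 0, "L": 1, "MO": 2}


@dataclass
class GrowthFit:
    """A fitted climate-augmented growth model for one forest type."""

    family: str
    mu: float                     # asymptote, Mg/ha
    k: float | None = None        # MM half-saturation age, years
    c: float | None = None        # MO/L shape, >= 1
    alpha: float | None = None    # MO/L rate, 1/years
    a: float = 0.0                # Mg/ha per degC
    b: float = 0.0                # Mg/ha per mm
    d: float = 0.0                # intercept, Mg/ha
    rmse: float = math.nan
    r2: float = math.nan
    aic: float = math.nan
    n: int = 0
    type_code: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FitError(f"unknown growth family {self.family!r}")
        if not np.isfinite(self.mu) or self.mu <= 0:
            raise FitError(f"asymptote mu must be positive and finite, got {self.mu}")
        if self.family == "MM":
            if self.k is None or not np.isfinite(self.k) or self.k <= 0:
                raise FitError(f"MM requires k > 0, got {self.k}")
        else:
            if self.alpha is None or not np.isfinite(self.alpha) or self.alpha <= 0:
                raise FitError(f"{self.family} requires alpha > 0, got {self.alpha}")
            if self.c is None or not np.isfinite(self.c) or self.c < 1:
                raise FitError(f"{self.family} requires c >= 1, got {self.c}")

    @property
    def growth_params(self) -> dict[str, float]:
        if self.family == "MM":
            return {"mu": self.mu, "k": self.k}
        return {"mu": self.mu, "c": self.c, "alpha": self.alpha}

    def to_dict(self) -> dict:
        return asdict(self)


def eval_growth(family: str, params: dict[str, float], t) -> np.ndarray | float:
    """Evaluate the pure growth law f(t) at age(s) ``t`` (years)."""
    t = np.asarray(t, dtype=float)
    for v in params.values():
        if not np.isfinite(v):
            raise FitError(f"non-finite growth parameter in {params}")
    if family == "MM":
        mu, k = params["mu"], params["k"]
        out = mu * t / (k + t)
    elif family == "MO":
        mu, c, alpha = params["mu"], params["c"], params["alpha"]
        out = mu * (1.0 - c * np.exp(-alpha * t))
    elif family == "L":
        mu, c, alpha = params["mu"], params["c"], params["alpha"]
        out = mu / (1.0 + c * np.exp(-alpha * t))
    else:
        raise FitError(f"unknown growth family {family!r}")
    return float(out) if out.ndim == 0 else out


def asymptote(fit: GrowthFit) -> float:
    """Saturated AGB of the growth law: lim_{t->inf} f(t) = mu for all families."""
    return float(fit.mu)


def half_saturation_age(fit: GrowthFit, t_max: float = 1e6) -> float:
    """Age at which f(t) reaches half the asymptote, by numerical inversion.

    For MM this equals k analytically; solved by bisection for all families
    so the value is an independent check on the closed form.
    """
    from scipy.optimize import brentq

    target = asymptote(fit) / 2.0
    f = lambda t: eval_growth(fit.family, fit.growth_params, t) - target
    lo = 0.0
    if f(lo) > 0:  # MO/L with small c can start above mu/2
        return 0.0
    return float(brentq(f, lo, t_max, xtol=1e-10, rtol=1e-12))


def eval_age_climate(fit: GrowthFit, t, mat, map_mm) -> np.ndarray | float:
    """C^{age+climate} = f(t) + a*MAT + b*MAP + d, clipped below at 0.

    The linear climate term can drive small-age predictions negative;
    negative biomass is unphysical, so predictions are floored at zero and
    the clipped count is logged.
    """
    raw = (eval_growth(fit.family, fit.growth_params, t)
           + fit.a * np.asarray(mat, float)
           + fit.b * np.asarray(map_mm, float) + fit.d)
    raw = np.asarray(raw, float)
    n_neg = int((raw < 0).sum())
    if n_neg:
        log.debug("clipped %d negative AGB predictions to 0 (%s)", n_neg, fit.label)
    out = np.clip(raw, 0.0, None)
    return float(out) if out.ndim == 0 else out


def age_component(fit: GrowthFit, t_future, mat_2020, map_2020) -> np.ndarray | float:
    """C^age: the future-age prediction under *baseline* (2020) climate."""
    return eval_age_climate(fit, t_future, mat_2020, map_2020)


def climate_component(c_age_climate, c_age) -> np.ndarray | float:
    """C^climate = C^{age+climate} - C^age; may be negative."""
    out = np.asarray(c_age_climate, float) - np.asarray(c_age, float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitting


def _design(records: pd.DataFrame) -> tuple[np.ndarray, ...]:
    t = records["t"].to_numpy(float)
    agb = records["agb"].to_numpy(float)
    mat = records["mat"].to_numpy(float)
    map_mm = records["map"].to_numpy(float)
    return t, agb, mat, map_mm


def _starts(family: str, agb_max: float) -> list[list[float]]:
    mus = [0.5 * agb_max, agb_max, 2.0 * agb_max]
    if family == "MM":
        return [[mu, k, 0.0, 0.0, 0.0] for mu in mus for k in (25.0, 50.0, 100.0, 200.0, 400.0, 800.0)]
    return [[mu, c, al, 0.0, 0.0, 0.0]
            for mu in mus for c in (1.0, 10.0, 1e5)
            for al in (0.01, 0.05, 0.2, 0.8)]


def fit_family(records: pd.DataFrame, family: str,
               type_code: int | None = None, label: str = "",
               freeze_climate: bool = False) -> GrowthFit:
    """Fit one growth family to survey records by constrained least squares.

    ``records`` needs columns ``t, agb, mat, map``. Growth parameters and
    climate coefficients are estimated jointly; a fixed multi-start grid
    makes the result deterministic. ``freeze_climate=True`` pins a = b = d
    = 0 (pure growth-curve fit, used for oracle comparisons).

    Metrics: RMSE = sqrt(RSS/n); R2 = 1 - RSS/TSS; Gaussian least-squares
    AIC = n*ln(RSS/n) + 2p with p counting all free parameters.
    """
    if family not in FAMILIES:
        raise FitError(f"unknown growth family {family!r}")
    t, agb, mat, map_mm = _design(records)
    n = len(agb)
    p_free = N_PARAMS[family] - (3 if freeze_climate else 0)
    if n < p_free + 1:
        raise FitError(f"{label or family}: need at least {p_free + 1} records, got {n}")
    if np.ptp(t) == 0:
        raise FitError(f"{label or family}: all stand ages identical")
    tss = float(((agb - agb.mean()) ** 2).sum())
    if tss == 0:
        raise FitError(f"{label or family}: constant AGB, nothing to fit")

    n_growth = 2 if family == "MM" else 3

    def residual(theta: np.ndarray) -> np.ndarray:
        gp = theta[:n_growth]
        if family == "MM":
            f = gp[0] * t / (gp[1] + t)
        elif family == "MO":
            f = gp[0] * (1.0 - gp[1] * np.exp(-gp[2] * t))
        else:
            f = gp[0] / (1.0 + gp[1] * np.exp(-gp[2] * t))
        if freeze_climate:
            return f - agb
        a, b, d = theta[n_growth:]
        return f + a * mat + b * map_mm + d - agb

    if family == "MM":
        lb = [1e-9, 1e-9]
    else:
        lb = [1e-9, 1.0, 1e-9]
    if not freeze_climate:
        lb = lb + [-np.inf] * 3

    best = None
    agb_max = max(float(agb.max()), 1e-6)
    for start in _starts(family, agb_max):
        x0 = start[:n_growth] if freeze_climate else start
        try:
            res = least_squares(residual, x0, bounds=(lb, np.inf), method="trf",
                                max_nfev=2000)
        except Exception:  # singular start; other starts may succeed
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        raise FitError(f"{label or family}: optimizer failed from every start")

    theta = best.x
    rss = float(2.0 * best.cost)
    rmse = math.sqrt(rss / n)
    r2 = 1.0 - rss / tss
    aic = n * math.log(max(rss / n, 1e-300)) + 2 * p_free
    a, b, d = (0.0, 0.0, 0.0) if freeze_climate else theta[n_growth:]
    kw: dict = {"family": family, "mu": theta[0], "a": float(a), "b": float(b),
                "d": float(d), "rmse": rmse, "r2": r2, "aic": aic, "n": n,
                "type_code": type_code, "label": label}
    if family == "MM":
        kw["k"] = float(theta[1])
    else:
        kw["c"] = float(max(theta[1], 1.0))
        kw["alpha"] = float(theta[2])
    return GrowthFit(**kw)


def select_model(fits: Iterable[GrowthFit | None]) -> GrowthFit:
    """Pick the best family by AIC; ties by lower RMSE, then MM > L > MO."""
    cands = [f for f in fits if f is not None]
    if not cands:
        raise SelectionError("all growth-family fits failed")
    return min(cands, key=lambda f: (f.aic, f.rmse, FAMILY_ORDER[f.family]))


def fit_all_types(survey: pd.DataFrame, families: Sequence[str] = FAMILIES,
                  typology=None) -> dict[int, GrowthFit]:
    """Fit every family per primary forest type and select the best.

    ``survey`` needs columns ``type, t, agb, mat, map``. A family that fails
    on a type is excluded from selection for that type (logged); if all
    fail, a SelectionError is raised naming the type.
    """
    fits: dict[int, GrowthFit] = {}
    for code, group in survey.groupby("type"):
        code = int(code)
        label = typology.name(code) if typology is not None else f"type{code}"
        cands: list[GrowthFit] = []
        for fam in families:
            try:
                cands.append(fit_family(group, fam, type_code=code, label=label))
            except FitError as err:
                log.warning("fit failed (%s, %s): %s", label, fam, err)
        if not cands:
            raise SelectionError(f"all growth families failed for {label}")
        fits[code] = select_model(cands)
    return fits


def fits_table(fits: dict[int, GrowthFit]) -> pd.DataFrame:
    """Tabular view of selected fits (one row per type)."""
    rows = [f.to_dict() for f in fits.values()]
    return pd.DataFrame(rows).sort_values("type_code").reset_index(drop=True)
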