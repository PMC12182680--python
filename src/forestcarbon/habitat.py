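"""Habitat-suitability decisions and environmental-variable pruning.

Species-distribution models (MaxEnt in the original study) are external to
this package: what enters the scenario engine is, per forest type, a
suitability probability surface P in [0, 1] and one MTSS threshold (the
probability at maximum training sensitivity plus specificity). A pixel is
suitable for a type iff P strictly exceeds the type's MTSS.

`prune_correlated` reproduces the pre-modelling step of discarding
collinear environmental variables (pairwise Pearson |r| > 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ShapeError


@dataclass
class SuitabilityStack:
    """Per-type suitability surfaces for one period x SSP, plus thresholds.

    ``prob`` maps forest type code -> probability raster; ``mtss`` maps
    type code -> threshold in (0, 1).
    """

    prob: dict[int, np.ndarray]
    mtss: dict[int, float]

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.prob.values()}
        if len(shapes) > 1:
            raise ShapeError(f"suitability rasters disagree on shape: {shapes}")
        for code, p in self.prob.items():
            if np.nanmin(p) < 0 or np.nanmax(p) > 1:
                raise DataError(f"suitability for type {code} outside [0, 1]")
        for code in self.prob:
            m = self.mtss.get(code)
            if m is None or not (0 < m < 1):
                raise DataError(f"type {code}: MTSS must lie in (0, 1), got {m}")

    @property
    def types(self) -> list[int]:
        return sorted(self.prob)

    def suitable_mask(self, code: int) -> np.ndarray:
        return self.prob[code] > self.mtss[code]

    def any_suitable(self) -> np.ndarray:
        out = np.zeros(next(iter(self.prob.values())).shape, bool)
        for code in self.prob:
            out |= self.suitable_mask(code)
        return out


def is_suitable(p: float, mtss: float) -> bool:
    """True iff the probability strictly exceeds the threshold."""
    return p > mtss


def best_type(p_by_type: dict[int, float], mtss_by_type: dict[int, float]) -> int | None:
    """Most-suitable qualifying type, or None.

    Among types with p > mtss, returns the one with maximal p; exact ties
    break to the lower typology code so the choice is deterministic.
    """
    if set(p_by_type) != set(mtss_by_type):
        raise DataError("p_by_type and mtss_by_type key sets differ")
    qualifying = [(p, -code) for code, p in p_by_type.items()
                  if is_suitable(p, mtss_by_type[code])]
    if not qualifying:
        return None
    p, neg = max(qualifying)
    return -neg


def best_type_grid(stack: SuitabilityStack,
                   exclude: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized best_type over a whole grid.

    ``exclude`` (optional int raster) removes one type per pixel from
    consideration (used for the replacement rule, which looks only at
    *other* types). Returns (best_code, best_p) with code 0 where no type
    qualifies.
    """
    shape = next(iter(stack.prob.values())).shape
    best_p = np.full(shape, -1.0)
    best_code = np.zeros(shape, dtype=int)
    for code in sorted(stack.prob, reverse=True):
        # descending code order + strict > below makes ties land on the lower code
        p = stack.prob[code]
        ok = p > stack.mtss[code]
        if exclude is not None:
            ok &= exclude != code
        take = ok & (p >= best_p)
        # p == best_p with a lower code should win: iterate descending, accept >=
        best_p = np.where(take, p, best_p)
        best_code = np.where(take, code, best_code)
    best_p[best_code == 0] = np.nan
    return best_code, best_p


def prune_correlated(env: pd.DataFrame, threshold: float = 0.8) -> list[str]:
    """Greedily drop variables until all pairwise Pearson |r| <= threshold.

    At each step the variable with the most |r| > threshold partners is
    removed; ties break to the larger mean |r| against the surviving set,
    then to name order (the later-named column is dropped, so the first
    occurrence of a duplicate survives). Returns surviving names in
    original column order.
    """
    if env.shape[1] < 2 or env.shape[0] < 3:
        raise DataError("need at least 2 variables and 3 locations")
    if not np.all(np.isfinite(env.to_numpy(float))):
        raise DataError("environmental matrix contains non-finite values")
    for col in env.columns:
        if env[col].nunique() <= 1:
            raise DataError(f"constant column {col!r}: correlation undefined")

    corr = env.corr(method="pearson").abs()
    keep = list(env.columns)
    while True:
        sub = corr.loc[keep, keep]
        over = (sub > threshold) & ~np.eye(len(keep), dtype=bool)
        counts = over.sum(axis=1)
        if counts.max() == 0:
            break
        worst = counts.max()
        tied = list(counts[counts == worst].index)
        if len(tied) > 1:
            means = sub.loc[tied, keep].mean(axis=1)
            top = means.max()
            tied = sorted(means[means >= top - 1e-15].index)
        keep.remove(tied[-1])
    return [c for c in env.columns if c in keep]
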