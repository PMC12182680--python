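"""Fusion of multi-source forest cover and stand-age products.

Three cover-type products (ranked by prior reliability) are merged
per pixel by sequential criteria:

  (1) if at least two products agree on a *forest* type, that type wins;
  (2) otherwise the rank-1 product's code, if it is a forest code;
  (3) otherwise the rank-2 product's code, if forest;
  (4) otherwise the rank-3 product's code — in particular, when ranks 1
      and 2 both say non-forest, the rank-3 product decides.

Three age products are merged by priority fill inside the forest mask:
rank 1 where non-null, else rank 2, else rank 3 plus its epoch offset
(+10 years for a 2010-vintage map used at a 2020 baseline). Pixels null in
all three are filled with the median fused age of same-type pixels and
reported.

A pixel is "forest" where fractional tree cover >= 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ShapeError, TypologyError
from .typology import Typology

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverProduct:
    codes: np.ndarray           # int raster of typology codes
    rank: int                   # 1 = most trusted
    label: str = ""
    nodata: int = -1

    def __post_init__(self) -> None:
        if self.rank not in (1, 2, 3):
            raise DataError(f"cover product rank must be 1-3, got {self.rank}")


@dataclass(frozen=True)
class AgeProduct:
    ages: np.ndarray            # float raster, NaN where null
    rank: int
    label: str = ""
    epoch_offset: float = 0.0   # years added on use (older-vintage maps)

    def __post_init__(self) -> None:
        if self.rank not in (1, 2, 3):
            raise DataError(f"age product rank must be 1-3, got {self.rank}")
        if self.epoch_offset < 0:
            raise DataError("epoch offset must be >= 0")
        valid = self.ages[np.isfinite(self.ages)]
        if valid.size and valid.min() < 0:
            raise DataError(f"age product {self.label!r} has negative ages")


def _by_rank(products, kind: str):
    ranks = sorted(p.rank for p in products)
    if ranks != [1, 2, 3]:
        raise DataError(f"{kind} products must carry ranks 1, 2, 3; got {ranks}")
    out = sorted(products, key=lambda p: p.rank)
    shapes = {tuple(np.asarray(p.codes if kind == 'cover' else p.ages).shape) for p in out}
    if len(shapes) > 1:
        raise ShapeError(f"{kind} products disagree on grid shape: {shapes}")
    return out


def fuse_cover(p1: CoverProduct, p2: CoverProduct, p3: CoverProduct,
               typology: Typology) -> np.ndarray:
    """Merge three cover products by the sequential criteria above."""
    a, b, c = (np.asarray(p.codes) for p in _by_rank([p1, p2, p3], "cover"))
    valid = set(typology.all_codes)
    for arr, prod in zip((a, b, c), sorted([p1, p2, p3], key=lambda p: p.rank)):
        unknown = set(np.unique(arr)) - valid
        if unknown:
            raise TypologyError(
                f"product {prod.label or prod.rank} contains codes outside the "
                f"typology: {sorted(int(u) for u in unknown)}")

    forest_codes = np.array(typology.codes)
    is_forest = lambda arr: np.isin(arr, forest_codes)

    out = c.copy()                                    # criterion (4)
    out = np.where(is_forest(b), b, out)              # criterion (3)
    out = np.where(is_forest(a), a, out)              # criterion (2)
    # criterion (1): a two-product agreement on a *forest* type wins; an
    # agreement on non-forest falls through to the priority chain (the
    # rank-3 product decides when ranks 1 and 2 both say non-forest)
    out = np.where((b == c) & is_forest(b), b, out)
    out = np.where((a == c) & is_forest(a), a, out)
    out = np.where((a == b) & is_forest(a), a, out)
    return out


def forest_mask(tree_cover: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """True where fractional tree cover >= threshold (inclusive).

    Accepts cover either as a fraction in [0, 1] or percent in [0, 100];
    percent input (values > 1) is detected and scaled, with the threshold
    always interpreted as a fraction.
    """
    tc = np.asarray(tree_cover, float)
    if np.nanmin(tc) < 0:
        raise DataError("tree cover has negative values")
    if np.nanmax(tc) > 1.0:
        if np.nanmax(tc) > 100.0:
            raise DataError("tree cover exceeds 100%")
        tc = tc / 100.0
    return tc >= threshold


def fuse_age(a1: AgeProduct, a2: AgeProduct, a3: AgeProduct,
             mask: np.ndarray, types: np.ndarray | None = None
             ) -> tuple[np.ndarray, int]:
    """Priority-fill stand age inside the forest mask.

    Returns (age raster with NaN outside mask, count of pixels that were
    null in all three products and fell back to the same-type median).
    """
    p1, p2, p3 = _by_rank([a1, a2, a3], "age")
    mask = np.asarray(mask, bool)
    if mask.shape != p1.ages.shape:
        raise ShapeError("forest mask shape does not match age products")

    age = np.where(np.isfinite(p1.ages), p1.ages + p1.epoch_offset, np.nan)
    age = np.where(np.isnan(age) & np.isfinite(p2.ages), p2.ages + p2.epoch_offset, age)
    age = np.where(np.isnan(age) & np.isfinite(p3.ages), p3.ages + p3.epoch_offset, age)

    holes = mask & np.isnan(age)
    n_holes = int(holes.sum())
    if n_holes:
        if types is not None:
            for code in np.unique(np.asarray(types)[holes]):
                sel = holes & (types == code)
                donor = mask & (types == code) & np.isfinite(age)
                fill = np.nanmedian(age[donor]) if donor.any() else np.nanmedian(age[mask])
                age[sel] = fill
        filled = age[mask & np.isfinite(age)]
        global_fill = np.median(filled) if filled.size else 0.0
        age[mask & np.isnan(age)] = global_fill
        log.warning("fuse_age: %d all-null pixels filled with median age", n_holes)
    age[~mask] = np.nan
    return age, n_holes
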