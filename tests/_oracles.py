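"""Independent literal transcriptions of the per-pixel rules.

These oracles are deliberately written as plain Python loops over scalar
values, mirroring the prose rules step by step, so the vectorized engines
can be checked against them. They must stay independent of the
implementations they audit: no calls into forestcarbon's fusion or
scenario code.
"""

import math

import numpy as np


# --- cover fusion, criteria (1)-(4) transcribed literally ------------------

def fuse_cover_pixel(a, b, c, forest_codes):
    """(rank1, rank2, rank3) codes -> fused code."""
    # (1) two datasets agreeing on a forest type adopt that classification
    for x, y in ((a, b), (a, c), (b, c)):
        if x == y and x in forest_codes:
            return x
    # (2) discrepancies: the rank-1 product is prioritized if it says forest
    if a in forest_codes:
        return a
    # (3) rank-1 non-forest: consult the rank-2 product
    if b in forest_codes:
        return b
    # (4) both non-forest: the rank-3 classification is used
    return c


def fuse_age_pixel(a1, a2, a3, offset3=10.0):
    """Priority fill: rank 1, else rank 2, else rank 3 + its epoch offset."""
    if not math.isnan(a1):
        return a1
    if not math.isnan(a2):
        return a2
    if not math.isnan(a3):
        return a3 + offset3
    return math.nan


# --- growth formulas (closed-form, no package calls) ------------------------

def growth_value(fit, t):
    if fit.family == "MM":
        return fit.mu * t / (fit.k + t)
    if fit.family == "MO":
        return fit.mu * (1.0 - fit.c * math.exp(-fit.alpha * t))
    return fit.mu / (1.0 + fit.c * math.exp(-fit.alpha * t))


def agb_prediction(fit, t, mat, map_mm):
    return max(growth_value(fit, t) + fit.a * mat + fit.b * map_mm + fit.d, 0.0)


def pixel_components(fit, t, mat0, map0, mat_f, map_f, F):
    c_age = agb_prediction(fit, t, mat0, map0)
    c_climate = agb_prediction(fit, t, mat_f, map_f) - c_age
    c_co2 = (F - 1.0) * c_age
    return c_age, c_climate, c_co2


# --- nature scenario, pixel-by-pixel ----------------------------------------

def nature_oracle(types0, age0, prob, mtss, fits, mat0, map0, mat_f, map_f,
                  F, n_years, half_age):
    """Literal transcription of the remain / replace / lose rules.

    ``prob``: {type: P raster}; returns dict of output rasters.
    """
    rows, cols = types0.shape
    out_type = np.zeros_like(types0)
    out_age = np.full(types0.shape, np.nan)
    c_age = np.zeros(types0.shape)
    c_climate = np.zeros(types0.shape)
    c_co2 = np.zeros(types0.shape)
    flag = np.zeros(types0.shape, dtype=int)  # 1 remain, 2 replace, 3 lost
    for r in range(rows):
        for c in range(cols):
            t0 = types0[r, c]
            if t0 == 0:
                continue
            if prob[t0][r, c] > mtss[t0]:
                new_type, new_age, fl = t0, age0[r, c] + n_years, 1
            else:
                # most suitable *other* qualifying type; ties -> lower code
                best, best_p = None, -1.0
                for code in sorted(prob):
                    if code == t0:
                        continue
                    p = prob[code][r, c]
                    if p > mtss[code] and p > best_p:
                        best, best_p = code, p
                if best is not None:
                    new_type, new_age, fl = best, half_age, 2
                else:
                    out_type[r, c] = 0
                    flag[r, c] = 3
                    continue
            out_type[r, c] = new_type
            out_age[r, c] = new_age
            ca, cc, co = pixel_components(
                fits[new_type], new_age, mat0[r, c], map0[r, c],
                mat_f[r, c], map_f[r, c], F)
            c_age[r, c], c_climate[r, c], c_co2[r, c] = ca, cc, co
            flag[r, c] = fl
    return {"types": out_type, "age": out_age, "c_age": c_age,
            "c_climate": c_climate, "c_co2": c_co2, "flag": flag}


def afforestation_oracle(nature_out, prob, mtss, fits, mat0, map0, mat_f,
                         map_f, F, area_needed_mha, cell_area_mha, half_age,
                         seed):
    """Literal transcription of random allocation on suitable non-forest pixels."""
    types = nature_out["types"].copy()
    age = nature_out["age"].copy()
    c_age = nature_out["c_age"].copy()
    c_climate = nature_out["c_climate"].copy()
    c_co2 = nature_out["c_co2"].copy()
    planted = np.zeros(types.shape, dtype=bool)

    rows, cols = types.shape
    best_code = np.zeros(types.shape, dtype=int)
    for r in range(rows):
        for c in range(cols):
            best, best_p = 0, -1.0
            for code in sorted(prob):
                p = prob[code][r, c]
                if p > mtss[code] and p > best_p:
                    best, best_p = code, p
            best_code[r, c] = best
    candidates = np.flatnonzero((types.ravel() == 0) & (best_code.ravel() > 0))
    if area_needed_mha > 0 and candidates.size:
        rng = np.random.default_rng(seed)
        order = rng.permutation(candidates)
        acc = 0.0
        for flat in order:
            if acc >= area_needed_mha:
                break
            r, c = divmod(flat, cols)
            code = best_code[r, c]
            types[r, c] = code
            age[r, c] = half_age
            ca, cc, co = pixel_components(fits[code], half_age, mat0[r, c],
                                          map0[r, c], mat_f[r, c], map_f[r, c], F)
            c_age[r, c], c_climate[r, c], c_co2[r, c] = ca, cc, co
            planted[r, c] = True
            acc += cell_area_mha[r, c]
    return {"types": types, "age": age, "c_age": c_age,
            "c_climate": c_climate, "c_co2": c_co2, "planted": planted}
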