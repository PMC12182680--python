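import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forestcarbon.errors import FitError, SelectionError
from forestcarbon.growth import (GrowthFit, age_component, asymptote,
                                 climate_component, eval_age_climate,
                                 eval_growth, fit_family, half_saturation_age,
                                 select_model)
from conftest import survey_from


# --- curve evaluation -------------------------------------------------------


def test_mm_limit_is_asymptote_and_origin():
    params = {"mu": 59.98, "k": 357.71}
    assert eval_growth("MM", params, 1e9) == pytest.approx(59.98, abs=1e-4)
    assert eval_growth("MM", params, 0.0) == 0.0


def test_logistic_midpoint_at_unit_shape():
    assert eval_growth("L", {"mu": 10.0, "c": 1.0, "alpha": 0.3}, 0.0) == pytest.approx(5.0)


def test_monomolecular_starts_at_mu_times_one_minus_c():
    assert eval_growth("MO", {"mu": 100.0, "c": 1.0, "alpha": 0.1}, 0.0) == pytest.approx(0.0)


def test_half_saturation_inversion_recovers_k():
    fit = GrowthFit(family="MM", mu=58.70, k=167.44)
    assert half_saturation_age(fit) == pytest.approx(167.44, abs=1e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(mu=st.floats(1.0, 500.0), shape=st.floats(1.0, 1e5),
       alpha=st.floats(1e-3, 2.0), family=st.sampled_from(["MM", "MO", "L"]))
def test_growth_bounded_by_mu_and_nondecreasing(mu, shape, alpha, family):
    """All families stay below the asymptote and never decline with age."""
    params = ({"mu": mu, "k": shape} if family == "MM"
              else {"mu": mu, "c": max(shape, 1.0), "alpha": alpha})
    t = np.linspace(0.0, 500.0, 200)
    y = eval_growth(family, params, t)
    assert np.all(y <= mu + 1e-9)
    assert np.all(np.diff(y) >= -1e-9)


# --- climate-augmented evaluation -------------------------------------------


def test_climate_term_reduces_to_growth_when_zero(mm_fit):
    bare = GrowthFit(family="MM", mu=mm_fit.mu, k=mm_fit.k)
    t = np.linspace(0, 300, 50)
    assert np.allclose(eval_age_climate(bare, t, 10.0, 500.0),
                       eval_growth("MM", bare.growth_params, t))


def test_climate_term_arithmetic():
    # f(t)=50 at the MM half-saturation age; a=1, b=0.5, d=2
    fit = GrowthFit(family="MM", mu=100.0, k=30.0, a=1.0, b=0.5, d=2.0)
    assert eval_age_climate(fit, 30.0, 10.0, 100.0) == pytest.approx(112.0)


def test_negative_predictions_clip_to_zero():
    fit = GrowthFit(family="MM", mu=10.0, k=30.0, a=-1000.0)
    assert eval_age_climate(fit, 5.0, 10.0, 0.0) == 0.0


def test_age_component_consistency_and_monotonicity(mm_fit):
    now = age_component(mm_fit, 30.0, 8.0, 600.0)
    assert now == pytest.approx(eval_age_climate(mm_fit, 30.0, 8.0, 600.0))
    later = age_component(mm_fit, 60.0, 8.0, 600.0)
    assert later >= now  # MM is non-decreasing in age


def test_climate_component_signs(mm_fit):
    c_age = age_component(mm_fit, 40.0, 8.0, 600.0)
    same = eval_age_climate(mm_fit, 40.0, 8.0, 600.0)
    assert climate_component(same, c_age) == pytest.approx(0.0)
    wetter = eval_age_climate(mm_fit, 40.0, 8.0, 700.0)
    assert climate_component(wetter, c_age) > 0  # b > 0, MAP increase only
    assert climate_component(100.0, 120.0) == pytest.approx(-20.0)


# --- fitting ----------------------------------------------------------------


def test_noiseless_mm_recovery_to_1e3_relative():
    df = survey_from("MM", {"mu": 80.0, "k": 200.0}, a=0.0, b=0.0, d=0.0,
                     n=120, noise_sd=0.0, seed=42)
    fit = fit_family(df, "MM")
    assert fit.mu == pytest.approx(80.0, rel=1e-3)
    assert fit.k == pytest.approx(200.0, rel=1e-3)
    assert fit.rmse == pytest.approx(0.0, abs=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_noiseless_recovery_with_climate_terms():
    df = survey_from("L", {"mu": 120.0, "c": 15.0, "alpha": 0.08},
                     a=2.0, b=0.04, d=10.0, n=200, noise_sd=0.0, seed=1)
    fit = fit_family(df, "L")
    assert fit.mu == pytest.approx(120.0, rel=1e-3)
    assert fit.a == pytest.approx(2.0, rel=1e-2)
    assert fit.b == pytest.approx(0.04, rel=1e-2)


def test_freeze_climate_matches_grid_search_oracle():
    """With a, b, d frozen at 0 the fit is a pure growth-curve fit."""
    df = survey_from("MM", {"mu": 90.0, "k": 100.0}, a=0.0, b=0.0, d=0.0,
                     n=100, noise_sd=5.0, seed=3)
    fit = fit_family(df, "MM", freeze_climate=True)
    t = df["t"].to_numpy()
    y = df["agb"].to_numpy()
    # coarse grid + local refinement, independent of the package optimizer
    mus = np.linspace(50, 150, 101)
    ks = np.linspace(20, 300, 141)
    rss = np.array([[np.sum((mu * t / (k + t) - y) ** 2) for k in ks]
                    for mu in mus])
    i, j = np.unravel_index(rss.argmin(), rss.shape)
    from scipy.optimize import minimize
    ref = minimize(lambda p: np.sum((p[0] * t / (p[1] + t) - y) ** 2),
                   [mus[i], ks[j]], method="Nelder-Mead").x
    assert fit.mu == pytest.approx(ref[0], rel=1e-3)
    assert fit.k == pytest.approx(ref[1], rel=1e-3)
    assert fit.a == fit.b == fit.d == 0.0


def test_degenerate_inputs_raise():
    base = pd.DataFrame({"type": 1, "t": [10, 20, 30, 40, 50, 60],
                         "agb": [50.0] * 6, "mat": [15.0] * 6, "map": [800.0] * 6})
    with pytest.raises(FitError):  # constant AGB
        fit_family(base, "MM")
    same_age = base.assign(agb=[10, 20, 30, 40, 50, 60], t=25.0)
    with pytest.raises(FitError):  # all ages equal
        fit_family(same_age, "MM")
    with pytest.raises(FitError):  # too few records
        fit_family(base.head(3), "L")


def test_constraint_c_at_least_one():
    df = survey_from("MO", {"mu": 100.0, "c": 1.2, "alpha": 0.05},
                     a=0.0, b=0.0, d=0.0, n=150, noise_sd=8.0, seed=5)
    fit = fit_family(df, "MO")
    assert fit.c >= 1.0


# --- model selection --------------------------------------------------------


def _fit(family, aic, rmse):
    kw = dict(mu=50.0, aic=aic, rmse=rmse)
    if family == "MM":
        return GrowthFit(family="MM", k=100.0, **kw)
    return GrowthFit(family=family, c=2.0, alpha=0.1, **kw)


def test_select_min_aic_and_tie_breaks():
    fits = [_fit("MM", 98.0, 5.0), _fit("L", 100.0, 4.0), _fit("MO", 105.0, 3.0)]
    assert select_model(fits).family == "MM"
    tie = [_fit("MM", 100.0, 5.0), _fit("L", 100.0, 4.0)]
    assert select_model(tie).family == "L"          # AIC tie -> lower RMSE
    full_tie = [_fit("MO", 100.0, 4.0), _fit("L", 100.0, 4.0)]
    assert select_model(full_tie).family == "L"     # family order MM > L > MO
    assert select_model([None, _fit("MM", 1.0, 1.0)]).family == "MM"
    with pytest.raises(SelectionError):
        select_model([None, None])


def test_selected_model_has_minimal_aic_among_candidates():
    df = survey_from("MM", {"mu": 100.0, "k": 60.0}, a=2.0, b=0.04, d=10.0,
                     n=150, noise_sd=10.0, seed=8)
    fits = [fit_family(df, fam) for fam in ("MM", "MO", "L")]
    chosen = select_model(fits)
    assert chosen.aic == min(f.aic for f in fits)
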