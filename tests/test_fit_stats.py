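"""Fit indices: closed forms, noncentral CI inversion, scaled differences, MIs."""

import numpy as np
import pytest
from scipy import stats as sps

from growthmap.fit_stats import (
    Candidate,
    cfi,
    modification_indices,
    rmsea,
    rmsea_ci,
    sb_scaled_diff,
)
from growthmap.fitting import FitOptions, fit_ml
from growthmap.invariance import build_measurement_spec, measurement_starts
from growthmap.panel import item_column
from growthmap.simulate import SimConfig, gen_item_panel


@pytest.mark.parametrize(
    "T,df,expected",
    [
        (1134.62, 534, 0.025),   # configural one-factor model per occasion
        (1208.75, 556, 0.025),   # loadings constrained equal over time
        (1673.23, 578, 0.032),   # intercepts additionally constrained
        (1260.73, 568, 0.026),   # five intercepts freed again
        (1267.43, 571, 0.026),   # second-order growth model
    ],
)
def test_rmsea_reproduces_reported_values(T, df, expected):
    """Published chi-square/df pairs at N=1814 map to the published RMSEAs."""
    assert round(rmsea(T, df, 1814), 3) == expected


def test_rmsea_truncates_at_zero_and_rejects_zero_df():
    assert rmsea(10.0, 20, 100) == 0.0
    with pytest.raises(ValueError):
        rmsea(5.0, 0, 100)
    with pytest.raises(ValueError):
        rmsea(5.0, 10, 1)


def test_rmsea_monotonicity():
    assert rmsea(120, 50, 200) < rmsea(150, 50, 200)
    assert rmsea(150, 50, 400) < rmsea(150, 50, 200)


def test_rmsea_ci_matches_grid_search_oracle():
    """CI endpoints agree with a brute 1e-4 grid over the noncentrality."""
    T, df, N = 30.0, 10, 100
    lo, hi = rmsea_ci(T, df, N)
    grid = np.arange(0.0, 200.0, 1e-4)
    tail = np.where(grid > 0, sps.ncx2.sf(T, df, np.maximum(grid, 1e-12)), sps.chi2.sf(T, df))
    lam_lo = grid[np.argmin(np.abs(tail - 0.05))]
    lam_hi = grid[np.argmin(np.abs(tail - 0.95))]
    assert lo == pytest.approx(np.sqrt(lam_lo / (df * (N - 1))), abs=1e-4)
    assert hi == pytest.approx(np.sqrt(lam_hi / (df * (N - 1))), abs=1e-4)


def test_rmsea_ci_lower_is_zero_when_T_at_df():
    lo, hi = rmsea_ci(10.0, 10, 200)
    assert lo == 0.0
    assert hi > 0.0


def test_rmsea_ci_shrinks_with_sample_size():
    lo1, hi1 = rmsea_ci(150.0, 50, 200)
    lo2, hi2 = rmsea_ci(150.0, 50, 2000)
    assert (hi2 - lo2) < (hi1 - lo1)


def test_cfi_formula_and_edge_cases():
    assert cfi(150, 100, 1100, 120) == pytest.approx(1 - 50 / 980, abs=1e-9)
    assert cfi(90, 100, 1100, 120) == 1.0           # T <= df
    assert cfi(1100, 120, 1100, 120) == 0.0          # model equals baseline
    with pytest.raises(ValueError):
        cfi(150, 120, 1100, 100)


def test_sb_scaled_diff_hand_arithmetic():
    """cd = (50*1.2 - 45*1.1)/5 = 2.1; T = (100*1.2 - 80*1.1)/2.1."""
    T, ddf = sb_scaled_diff(100, 50, 1.2, 80, 45, 1.1)
    assert ddf == 5
    assert T == pytest.approx(32.0 / 2.1, abs=1e-9)
    assert round(T, 3) == 15.238


def test_sb_scaled_diff_reduces_to_plain_difference():
    T, ddf = sb_scaled_diff(100, 50, 1.0, 80, 45, 1.0)
    assert (T, ddf) == (20.0, 5)


def test_sb_scaled_diff_degenerate_cases():
    with pytest.raises(ValueError, match="nested"):
        sb_scaled_diff(100, 45, 1.0, 80, 50, 1.0)
    with pytest.raises(ValueError, match="degenerate"):
        sb_scaled_diff(100, 50, 0.1, 80, 49, 60.0)
    with pytest.warns(UserWarning, match="negative"):
        T, _ = sb_scaled_diff(80, 50, 1.0, 90, 45, 1.0)
    assert T < 0


@pytest.fixture(scope="module")
def drifted_six_item_fit():
    """Strong model fitted to a 6-item panel with one planted drifted intercept."""
    cfg = SimConfig(
        n_per_occasion=(700, 560, 500), n_intermittent=30, n_items=6,
        drift_items=(3,), drift_magnitude=0.35, n_sites=1, seed=44,
    )
    panel, _ = gen_item_panel(cfg)
    spec = build_measurement_spec(6, 3, "strong")
    fit = fit_ml(
        spec, panel,
        FitOptions(start=measurement_starts(panel, spec), compute_se=False),
    )
    assert fit.converged
    return panel, spec, fit


def _refit_drop(panel, freed_item, base_T):
    spec = build_measurement_spec(6, 3, "strong", freed_items=[freed_item])
    fit = fit_ml(
        spec, panel,
        FitOptions(start=measurement_starts(panel, spec), compute_se=False),
    )
    assert fit.converged
    return base_T - fit.T


def test_modification_indices_approximate_refit_drop(drifted_six_item_fit):
    """Score-test MI tracks the actual chi-square drop from freeing each item."""
    panel, spec, fit = drifted_six_item_fit
    cands = [
        Candidate(f"item{i}", [("tau", item_column(i, t), None) for t in (2, 3)])
        for i in range(1, 7)
    ]
    mi = modification_indices(fit, cands, panel).set_index("candidate")["mi"]
    drops = {f"item{i}": _refit_drop(panel, i, fit.T) for i in range(1, 7)}
    for name, mi_val in mi.items():
        if mi_val > 5:
            assert mi_val == pytest.approx(drops[name], rel=0.15), name
    # ranking by MI equals ranking by actual refit drop
    mi_order = list(mi.sort_values(ascending=False).index)
    drop_order = sorted(drops, key=drops.get, reverse=True)
    assert mi_order[0] == drop_order[0] == "item3"  # the planted item leads
    assert mi_order == drop_order


def test_residual_report_flags_drifted_item(drifted_six_item_fit):
    """The largest standardized mean residuals implicate the planted item."""
    from growthmap.fit_stats import residual_moments

    panel, spec, fit = drifted_six_item_fit
    rep = residual_moments(fit, panel)
    top_means = rep[rep["moment"] == "mean"].head(2)["var1"].tolist()
    assert any(v.startswith("item3_") for v in top_means)


def test_modification_index_near_zero_at_unconstrained_optimum(drifted_six_item_fit):
    """Freeing a parameter already at its optimum yields MI ~ 0."""
    panel, spec, fit = drifted_six_item_fit
    # residual variance of item1 at occasion 1 is free already; a redundant
    # release direction on it must carry (numerically) zero score
    cand = Candidate("redundant", [("theta", item_column(1, 1), item_column(1, 1))])
    mi = modification_indices(fit, [cand], panel)
    assert mi.loc[0, "mi"] == pytest.approx(0.0, abs=1e-3) or np.isnan(mi.loc[0, "mi"])
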