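"""FIML estimation: saturated fits, recovery, nesting, standardization, flags."""

import numpy as np
import pytest

from growthmap.fitting import FitOptions, fit_ml, standardize
from growthmap.likelihood import fiml_loglik, pattern_stats
from growthmap.modelspec import ModelSpec, fixed, free

from .conftest import simulate_factor_data, three_indicator_spec


def saturated_spec(names):
    spec = ModelSpec(list(names), [])
    for i, v in enumerate(names):
        spec.set_intercept(v, free(f"tau_{v}"))
        for j in range(i + 1):
            spec.set_residual(names[j], v, free(f"s_{j}{i}"))
    return spec


def test_saturated_model_has_zero_T():
    """T = 2(loglik_sat - loglik_model) vanishes for a saturated spec."""
    Y = simulate_factor_data(n=120, seed=20)
    spec = saturated_spec(["y1", "y2", "y3"])
    start = {}
    S = np.cov(Y.T, bias=True)
    for i in range(3):
        start[f"tau_y{i+1}"] = Y[:, i].mean()
        for j in range(i + 1):
            start[f"s_{j}{i}"] = S[j, i]
    fit = fit_ml(spec, Y, FitOptions(start=start, compute_se=False))
    assert fit.converged
    assert fit.df == 0
    assert abs(fit.T) < 1e-6


def test_fiml_equals_complete_data_ml_without_missingness():
    """With complete data the FIML objective is the ordinary ML objective."""
    Y = simulate_factor_data(n=200, seed=21)
    spec = three_indicator_spec()
    fit = fit_ml(spec, Y, FitOptions(compute_se=False))
    # N * F_ML at the optimum equals T for complete data
    ps = pattern_stats(Y)
    theta = fit.theta
    ll = fiml_loglik(theta, spec, ps)
    assert ll == pytest.approx(fit.loglik, abs=1e-8)
    Sigma, mu = spec.implied(theta)
    S = np.cov(Y.T, bias=True)
    m = Y.mean(0)
    d = m - mu
    Si = np.linalg.inv(Sigma)
    F_ml = (
        np.log(np.linalg.det(Sigma)) + np.trace(Si @ S) + d @ Si @ d
        - np.log(np.linalg.det(S)) - 3
    )
    assert fit.T == pytest.approx(len(Y) * F_ml, rel=1e-6, abs=1e-5)


def test_parameter_recovery_three_indicator():
    """Known loadings recovered within 3 reported SEs at n=2000."""
    Y = simulate_factor_data(n=2000, loadings=(1.0, 0.8, 1.2), psi=1.0,
                             theta=0.36, mean=0.5, seed=22, miss_frac=0.25)
    spec = three_indicator_spec()
    fit = fit_ml(spec, Y, FitOptions(seed=0))
    assert fit.converged and fit.se_available
    for lab, truth in [("l2", 0.8), ("l3", 1.2), ("psi_f", 1.0)]:
        assert abs(fit.estimates[lab] - truth) < 3 * fit.se[lab], lab


def test_loglik_matches_brute_force_multistart():
    """Optimum agrees with an independent derivative-free multi-start search."""
    from scipy.optimize import minimize

    Y = simulate_factor_data(n=150, seed=23)
    spec = three_indicator_spec()
    fit = fit_ml(spec, Y, FitOptions(compute_se=False))
    ps = pattern_stats(Y)

    def nll(x):
        try:
            v = fiml_loglik(x, spec, ps)
        except FloatingPointError:
            return 1e10
        return -v if np.isfinite(v) else 1e10

    rng = np.random.default_rng(0)
    best = np.inf
    for k in range(6):
        x0 = spec.start_vector({"tau_y1": Y[:, 0].mean(), "tau_y2": Y[:, 1].mean(),
                                "tau_y3": Y[:, 2].mean()})
        if k:
            x0 = x0 + rng.normal(0, 0.2, len(x0))
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 40000, "fatol": 1e-12, "xatol": 1e-9})
        best = min(best, res.fun)
    assert -fit.loglik == pytest.approx(best, abs=1e-4)


def test_nested_spec_has_larger_T(strong_fit):
    """Adding constraints can only worsen (raise) T on the same panel."""
    from growthmap.invariance import build_measurement_spec, measurement_starts

    spec_strong, fit_strong, panel = strong_fit
    spec_weak = build_measurement_spec(12, 3, "weak")
    fit_weak = fit_ml(
        spec_weak, panel,
        FitOptions(start=measurement_starts(panel, spec_weak), compute_se=False),
    )
    assert fit_weak.converged
    assert fit_strong.T >= fit_weak.T - 1e-6


def test_heywood_case_flagged_not_hidden():
    """A negative residual-variance estimate is retained and flagged.

    The marker indicator has zero true residual variance, so in the
    just-identified model the closed-form MLE th1 = S11 - S12*S13/S23 falls
    below zero for this draw; the estimate must match that value (not be
    clipped) and carry the Heywood flag.
    """
    rng = np.random.default_rng(1)
    f = rng.normal(0, 1, 200)
    Y = np.column_stack([
        f,
        0.8 * f + rng.normal(0, 0.5, 200),
        1.1 * f + rng.normal(0, 0.5, 200),
    ])
    S = np.cov(Y.T, bias=True)
    th1_closed = S[0, 0] - S[0, 1] * S[0, 2] / S[1, 2]
    assert th1_closed < 0  # this draw produces the degenerate case
    spec = three_indicator_spec()
    fit = fit_ml(spec, Y, FitOptions(compute_se=False))
    assert fit.converged
    assert fit.heywood
    assert fit.estimates["th_y1"] == pytest.approx(th1_closed, abs=1e-4)


def test_nonconvergence_flagged_and_guarded():
    Y = simulate_factor_data(n=100, seed=24)
    spec = three_indicator_spec()
    fit = fit_ml(spec, Y, FitOptions(max_iter=1, n_restarts=0, compute_se=False,
                                     start={"psi_f": 40.0, "l2": -5.0}))
    if not fit.converged:
        with pytest.raises(RuntimeError, match="did not converge"):
            fit.require_converged()
    else:  # L-BFGS can occasionally satisfy its test in one step; flag must be honest
        fit.require_converged()


def four_indicator_spec():
    spec = ModelSpec(["y1", "y2", "y3", "y4"], ["f"])
    spec.set_loading("y1", "f", fixed(1.0))
    for v, l in [("y2", "l2"), ("y3", "l3"), ("y4", "l4")]:
        spec.set_loading(v, "f", free(l))
    for v in ("y1", "y2", "y3", "y4"):
        spec.set_intercept(v, free(f"tau_{v}"))
        spec.set_residual(v, v, free(f"th_{v}"))
    spec.set_latent_intercept("f", fixed(0.0))
    spec.set_latent_cov("f", "f", free("psi"))
    spec.start = {"l2": 1, "l3": 1, "l4": 1, "psi": 0.5,
                  "th_y1": 0.3, "th_y2": 0.3, "th_y3": 0.3, "th_y4": 0.3}
    return spec


def test_robust_scaling_factor_calibration():
    """The trace-difference chi-square scaling factor is ~1 for normal data
    and rises well above 1 for elliptical heavy-tailed data."""
    rng = np.random.default_rng(6)
    lam = np.array([1.0, 0.8, 1.2, 0.9])
    n = 6000
    w = np.sqrt(rng.chisquare(5, n) / 5)  # scale mixture -> heavy tails
    f_h = rng.normal(0, 1, n) / w
    Y_heavy = np.outer(f_h, lam) + rng.normal(0, 0.6, (n, 4)) / w[:, None]
    fit_h = fit_ml(four_indicator_spec(), Y_heavy, FitOptions(robust=True))
    assert fit_h.c > 1.5

    f_n = rng.normal(0, 1, n)
    Y_norm = np.outer(f_n, lam) + rng.normal(0, 0.6, (n, 4))
    fit_n = fit_ml(four_indicator_spec(), Y_norm, FitOptions(robust=True))
    assert fit_n.c == pytest.approx(1.0, abs=0.1)
    # robust (sandwich) SEs agree with ML SEs under correct specification
    fit_ml_se = fit_ml(four_indicator_spec(), Y_norm, FitOptions(robust=False))
    for k in fit_ml_se.se:
        assert fit_n.se[k] / fit_ml_se.se[k] == pytest.approx(1.0, abs=0.15)


def test_stdy_and_stdyx_definitions():
    """stdy divides by outcome SD; stdyx additionally multiplies by predictor SD."""
    spec = ModelSpec(["y", "x"], ["fy", "fx"])
    spec.set_loading("y", "fy", fixed(1.0))
    spec.set_loading("x", "fx", fixed(1.0))
    spec.set_residual("y", "y", fixed(0.0))
    spec.set_residual("x", "x", fixed(0.0))
    spec.set_regression("fy", "fx", free("b"))
    spec.set_latent_cov("fx", "fx", free("vx"))
    spec.set_latent_cov("fy", "fy", free("vy"))
    spec.set_intercept("y", free("ty"))
    spec.set_intercept("x", free("tx"))
    rng = np.random.default_rng(31)
    x = rng.normal(0, 0.5, 4000)
    y = 1.0 * x + rng.normal(0, np.sqrt(4.0 - 0.25), 4000)  # total SD(y) = 2
    Y = np.column_stack([y, x])
    spec.start = {"vx": 0.25, "vy": 3.0, "b": 0.5}
    fit = fit_ml(spec, Y, FitOptions(seed=0))
    assert fit.converged
    tab_yx = standardize(fit, "stdyx").set_index("label")
    tab_y = standardize(fit, "stdy").set_index("label")
    b, vx = fit.estimates["b"], fit.estimates["vx"]
    vy_total = fit.estimates["vy"] + b * b * vx
    assert tab_y.loc["b", "stdy"] == pytest.approx(b / np.sqrt(vy_total), rel=1e-9)
    assert tab_yx.loc["b", "stdyx"] == pytest.approx(
        b * np.sqrt(vx) / np.sqrt(vy_total), rel=1e-9
    )
    # against the planted values: b=1, SD(x)=0.5, SD(y)=2
    assert tab_y.loc["b", "stdy"] == pytest.approx(0.5, abs=0.05)
    assert tab_yx.loc["b", "stdyx"] == pytest.approx(0.25, abs=0.03)


def test_standardized_loading_matches_covariance_algebra():
    """Standardized loading = lam * SD(eta) / SD(y) from implied variances."""
    Y = simulate_factor_data(n=400, seed=25)
    spec = three_indicator_spec()
    fit = fit_ml(spec, Y, FitOptions(seed=0))
    tab = standardize(fit, "stdyx")
    Sigma, _ = spec.implied(fit.theta)
    psi = fit.estimates["psi_f"]
    lam2 = fit.estimates["l2"]
    expected = lam2 * np.sqrt(psi) / np.sqrt(Sigma[1, 1])
    got = tab.set_index("path").loc["y2~f", "stdyx"]
    assert got == pytest.approx(expected, rel=1e-9)
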