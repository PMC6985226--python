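"""Shared fixtures: small synthetic panels and model specs.

Everything is generated programmatically at fixed seeds; session scope keeps
the heavier panels and fits shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from growthmap.fitting import FitOptions, fit_ml
from growthmap.invariance import build_measurement_spec
from growthmap.modelspec import ModelSpec, fixed, free
from growthmap.simulate import SimConfig, gen_item_panel


def three_indicator_spec(latent_mean_free: bool = False) -> ModelSpec:
    """Marker-identified 1-factor, 3-indicator model."""
    spec = ModelSpec(["y1", "y2", "y3"], ["f"])
    spec.set_loading("y1", "f", fixed(1.0))
    spec.set_loading("y2", "f", free("l2"))
    spec.set_loading("y3", "f", free("l3"))
    for v in ("y1", "y2", "y3"):
        spec.set_intercept(v, free(f"tau_{v}"))
        spec.set_residual(v, v, free(f"th_{v}"))
    spec.set_latent_intercept("f", free("a_f") if latent_mean_free else fixed(0.0))
    spec.set_latent_cov("f", "f", free("psi_f"))
    spec.start = {"l2": 1.0, "l3": 1.0, "psi_f": 0.5, "th_y1": 0.3, "th_y2": 0.3, "th_y3": 0.3}
    return spec


def simulate_factor_data(n=500, loadings=(1.0, 0.8, 1.2), psi=1.0, theta=0.36,
                         mean=0.5, seed=0, miss_frac=0.0):
    rng = np.random.default_rng(seed)
    f = rng.normal(mean, np.sqrt(psi), n)
    Y = np.outer(f, np.asarray(loadings)) + rng.normal(0, np.sqrt(theta), (n, len(loadings)))
    if miss_frac > 0:
        Y[rng.random(n) < miss_frac, -1] = np.nan
    return Y


@pytest.fixture(scope="session")
def null_panel():
    """Moderate panel with full strong invariance (no intercept drift)."""
    cfg = SimConfig(
        n_per_occasion=(600, 480, 420), n_intermittent=30,
        drift_items=(), n_sites=1, seed=101,
    )
    panel, truth = gen_item_panel(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def drifted_panel():
    """Panel with the default five drifting intercepts planted."""
    cfg = SimConfig(
        n_per_occasion=(900, 720, 640), n_intermittent=40, n_sites=1, seed=202,
    )
    panel, truth = gen_item_panel(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def strong_fit(null_panel):
    panel, _, _ = null_panel
    spec = build_measurement_spec(12, 3, "strong")
    from growthmap.invariance import measurement_starts

    fit = fit_ml(
        spec, panel,
        FitOptions(start=measurement_starts(panel, spec), compute_se=False, seed=0),
    )
    assert fit.converged
    return spec, fit, panel
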