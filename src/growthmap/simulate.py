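"""Synthetic study data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a 12-item Likert-type scale measuring one latent trait at three occasions,
  with linear latent growth (negative intercept-slope correlation), a
  configurable set of intercept-drifting (non-invariant) items, and the
  three-pattern dropout of a longitudinal cohort (complete baseline,
  dropout after baseline, dropout after the second occasion, intermittent
  return);
* per-participant 3D "modulated volume" images: a smoothed random field on
  a brain-like ellipsoidal support, plus a small spherical region whose
  voxel values couple linearly to each participant's latent slope.

Defaults mirror the cohort scale the package is designed around: occasion
sample sizes 1808/1414/1282, item loading profile taken from a published
12-item neuroticism factor solution (rescaled to average 1 for effects
coding), latent intercept mean 2.8 / SD 0.8 on the 1-5 Likert metric, slope
mean -0.20 / SD 0.30 over the study window, intercept-slope correlation
-0.2, and an 8 mm FWHM smoothing kernel on 2 mm voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .panel import ItemPanel, item_column

__all__ = ["SimConfig", "gen_item_panel", "gen_volumes", "STANDARDIZED_LOADINGS_T1"]

# Standardized occasion-1 loading profile of the 12-item scale (one published
# solution); used only as a realistic *shape* for the generating loadings.
STANDARDIZED_LOADINGS_T1 = np.array(
    [0.28, 0.59, 0.59, 0.50, 0.59, 0.71, 0.49, 0.44, 0.59, 0.47, 0.62, 0.49]
)

# Items whose intercepts drift across occasions by default (1-based), the
# starred subset of the published solution.
DEFAULT_DRIFT_ITEMS = (2, 4, 7, 8, 12)


@dataclass
class SimConfig:
    """All generating values for one synthetic study."""

    # panel
    n_per_occasion: Tuple[int, int, int] = (1808, 1414, 1282)
    n_intermittent: int = 100  # miss occasion 2, return at occasion 3
    n_items: int = 12
    loadings: Optional[Sequence[float]] = None  # raw; default: table profile / mean
    intercepts: Optional[Sequence[float]] = None  # effects-coded (sum 0)
    drift_items: Sequence[int] = DEFAULT_DRIFT_ITEMS
    drift_magnitude: float = 0.4  # raw units at final occasion (~0.5 latent SD)
    basis: Tuple[float, float, float] = (0.0, 0.5, 1.0)
    intercept_mean: float = 2.8
    intercept_sd: float = 0.8
    slope_mean: float = -0.20
    slope_sd: float = 0.30
    intercept_slope_corr: float = -0.2
    disturbance_sd: float = 0.15  # occasion-specific latent disturbance
    residual_sd: Optional[Sequence[float]] = None  # per item; default from loadings
    sex_effect_intercept: float = 0.3  # females (coded 1) higher baseline
    sex_effect_slope: float = 0.1
    n_sites: int = 3
    site_sd: float = 0.08  # SD of site offsets on the latent intercept
    discretize: bool = False  # threshold responses to the 1-5 Likert grid
    # volumes
    grid_shape: Tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 2.0
    effect_center: Tuple[int, int, int] = (10, 10, 10)
    effect_radius: float = 4.0  # voxels
    coupling: float = 1.0  # sized for a clearly suprathreshold effect at n ~ 200
    fwhm_mm: float = 8.0
    background_sd: float = 1.0
    local_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in (self.intercept_sd, self.slope_sd, self.disturbance_sd)):
            raise ValueError("all SDs must be positive")
        if self.effect_radius < 0:
            raise ValueError("effect radius must be non-negative")
        n1, n2, n3 = self.n_per_occasion
        if not (n1 >= n2 >= n3):
            raise ValueError("dropout counts must be non-increasing across occasions")
        if self.n_intermittent > n1 - n2 or self.n_intermittent > n3:
            raise ValueError("infeasible intermittent-dropout count")
        if n3 - self.n_intermittent > n2:
            raise ValueError("infeasible dropout pattern: more completers than occasion-2 N")

    def raw_loadings(self) -> np.ndarray:
        if self.loadings is not None:
            lam = np.asarray(self.loadings, dtype=float)
        else:
            prof = STANDARDIZED_LOADINGS_T1[: self.n_items]
            lam = prof / prof.mean()
        if len(lam) != self.n_items:
            raise ValueError("loadings length must equal n_items")
        return lam

    def raw_intercepts(self) -> np.ndarray:
        if self.intercepts is not None:
            tau = np.asarray(self.intercepts, dtype=float)
            if abs(tau.sum()) > 1e-8:
                raise ValueError("intercepts must sum to zero (effects coding)")
            return tau
        rng = np.random.default_rng(12)  # fixed aesthetic scatter, not per-run noise
        tau = rng.normal(0.0, 0.15, self.n_items)
        return tau - tau.mean()

    def raw_residual_sd(self) -> np.ndarray:
        if self.residual_sd is not None:
            return np.asarray(self.residual_sd, dtype=float)
        # choose residuals so occasion-1 standardized loadings match the
        # published profile: theta = (lam*sd)^2 * (1/s^2 - 1)
        lam = self.raw_loadings()
        s = STANDARDIZED_LOADINGS_T1[: self.n_items]
        occ1_var = self.intercept_sd**2 + self.disturbance_sd**2
        theta = (lam**2) * occ1_var * (1.0 / s**2 - 1.0)
        return np.sqrt(theta)


def _dropout_masks(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """n x 3 boolean observation matrix with the four dropout patterns."""
    n1, n2, n3 = cfg.n_per_occasion
    n_int = cfg.n_intermittent
    n_completer = n3 - n_int
    n_drop_after_2 = n2 - n_completer
    n_bl_only = n1 - n2 - n_int
    counts = [n_completer, n_drop_after_2, n_int, n_bl_only]
    pats = [
        (True, True, True),
        (True, True, False),
        (True, False, True),
        (True, False, False),
    ]
    rows = np.repeat(np.arange(4), counts)
    rng.shuffle(rows)  # missing completely at random within occasion
    return np.array([pats[r] for r in rows], dtype=bool)


def gen_item_panel(cfg: SimConfig) -> Tuple[ItemPanel, Dict]:
    """Generate an item panel; returns ``(panel, truth)``.

    ``truth`` records every generating value including per-participant
    latent intercepts/slopes and the planted intercept drifts.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_occasion[0]
    lam = cfg.raw_loadings()
    tau = cfg.raw_intercepts()
    res_sd = cfg.raw_residual_sd()

    # covariates
    sex = rng.integers(0, 2, n).astype(float)  # 1 = female
    site = rng.integers(0, cfg.n_sites, n)
    site_offsets = (
        rng.normal(0.0, cfg.site_sd, cfg.n_sites) if cfg.n_sites > 1 else np.zeros(1)
    )
    site_offsets -= site_offsets[0]  # first site is the reference

    cov = np.array(
        [
            [cfg.intercept_sd**2, cfg.intercept_slope_corr * cfg.intercept_sd * cfg.slope_sd],
            [cfg.intercept_slope_corr * cfg.intercept_sd * cfg.slope_sd, cfg.slope_sd**2],
        ]
    )
    growth = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    intercept = (
        cfg.intercept_mean
        + growth[:, 0]
        + cfg.sex_effect_intercept * sex
        + site_offsets[site]
    )
    slope = cfg.slope_mean + growth[:, 1] + cfg.sex_effect_slope * sex

    basis = np.asarray(cfg.basis, dtype=float)
    drift = np.zeros((cfg.n_items, 3))
    drift_ramp = (0.6, 1.0)  # fraction of drift_magnitude applied at occasions 2, 3
    signs = {item: (1 if k % 2 == 0 else -1) for k, item in enumerate(sorted(set(cfg.drift_items)))}
    for item in sorted(set(cfg.drift_items)):
        drift[item - 1, 1] = signs[item] * cfg.drift_magnitude * drift_ramp[0]
        drift[item - 1, 2] = signs[item] * cfg.drift_magnitude * drift_ramp[1]

    data: Dict[str, np.ndarray] = {}
    eta_all = np.empty((n, 3))
    for t in range(3):
        disturb = rng.normal(0.0, cfg.disturbance_sd, n)
        eta = intercept + basis[t] * slope + disturb
        eta_all[:, t] = eta
        eps = rng.normal(0.0, 1.0, (n, cfg.n_items)) * res_sd
        Y = tau + drift[:, t] + np.outer(eta, lam) + eps
        if cfg.discretize:
            Y = np.clip(np.rint(Y), 1, 5)
        for i in range(cfg.n_items):
            data[item_column(i + 1, t + 1)] = Y[:, i]

    obs = _dropout_masks(cfg, rng)
    df = pd.DataFrame(data)
    for t in range(3):
        cols = [item_column(i, t + 1) for i in range(1, cfg.n_items + 1)]
        df.loc[~obs[:, t], cols] = np.nan
    df["sex"] = sex
    df["site"] = pd.Categorical([f"site{s+1}" for s in site])

    panel = ItemPanel(df=df, n_items=cfg.n_items, n_occasions=3)
    truth = {
        "config": _cfg_dict(cfg),
        "loadings": lam.tolist(),
        "intercepts": tau.tolist(),
        "residual_sd": res_sd.tolist(),
        "drift": drift.tolist(),
        "site_offsets": site_offsets.tolist(),
        "latent_intercept": intercept.tolist(),
        "latent_slope": slope.tolist(),
        "eta": eta_all.tolist(),
        "observed": obs.tolist(),
    }
    return panel, truth


def _cfg_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def smooth_field(field: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian smoothing (normalized kernel, reflective boundary).

    With a symmetric kernel and reflective boundaries the volume sum is
    preserved.  FWHM 0 returns the field untouched.
    """
    if fwhm_mm <= 0:
        return field
    sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm)
    return gaussian_filter(field, sigma=sigma, mode="reflect")


def _ellipsoid_mask(shape: Tuple[int, int, int]) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def gen_volumes(
    cfg: SimConfig, slopes: Sequence[float]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Dict]:
    """Per-participant volumes coupled to latent slopes.

    Returns ``(volumes, mask, affine, truth)`` where ``volumes`` is a 4D
    array (x, y, z, participant), ``mask`` the brain-like binary support,
    ``affine`` the voxel-to-mm map (isotropic scaling, centered), and
    ``truth`` holds the effect-region membership map.
    """
    slopes = np.asarray(slopes, dtype=float)
    rng = np.random.default_rng(cfg.seed + 1)
    shape = tuple(cfg.grid_shape)
    center = np.asarray(cfg.effect_center, dtype=float)
    if (center < 0).any() or (center >= np.asarray(shape)).any():
        raise ValueError("effect region center outside the grid")

    mask = _ellipsoid_mask(shape)
    grids = np.indices(shape).astype(float)
    dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    region = (dist <= cfg.effect_radius) & mask

    n = len(slopes)
    vols = np.empty(shape + (n,), dtype=np.float32)
    for k in range(n):
        background = smooth_field(
            rng.normal(0.0, cfg.background_sd, shape), cfg.fwhm_mm, cfg.voxel_size_mm
        )
        v = background
        if region.any():
            v = v.copy()
            v[region] += cfg.coupling * slopes[k] + rng.normal(
                0.0, cfg.local_noise_sd, int(region.sum())
            )
        v = np.where(mask, v, 0.0)
        vols[..., k] = v

    vs = cfg.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
    truth = {"region": region, "mask": mask, "coupling": cfg.coupling}
    return vols, mask, affine, truth
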