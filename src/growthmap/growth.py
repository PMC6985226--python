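"""Second-order latent growth curve model.

Growth factors (intercept, slope) load on the occasion-specific latent
trait factors of an accepted (partial-)strong measurement model.  The
intercept factor loads 1 on every occasion; the slope factor's basis is
either fully fixed (default linear ``[0, 0.5, 1]``, the study window on a
0-1 scale) or latent-basis (endpoints fixed, interior loadings free).
First-order latent intercepts are fixed to zero so occasion means are
carried by the growth factors (effects coding keeps them identified).

Time-invariant covariates enter as observed exogenous variables (identity
measurement block) regressing onto both growth factors; categorical
covariates are dummy-coded against a declared reference level.  A voxel
predictor slot is the same mechanism with a reserved variable name, used by
the voxelwise module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import FitOptions, FitResult, fit_ml, standardize
from .invariance import build_measurement_spec, measurement_starts
from .modelspec import LinExpr, ModelSpec, fixed, free
from .panel import ItemPanel

__all__ = [
    "GrowthSpec",
    "GrowthEstimates",
    "build_lgcm",
    "estimate_growth",
    "expand_covariates",
    "dummy_code",
    "VOXEL_VAR",
]

log = logging.getLogger(__name__)

VOXEL_VAR = "voxel"
INTERCEPT_FACTOR = "g_int"
SLOPE_FACTOR = "g_slope"


@dataclass
class GrowthSpec:
    """Growth-factor configuration.

    ``basis`` entries are floats (fixed loading) or the string ``"free"``
    (latent-basis pattern); at least two entries must be fixed.
    """

    basis: Sequence = (0.0, 0.5, 1.0)
    covariates: Sequence[str] = ()
    categorical: Dict[str, str] = field(default_factory=dict)  # column -> reference level
    predictor_slot: Optional[str] = None  # None | 'slope' | 'intercept' | 'both'

    def fixed_count(self) -> int:
        return sum(1 for b in self.basis if not _is_free(b))


def _is_free(b) -> bool:
    return isinstance(b, str) and b == "free"


def dummy_code(series: pd.Series, reference: str) -> pd.DataFrame:
    """Dummy-code a categorical column against ``reference``.

    A k-level column yields k-1 columns named ``<col>_<level>``.
    """
    levels = list(pd.unique(series.astype(str)))
    if reference not in levels:
        raise ValueError(f"reference level '{reference}' not present in {series.name}")
    cols = {}
    for lev in levels:
        if lev == reference:
            continue
        cols[f"{series.name}_{lev}"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def expand_covariates(panel: ItemPanel, growth: GrowthSpec) -> Tuple[ItemPanel, List[str]]:
    """Dummy-code categorical covariates; returns a widened panel and the
    final covariate column list."""
    df = panel.df.copy()
    cov_cols: List[str] = []
    for c in growth.covariates:
        if c not in df.columns:
            raise KeyError(f"covariate '{c}' not in panel")
        if c in growth.categorical or df[c].dtype.name in ("object", "category"):
            ref = growth.categorical.get(c)
            if ref is None:
                ref = str(sorted(df[c].astype(str).unique())[0])
                log.info("covariate '%s': using '%s' as reference level", c, ref)
            dd = dummy_code(df[c], ref)
            df = pd.concat([df.drop(columns=[c]), dd], axis=1)
            cov_cols.extend(dd.columns)
        else:
            cov_cols.append(c)
    out = ItemPanel(df=df, n_items=panel.n_items, n_occasions=panel.n_occasions)
    return out, cov_cols


def build_lgcm(
    mi_spec: ModelSpec,
    growth: GrowthSpec,
    covariate_names: Sequence[str] = (),
) -> ModelSpec:
    """Mount growth factors and covariates onto a measurement ModelSpec.

    ``mi_spec`` must be a (partial-)strong measurement spec built by
    :func:`growthmap.invariance.build_measurement_spec`; ``covariate_names``
    are already dummy-coded observed columns (see :func:`expand_covariates`).
    """
    basis = list(growth.basis)
    n_occ = len([l for l in mi_spec.latent_names if l.startswith("eta_t")])
    if len(basis) != n_occ:
        raise ValueError("basis length must match the number of occasions")
    if growth.fixed_count() < 2:
        raise ValueError("slope basis needs >= 2 fixed values for identification")

    covs = list(covariate_names)
    if growth.predictor_slot is not None:
        covs = covs + [VOXEL_VAR]
    var_names = list(mi_spec.var_names) + covs
    latents = list(mi_spec.latent_names) + [INTERCEPT_FACTOR, SLOPE_FACTOR] + [
        f"x_{c}" for c in covs
    ]
    spec = ModelSpec(var_names, latents)

    # copy the measurement block
    for i, v in enumerate(mi_spec.var_names):
        spec.tau[spec._v(v)] = mi_spec.tau[i].copy()
        for j, l in enumerate(mi_spec.latent_names):
            spec.lam[spec._v(v), spec._l(l)] = mi_spec.lam[i, j].copy()
        for i2, v2 in enumerate(mi_spec.var_names):
            spec.theta[spec._v(v), spec._v(v2)] = mi_spec.theta[i, i2].copy()

    # first-order latents: intercepts 0, disturbances free, loadings on growth
    for t in range(1, n_occ + 1):
        eta = f"eta_t{t}"
        spec.set_latent_intercept(eta, fixed(0.0))
        spec.set_latent_cov(eta, eta, free(f"dist_t{t}"))
        spec.set_regression(eta, INTERCEPT_FACTOR, fixed(1.0))
        b = basis[t - 1]
        spec.set_regression(
            eta, SLOPE_FACTOR, free(f"basis_t{t}") if _is_free(b) else fixed(float(b))
        )

    # growth factors
    spec.set_latent_intercept(INTERCEPT_FACTOR, free("int_mean"))
    spec.set_latent_intercept(SLOPE_FACTOR, free("slope_mean"))
    spec.set_latent_cov(INTERCEPT_FACTOR, INTERCEPT_FACTOR, free("int_var"))
    spec.set_latent_cov(SLOPE_FACTOR, SLOPE_FACTOR, free("slope_var"))
    spec.set_latent_cov(INTERCEPT_FACTOR, SLOPE_FACTOR, free("int_slope_cov"))

    # covariates: identity measurement, free moments, paths onto growth factors
    for c in covs:
        xl = f"x_{c}"
        spec.set_loading(c, xl, fixed(1.0))
        spec.set_intercept(c, fixed(0.0))
        spec.set_residual(c, c, fixed(0.0))
        spec.set_latent_intercept(xl, free(f"mean_{c}"))
        spec.set_latent_cov(xl, xl, free(f"var_{c}"))
        for c2 in covs:
            if c2 == c:
                break
            spec.set_latent_cov(xl, f"x_{c2}", free(f"cov_{c2}_{c}"))
        if c == VOXEL_VAR:
            slot = growth.predictor_slot
            if slot in ("slope", "both"):
                spec.set_regression(SLOPE_FACTOR, xl, free("b_slope_voxel"))
            if slot in ("intercept", "both"):
                spec.set_regression(INTERCEPT_FACTOR, xl, free("b_int_voxel"))
        else:
            spec.set_regression(INTERCEPT_FACTOR, xl, free(f"b_int_{c}"))
            spec.set_regression(SLOPE_FACTOR, xl, free(f"b_slope_{c}"))

    starts = dict(mi_spec.start)
    starts.update(
        {
            "int_var": 0.4,
            "slope_var": 0.1,
            "int_slope_cov": -0.02,
            **{f"dist_t{t}": 0.05 for t in range(1, n_occ + 1)},
            **{f"basis_t{t}": 0.5 for t in range(1, n_occ + 1)},
            **{f"var_{c}": 0.25 for c in covs},
        }
    )
    spec.start = {k: v for k, v in starts.items() if k in set(spec.free_params)}
    return spec


@dataclass
class GrowthEstimates:
    intercept_mean: float
    intercept_mean_se: Optional[float]
    slope_mean: float
    slope_mean_se: Optional[float]
    intercept_var: float
    intercept_var_se: Optional[float]
    slope_var: float
    slope_var_se: Optional[float]
    intercept_slope_cov: float
    intercept_slope_corr: float
    covariate_paths: pd.DataFrame
    disturbances: Dict[str, float]
    basis: List[float]
    fit: FitResult
    heywood: bool

    def to_dict(self) -> dict:
        return {
            "intercept_mean": self.intercept_mean,
            "intercept_mean_se": self.intercept_mean_se,
            "slope_mean": self.slope_mean,
            "slope_mean_se": self.slope_mean_se,
            "intercept_var": self.intercept_var,
            "intercept_var_se": self.intercept_var_se,
            "slope_var": self.slope_var,
            "slope_var_se": self.slope_var_se,
            "intercept_slope_cov": self.intercept_slope_cov,
            "intercept_slope_corr": self.intercept_slope_corr,
            "disturbances": self.disturbances,
            "basis": self.basis,
            "covariate_paths": self.covariate_paths.to_dict(orient="records"),
            "heywood": self.heywood,
            "T": self.fit.T,
            "df": self.fit.df,
            "n": self.fit.n,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def table(self) -> pd.DataFrame:
        """Growth-parameter table shaped like a standard LGCM report."""
        rows = [
            ("intercept_mean", self.intercept_mean, self.intercept_mean_se),
            ("slope_mean", self.slope_mean, self.slope_mean_se),
            ("intercept_var", self.intercept_var, self.intercept_var_se),
            ("slope_var", self.slope_var, self.slope_var_se),
            ("intercept_slope_cov", self.intercept_slope_cov, None),
            ("intercept_slope_corr", self.intercept_slope_corr, None),
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


def estimate_growth(
    spec: ModelSpec,
    panel: ItemPanel,
    opts: Optional[FitOptions] = None,
) -> GrowthEstimates:
    """Fit a built LGCM spec and extract growth-parameter estimates."""
    opts = opts or FitOptions()
    starts = measurement_starts(panel, spec)
    # occasion means feed the growth means: intercept ~ occasion-1 mean level
    occ1 = float(np.nanmean(panel.matrix(panel.occasion_columns(1))))
    occT = float(np.nanmean(panel.matrix(panel.occasion_columns(panel.n_occasions))))
    starts["int_mean"] = occ1
    starts["slope_mean"] = occT - occ1
    for c in spec.var_names:
        if f"mean_{c}" in spec.free_params and c in panel.df.columns:
            starts[f"mean_{c}"] = float(panel.df[c].mean())
            starts[f"var_{c}"] = float(panel.df[c].var())
    if opts.start:
        starts.update(opts.start)
    merged = FitOptions(
        start=starts,
        max_iter=opts.max_iter,
        tol=opts.tol,
        n_restarts=opts.n_restarts,
        seed=opts.seed,
        compute_se=opts.compute_se,
        robust=opts.robust,
        free_labels=opts.free_labels,
    )
    fit = fit_ml(spec, panel, merged)
    fit.require_converged()
    est, se = fit.estimates, fit.se

    iv, sv = est["int_var"], est["slope_var"]
    cov = est["int_slope_cov"]
    denom = np.sqrt(max(iv, 0.0) * max(sv, 0.0))
    corr = float(cov / denom) if denom > 0 else np.nan

    cov_rows = []
    std = None
    if fit.se_available:
        try:
            std_tab = standardize(fit, "stdyx")
            stdy_tab = standardize(fit, "stdy")
            std = std_tab.set_index("label")["stdyx"].to_dict()
            stdy = stdy_tab.set_index("label")["stdy"].to_dict()
        except (ZeroDivisionError, RuntimeError):
            std = stdy = None
    for lab, v in est.items():
        if lab.startswith("b_"):
            cov_rows.append(
                {
                    "path": lab,
                    "raw": v,
                    "se": se.get(lab),
                    "stdyx": None if std is None else std.get(lab),
                    "stdy": None if std is None else stdy.get(lab),
                }
            )
    basis = []
    for t in range(1, panel.n_occasions + 1):
        lab = f"basis_t{t}"
        if lab in est:
            basis.append(float(est[lab]))
        else:
            mats = spec.build(fit.theta)
            basis.append(float(mats["beta"][spec._l(f"eta_t{t}"), spec._l(SLOPE_FACTOR)]))
    return GrowthEstimates(
        intercept_mean=est["int_mean"],
        intercept_mean_se=se.get("int_mean"),
        slope_mean=est["slope_mean"],
        slope_mean_se=se.get("slope_mean"),
        intercept_var=iv,
        intercept_var_se=se.get("int_var"),
        slope_var=sv,
        slope_var_se=se.get("slope_var"),
        intercept_slope_cov=cov,
        intercept_slope_corr=corr,
        covariate_paths=pd.DataFrame(
            cov_rows, columns=["path", "raw", "se", "stdyx", "stdy"]
        ),
        disturbances={k: v for k, v in est.items() if k.startswith("dist_")},
        basis=basis,
        fit=fit,
        heywood=fit.heywood,
    )
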