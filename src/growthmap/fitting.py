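"""FIML estimation of a ModelSpec on an item panel.

Quasi-Newton (L-BFGS) on the unconstrained free-parameter vector; variances
are deliberately not log-transformed so that Heywood cases (negative
residual-variance estimates) remain representable and are flagged rather
than hidden.  Points where an implied pattern submatrix loses positive
definiteness act as a barrier (large objective, zero gradient), which the
line search backs away from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .likelihood import (
    NonEvaluablePoint,
    PatternStats,
    casewise_scores,
    loglik_and_grad,
    pattern_stats,
    saturated_moments,
)
from .modelspec import ModelSpec, SingularStructureError

__all__ = ["FitOptions", "FitResult", "fit_ml", "standardize", "observed_information"]

log = logging.getLogger(__name__)

_BARRIER = 1e12


@dataclass
class FitOptions:
    start: Optional[Mapping[str, float]] = None
    max_iter: int = 2000
    tol: float = 1e-9
    n_restarts: int = 3
    seed: int = 0
    compute_se: bool = True
    robust: bool = False
    free_labels: Optional[Sequence[str]] = None  # fix all other params at start values


@dataclass
class FitResult:
    """Estimates and diagnostics of one FIML fit."""

    spec: ModelSpec
    estimates: Dict[str, float]
    se: Dict[str, Optional[float]]
    vcov: Optional[np.ndarray]
    loglik: float
    loglik_sat: float
    T: float
    df: int
    c: float
    n: int
    converged: bool
    heywood: bool
    se_available: bool
    message: str = ""
    n_iter: int = 0
    seed: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.estimates[k] for k in self.spec.free_params])

    def require_converged(self) -> "FitResult":
        if not self.converged:
            raise RuntimeError(f"model did not converge: {self.message}")
        return self

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "se": self.se,
            "loglik": self.loglik,
            "loglik_sat": self.loglik_sat,
            "T": self.T,
            "df": self.df,
            "scaling_factor": self.c,
            "n": self.n,
            "converged": self.converged,
            "heywood": self.heywood,
            "se_available": self.se_available,
            "message": self.message,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _panel_matrix(spec: ModelSpec, panel) -> np.ndarray:
    if hasattr(panel, "matrix"):
        return panel.matrix(spec.var_names)
    return np.asarray(panel, dtype=float)


def default_starts(spec: ModelSpec, pstats: Sequence[PatternStats], p: int) -> Dict[str, float]:
    """Data-informed fallback starts layered under builder-provided ones.

    Intercept-like parameters start at the available-case mean of the first
    variable they enter; variance-like parameters at half the available-case
    variance; everything else keeps the builder default (or zero).
    """
    mu = np.zeros(p)
    cnt = np.zeros(p)
    ss = np.zeros(p)
    for ps in pstats:
        mu[ps.obs] += ps.n * ps.mean
        cnt[ps.obs] += ps.n
    mu /= np.maximum(cnt, 1)
    for ps in pstats:
        d = ps.mean - mu[ps.obs]
        ss[ps.obs] += ps.n * (np.diag(ps.scatter) + d**2)
    var = ss / np.maximum(cnt, 1)

    starts: Dict[str, float] = {}
    comp = spec._compile()
    for k, lab in enumerate(comp["labels"]):
        for name, idx, coeff in comp["entries"][k]:
            if name == "tau":
                starts.setdefault(lab, float(mu[idx[0]]))
                break
            if name == "theta" and idx[0] == idx[1]:
                starts.setdefault(lab, float(0.5 * var[idx[0]]))
                break
    return starts


def fit_ml(spec: ModelSpec, panel, opts: Optional[FitOptions] = None) -> FitResult:
    """Fit ``spec`` to ``panel`` by FIML; returns a :class:`FitResult`.

    ``opts.n_restarts`` jittered restarts are attempted only if the primary
    start fails to converge.  ``opts.free_labels`` restricts estimation to a
    parameter subset (remaining parameters pinned at their start values),
    used by the voxelwise fixed-measurement mode.
    """
    opts = opts or FitOptions()
    Y = _panel_matrix(spec, panel)
    if Y.shape[0] == 0:
        raise ValueError("empty panel")
    if spec.df < 0:
        raise ValueError(f"model not identified: df = {spec.df} < 0")
    pstats = pattern_stats(Y)

    work_spec = spec
    start_map = dict(default_starts(spec, pstats, Y.shape[1]))
    start_map.update(spec.start)
    if opts.start:
        start_map.update(opts.start)
    if opts.free_labels is not None:
        fixed_vals = {
            lab: start_map.get(lab, 0.0)
            for lab in spec.free_params
            if lab not in set(opts.free_labels)
        }
        work_spec = spec.fix_params(fixed_vals)

    labels = work_spec.free_params
    x0 = np.array([start_map.get(lab, 0.0) for lab in labels])

    def objective(x):
        try:
            ll, g = loglik_and_grad(x, work_spec, pstats)
        except (NonEvaluablePoint, SingularStructureError, np.linalg.LinAlgError):
            return _BARRIER, np.zeros_like(x)
        if not np.isfinite(ll):
            return _BARRIER, np.zeros_like(x)
        return -ll, -g

    rng = np.random.default_rng(opts.seed)
    best = None
    n_attempts = 0
    for attempt in range(1 + max(0, opts.n_restarts)):
        x_init = x0 if attempt == 0 else x0 + rng.normal(0, 0.1 * (1 + np.abs(x0)))
        res = minimize(
            objective,
            x_init,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": opts.max_iter, "ftol": opts.tol, "gtol": 1e-7},
        )
        n_attempts += 1
        ok = bool(res.success) and res.fun < _BARRIER / 2
        if best is None or (ok and not best[1]) or (ok and res.fun < best[0].fun - 1e-10):
            best = (res, ok)
        if best[1]:
            break
    res, converged = best
    theta_hat = res.x
    ll_model = -res.fun if res.fun < _BARRIER / 2 else -np.inf

    mu_sat, Sigma_sat, ll_sat, sat_ok = saturated_moments(pstats)
    T = max(0.0, 2.0 * (ll_sat - ll_model)) if np.isfinite(ll_model) else np.inf
    # df bookkeeping is against the estimated parameter count
    df = spec.n_moments - len(labels)

    # Heywood screening: any variance-like cell (diagonal of theta / psi) negative
    mats = work_spec.build(theta_hat)
    heywood = bool(
        (np.diag(mats["theta"]) < -1e-8).any() or (np.diag(mats["psi"]) < -1e-8).any()
    )

    se: Dict[str, Optional[float]] = {lab: None for lab in labels}
    vcov = None
    se_available = False
    c_factor = 1.0
    if opts.compute_se and converged:
        info = observed_information(work_spec, theta_hat, pstats)
        try:
            vcov = np.linalg.inv(info)
            diag = np.diag(vcov)
            if (diag <= 0).any():
                raise np.linalg.LinAlgError
            if opts.robust:
                B = _score_outer(work_spec, theta_hat, Y)
                vcov = vcov @ B @ vcov
                diag = np.diag(vcov)
            se = {lab: float(np.sqrt(diag[i])) for i, lab in enumerate(labels)}
            se_available = True
        except np.linalg.LinAlgError:
            log.warning("observed information singular; SEs not available")
            vcov = None
    if opts.robust and converged:
        c_factor = _scaling_factor(work_spec, theta_hat, Y, pstats, df)

    estimates = {lab: float(v) for lab, v in zip(labels, theta_hat)}
    if opts.free_labels is not None:
        # report pinned values too, for downstream consumers
        for lab in spec.free_params:
            if lab not in estimates:
                estimates[lab] = float(start_map.get(lab, 0.0))
                se.setdefault(lab, None)

    return FitResult(
        spec=spec if opts.free_labels is None else work_spec,
        estimates=estimates,
        se=se,
        vcov=vcov,
        loglik=ll_model,
        loglik_sat=ll_sat,
        T=T,
        df=df,
        c=c_factor,
        n=Y.shape[0],
        converged=bool(converged and np.isfinite(ll_model)),
        heywood=heywood,
        se_available=se_available,
        message=str(res.message),
        n_iter=int(res.nit) * n_attempts,
        seed=opts.seed,
    )


def observed_information(
    spec: ModelSpec, theta: np.ndarray, pstats: Sequence[PatternStats], h: float = 1e-5
) -> np.ndarray:
    """Observed information (negative loglik Hessian) by central differences
    of the analytic gradient."""
    q = len(theta)
    H = np.zeros((q, q))
    for k in range(q):
        step = h * (1.0 + abs(theta[k]))
        tp = theta.copy()
        tp[k] += step
        tm = theta.copy()
        tm[k] -= step
        _, gp = loglik_and_grad(tp, spec, pstats)
        _, gm = loglik_and_grad(tm, spec, pstats)
        H[k] = -(gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def _score_outer(spec: ModelSpec, theta: np.ndarray, Y: np.ndarray) -> np.ndarray:
    s = casewise_scores(theta, spec, Y)
    return s.T @ s


def _scaling_factor(spec, theta, Y, pstats, df) -> float:
    """Trace-based chi-square scaling factor (robust / 'MLR-style').

    c = [tr(A_sat^-1 B_sat) - tr(A_mod^-1 B_mod)] / df, with A the observed
    information and B the casewise score outer-product sum, for the
    saturated and fitted models respectively.  Equals 1 asymptotically under
    correct specification with normal data.
    """
    if df <= 0:
        return 1.0
    try:
        A_mod = observed_information(spec, theta, pstats)
        B_mod = _score_outer(spec, theta, Y)
        t_mod = float(np.trace(np.linalg.solve(A_mod, B_mod)))
        mu_s, Sigma_s, _, _ = saturated_moments(pstats)
        t_sat = _saturated_trace(mu_s, Sigma_s, pstats, Y)
        c = (t_sat - t_mod) / df
        if not np.isfinite(c) or c <= 0:
            return 1.0
        return c
    except np.linalg.LinAlgError:
        return 1.0


def _saturated_trace(mu, Sigma, pstats, Y) -> float:
    """tr(A^-1 B) for the saturated model, assembled per missingness pattern.

    Parameterization: (mu_1..mu_p, sigma_ij for i <= j).  A is the expected
    information under the fitted saturated moments; B the casewise score
    outer-product sum.
    """
    from scipy.linalg import cho_factor, cho_solve

    p = len(mu)
    ii, jj = np.triu_indices(p)
    dvec = np.where(ii == jj, 1.0, 2.0)
    q = p + len(ii)
    A = np.zeros((q, q))
    scores = np.zeros((Y.shape[0], q))
    for ps in pstats:
        o = ps.obs
        So = Sigma[np.ix_(o, o)]
        cf = cho_factor(So, lower=True, check_finite=False)
        Sinv = cho_solve(cf, np.eye(len(o)), check_finite=False)
        Sfull = np.zeros((p, p))
        Sfull[np.ix_(o, o)] = Sinv
        A[:p, :p] += ps.n * Sfull
        # I_{(ij),(kl)} = 0.25 n d_ij d_kl (a_ik a_jl + a_il a_jk)
        M1 = Sfull[np.ix_(ii, ii)] * Sfull[np.ix_(jj, jj)]
        M2 = Sfull[np.ix_(ii, jj)] * Sfull[np.ix_(jj, ii)]
        A[p:, p:] += 0.25 * ps.n * np.outer(dvec, dvec) * (M1 + M2)
        for r in ps.rows:
            d = Y[r, o] - mu[o]
            Sid = Sinv @ d
            Wfull = np.zeros((p, p))
            Wfull[np.ix_(o, o)] = -0.5 * (Sinv - np.outer(Sid, Sid))
            scores[r, o] = Sid
            scores[r, p:] = Wfull[ii, jj] * dvec
    B = scores.T @ scores
    keep = np.flatnonzero(np.diag(A) > 1e-12)
    A = A[np.ix_(keep, keep)]
    B = B[np.ix_(keep, keep)]
    return float(np.trace(np.linalg.solve(A, B)))


def standardize(fit: FitResult, style: str = "stdyx"):
    """Standardized coefficient table.

    ``stdyx`` multiplies each path by SD(predictor)/SD(outcome); ``stdy``
    divides by SD(outcome) only (the convention for binary dummy
    predictors).  Latent SDs come from the model-implied latent covariance
    ``(I-B)^-1 Psi (I-B)^-T``; observed SDs from the implied Sigma.
    """
    import pandas as pd

    if style not in ("stdyx", "stdy"):
        raise ValueError("style must be 'stdyx' or 'stdy'")
    fit.require_converged()
    spec = fit.spec
    theta = fit.theta
    mats = spec.build(theta)
    Sigma, _ = spec.implied(theta)
    B = mats["beta"]
    G = np.linalg.inv(np.eye(B.shape[0]) - B)
    Vlat = G @ mats["psi"] @ G.T
    sd_lat = np.sqrt(np.maximum(np.diag(Vlat), 0.0))
    sd_obs = np.sqrt(np.maximum(np.diag(Sigma), 0.0))

    rows = []
    # structural paths
    for i, out_name in enumerate(spec.latent_names):
        for j, pred_name in enumerate(spec.latent_names):
            expr = spec.beta[i, j]
            if expr.is_fixed and expr.const == 0.0:
                continue
            raw = float(mats["beta"][i, j])
            if sd_lat[i] <= 0:
                raise ZeroDivisionError(
                    f"model-implied variance of outcome '{out_name}' is zero"
                )
            std = raw / sd_lat[i] * (sd_lat[j] if style == "stdyx" else 1.0)
            lab = next(iter(expr.terms)) if expr.terms else ""
            rows.append(("regression", f"{out_name}~{pred_name}", lab, raw, std))
    # loadings
    for i, var in enumerate(spec.var_names):
        for j, lat in enumerate(spec.latent_names):
            expr = spec.lam[i, j]
            if expr.is_fixed and expr.const == 0.0:
                continue
            raw = float(mats["lam"][i, j])
            if sd_obs[i] <= 0:
                raise ZeroDivisionError(f"implied variance of '{var}' is zero")
            std = raw * sd_lat[j] / sd_obs[i]
            lab = next(iter(expr.terms)) if expr.terms else ""
            rows.append(("loading", f"{var}~{lat}", lab, raw, std))
    return pd.DataFrame(
        rows, columns=["kind", "path", "label", "raw", style]
    )
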