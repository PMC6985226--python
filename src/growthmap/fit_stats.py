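"""Fit indices and nested-model tests.

RMSEA is computed with the N-1 denominator (the convention that reproduces
the reported values of the study design this package emulates; the plain-N
convention is available via ``n_convention``).  The RMSEA confidence
interval inverts the noncentral chi-square distribution.  CFI is relative
to the independence baseline (free means and variances, zero covariances).
The Satorra-Bentler scaled difference combines two robust chi-squares and
their scaling factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .fitting import FitResult, observed_information
from .likelihood import loglik_and_grad, pattern_stats

__all__ = [
    "FitStatistics",
    "rmsea",
    "rmsea_ci",
    "cfi",
    "sb_scaled_diff",
    "modification_indices",
    "fit_statistics",
]


@dataclass
class FitStatistics:
    T: float
    df: int
    c: float
    rmsea: float
    rmsea_ci: Tuple[float, float]
    cfi: float
    N: int

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "df": self.df,
            "scaling_factor": self.c,
            "rmsea": self.rmsea,
            "rmsea_ci_lo": self.rmsea_ci[0],
            "rmsea_ci_hi": self.rmsea_ci[1],
            "cfi": self.cfi,
            "N": self.N,
        }


def _nm1(N: int, n_convention: str) -> float:
    if n_convention == "n-1":
        return N - 1.0
    if n_convention == "n":
        return float(N)
    raise ValueError("n_convention must be 'n-1' or 'n'")


def rmsea(T: float, df: int, N: int, n_convention: str = "n-1") -> float:
    """Root mean square error of approximation.

    ``sqrt(max(0, (T - df) / (df * (N - 1))))``.
    """
    if df <= 0:
        raise ValueError("RMSEA is undefined for df = 0")
    if N <= 1:
        raise ValueError("RMSEA requires N > 1")
    return float(np.sqrt(max(0.0, (T - df) / (df * _nm1(N, n_convention)))))


def rmsea_ci(
    T: float,
    df: int,
    N: int,
    coverage: float = 0.90,
    n_convention: str = "n-1",
) -> Tuple[float, float]:
    """Noncentral chi-square confidence interval for RMSEA.

    The lower (upper) bound solves ``P(chi2_df(lam) >= T) = (1+coverage)/2``
    (``(1-coverage)/2``) for the noncentrality ``lam``, clipped at zero, and
    maps it through ``sqrt(lam / (df * (N-1)))``.
    """
    if df <= 0:
        raise ValueError("RMSEA CI is undefined for df = 0")
    denom = df * _nm1(N, n_convention)

    def tail(lam: float) -> float:
        # increasing in lam
        return stats.ncx2.sf(T, df, lam) if lam > 0 else stats.chi2.sf(T, df)

    # lower bound: P(chi2_df(lam) >= T) = (1-coverage)/2; upper: (1+coverage)/2
    lam_lo = _solve_lambda(tail, T, df, (1.0 - coverage) / 2.0)
    lam_hi = _solve_lambda(tail, T, df, (1.0 + coverage) / 2.0)
    return (
        float(np.sqrt(max(0.0, lam_lo) / denom)),
        float(np.sqrt(max(0.0, lam_hi) / denom)),
    )


def _solve_lambda(tail, T, df, target) -> float:
    """Solve tail(lam) = target for lam >= 0; tail is increasing in lam."""
    if tail(0.0) >= target:
        return 0.0
    hi = max(T, 1.0)
    for _ in range(60):
        if tail(hi) >= target:
            break
        hi *= 2.0
    else:
        warnings.warn("noncentrality bracket expansion failed; returning bracket top")
        return hi
    return brentq(lambda l: tail(l) - target, 0.0, hi, xtol=1e-10)


def cfi(T: float, df: int, T_base: float, df_base: int) -> float:
    """Comparative fit index against the independence baseline."""
    if df_base < df:
        raise ValueError("baseline must be more restrictive than the model (df_base >= df)")
    num = max(T - df, 0.0)
    den = max(T_base - df_base, T - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(1.0 - num / den)


def sb_scaled_diff(
    T0: float, df0: int, c0: float, T1: float, df1: int, c1: float
) -> Tuple[float, int]:
    """Satorra-Bentler scaled chi-square difference.

    Model 0 is the more constrained model (df0 > df1).  Returns
    ``(T_scaled, ddf)``; a negative statistic (possible in the scaled form)
    is returned as-is with a warning.
    """
    if df0 <= df1:
        raise ValueError("model 0 must be nested in model 1 (df0 > df1)")
    ddf = df0 - df1
    cd = (df0 * c0 - df1 * c1) / ddf
    if cd <= 0:
        raise ValueError(f"degenerate scaled-difference correction cd={cd:.4g} <= 0")
    T_scaled = (T0 * c0 - T1 * c1) / cd
    if T_scaled < 0:
        warnings.warn("scaled chi-square difference is negative (degenerate case)")
    return float(T_scaled), int(ddf)


def fit_statistics(
    fit: FitResult,
    baseline: Tuple[float, int],
    coverage: float = 0.90,
    n_convention: str = "n-1",
) -> FitStatistics:
    """Assemble the full index set for a fitted model.

    ``baseline`` is the independence model's ``(T, df)`` on the same data.
    """
    T_base, df_base = baseline
    eps = rmsea(fit.T, fit.df, fit.n, n_convention)
    ci = rmsea_ci(fit.T, fit.df, fit.n, coverage, n_convention)
    return FitStatistics(
        T=fit.T,
        df=fit.df,
        c=fit.c,
        rmsea=eps,
        rmsea_ci=ci,
        cfi=cfi(fit.T, fit.df, T_base, df_base),
        N=fit.n,
    )


def residual_moments(fit: FitResult, panel) -> "pd.DataFrame":
    """Standardized residual moments: data vs model-implied means/covariances.

    The mean rows report (saturated mean − implied mean) / implied SD per
    variable; covariance rows report the residual covariance standardized by
    the implied SDs.  This is the 'inspect the residuals' companion to the
    modification indices — informative to a human, not used by automation.
    """
    import pandas as pd

    from .likelihood import pattern_stats, saturated_moments

    fit.require_converged()
    spec = fit.spec
    Y = panel.matrix(spec.var_names) if hasattr(panel, "matrix") else np.asarray(panel, float)
    mu_s, Sigma_s, _, _ = saturated_moments(pattern_stats(Y))
    Sigma, mu = spec.implied(fit.theta)
    sd = np.sqrt(np.maximum(np.diag(Sigma), 1e-12))
    rows = []
    for i, v in enumerate(spec.var_names):
        rows.append(("mean", v, "", float((mu_s[i] - mu[i]) / sd[i])))
    for i, v in enumerate(spec.var_names):
        for j in range(i, len(spec.var_names)):
            rows.append(
                (
                    "cov",
                    v,
                    spec.var_names[j],
                    float((Sigma_s[i, j] - Sigma[i, j]) / (sd[i] * sd[j])),
                )
            )
    out = pd.DataFrame(rows, columns=["moment", "var1", "var2", "std_residual"])
    return out.reindex(
        out["std_residual"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


# -- modification indices ------------------------------------------------------


@dataclass
class Candidate:
    """A release candidate: extra free directions added to fixed/constrained cells.

    ``additions`` lists (matrix_name, row_key, col_key) cells; each addition
    receives its own score direction.  Row/col keys are names (observed or
    latent) resolved against the spec.
    """

    name: str
    additions: List[Tuple[str, str, Optional[str]]]


def modification_indices(
    fit: FitResult,
    candidates: Sequence[Candidate],
    panel,
) -> "pd.DataFrame":
    """Univariate score-test modification indices, ranked descending.

    For each candidate the MI approximates the chi-square drop from freeing
    the candidate's cells, via the score statistic
    ``s' (I_cc - I_ct I_tt^-1 I_tc)^-1 s`` evaluated at the restricted
    optimum.  Candidates whose conditional information is singular get NaN.
    """
    import pandas as pd

    from .modelspec import free as free_expr

    fit.require_converged()
    spec = fit.spec
    ext = spec.copy()
    cand_labels: Dict[str, List[str]] = {}
    for c_i, cand in enumerate(candidates):
        labs = []
        for a_i, (mat, r, col) in enumerate(cand.additions):
            lab = f"__mi_{c_i}_{a_i}"
            labs.append(lab)
            if mat == "tau":
                ext.set_intercept(r, ext.tau[ext._v(r)] + free_expr(lab))
            elif mat == "lam":
                ext.set_loading(r, col, ext.lam[ext._v(r), ext._l(col)] + free_expr(lab))
            elif mat == "theta":
                ext.set_residual(r, col, ext.theta[ext._v(r), ext._v(col)] + free_expr(lab))
            elif mat == "beta":
                ext.set_regression(r, col, ext.beta[ext._l(r), ext._l(col)] + free_expr(lab))
            elif mat == "psi":
                ext.set_latent_cov(r, col, ext.psi[ext._l(r), ext._l(col)] + free_expr(lab))
            else:
                raise ValueError(f"unknown matrix {mat}")
        cand_labels[cand.name] = labs

    Y = panel.matrix(spec.var_names) if hasattr(panel, "matrix") else np.asarray(panel, float)
    pstats = pattern_stats(Y)
    labels_ext = ext.free_params
    est = dict(fit.estimates)
    theta_ext = np.array([est.get(lab, 0.0) for lab in labels_ext])
    _, score = loglik_and_grad(theta_ext, ext, pstats)
    info = observed_information(ext, theta_ext, pstats)
    base_idx = [i for i, lab in enumerate(labels_ext) if not lab.startswith("__mi_")]
    rows = []
    for cand in candidates:
        labs = cand_labels[cand.name]
        c_idx = [labels_ext.index(l) for l in labs]
        s = score[c_idx]
        I_cc = info[np.ix_(c_idx, c_idx)]
        I_ct = info[np.ix_(c_idx, base_idx)]
        I_tt = info[np.ix_(base_idx, base_idx)]
        try:
            S = I_cc - I_ct @ np.linalg.solve(I_tt, I_ct.T)
            mi = float(s @ np.linalg.solve(S, s))
            if mi < 0:
                mi = np.nan
        except np.linalg.LinAlgError:
            mi = np.nan
        rows.append((cand.name, mi, len(labs)))
    out = pd.DataFrame(rows, columns=["candidate", "mi", "n_released"])
    return out.sort_values("mi", ascending=False, na_position="last").reset_index(
        drop=True
    )
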