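"""Longitudinal measurement-invariance ladder.

A one-factor model per occasion, identified by effects coding: within each
factor the loadings average to one and the intercepts sum to zero, leaving
all latent means and variances free.  The ladder constrains, in order,

* configural — same pattern, occasion-specific loadings and intercepts;
* weak       — loadings equal across occasions;
* strong     — intercepts equal across occasions too;
* partial strong — intercepts of a searched item subset freed again.

Acceptance of a step follows the change-in-fit rule: the comparative fit
index may not drop by more than ``delta_cfi_max`` and the new RMSEA must lie
inside the previous level's RMSEA confidence interval.  The scaled
chi-square difference is computed and reported but is not decisive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fit_stats import (
    Candidate,
    FitStatistics,
    cfi,
    fit_statistics,
    modification_indices,
    sb_scaled_diff,
)
from .fitting import FitOptions, FitResult, fit_ml
from .likelihood import independence_loglik, pattern_stats, saturated_loglik
from .modelspec import LinExpr, ModelSpec, fixed, free
from .panel import ItemPanel, item_column

__all__ = [
    "build_measurement_spec",
    "build_ladder",
    "run_ladder",
    "partial_search",
    "InvarianceRules",
    "InvarianceReport",
]

log = logging.getLogger(__name__)


def _neg_sum(labels: Sequence[str], const: float = 0.0) -> LinExpr:
    return LinExpr(const, {lab: -1.0 for lab in labels})


def build_measurement_spec(
    n_items: int = 12,
    n_occasions: int = 3,
    level: str = "configural",
    freed_items: Sequence[int] = (),
    lag_residuals: bool = True,
) -> ModelSpec:
    """Measurement model at one rung of the invariance ladder.

    ``level`` is ``configural`` | ``weak`` | ``strong``; ``freed_items``
    (1-based) lists items whose intercepts stay occasion-specific in a
    partial-strong model (deviations at occasions 2..T).  Item-specific
    residual covariances across occasions are free when ``lag_residuals``.
    """
    if n_items < 3:
        raise ValueError("at least 3 items are required for identification")
    if level not in ("configural", "weak", "strong"):
        raise ValueError(f"unknown invariance level: {level}")
    freed = sorted(set(freed_items))
    if freed and level != "strong":
        raise ValueError("freed_items only apply to (partial) strong models")
    if any(i < 1 or i > n_items for i in freed):
        raise ValueError("freed item index out of range")
    if len(freed) >= n_items:
        raise ValueError("at least one intercept must remain invariant")

    occ = range(1, n_occasions + 1)
    items = range(1, n_items + 1)
    var_names = [item_column(i, t) for t in occ for i in items]
    latents = [f"eta_t{t}" for t in occ]
    spec = ModelSpec(var_names, latents)

    for t in occ:
        # loadings under effects coding: first n-1 free, last = n_items - sum
        if level == "configural":
            labs = [f"lam_i{i}_t{t}" for i in range(1, n_items)]
        else:
            labs = [f"lam_i{i}" for i in range(1, n_items)]
        for i in items:
            if i < n_items:
                expr = free(labs[i - 1])
            else:
                expr = _neg_sum(labs, const=float(n_items))
            spec.set_loading(item_column(i, t), f"eta_t{t}", expr)

        # intercepts: sum-to-zero effects coding
        if level == "strong":
            tau_labs = [f"tau_i{i}" for i in range(1, n_items)]
        else:
            tau_labs = [f"tau_i{i}_t{t}" for i in range(1, n_items)]
        for i in items:
            if i < n_items:
                expr = free(tau_labs[i - 1])
            else:
                expr = _neg_sum(tau_labs)
            if level == "strong" and t > 1 and i in freed:
                expr = expr + free(f"taudev_i{i}_t{t}")
            spec.set_intercept(item_column(i, t), expr)

        spec.set_latent_intercept(f"eta_t{t}", free(f"eta_mean_t{t}"))
        spec.set_latent_cov(f"eta_t{t}", f"eta_t{t}", free(f"eta_var_t{t}"))
        for i in items:
            spec.set_residual(
                item_column(i, t), item_column(i, t), free(f"th_i{i}_t{t}")
            )
    for t1 in occ:
        for t2 in occ:
            if t1 < t2:
                spec.set_latent_cov(
                    f"eta_t{t1}", f"eta_t{t2}", free(f"eta_cov_t{t1}_t{t2}")
                )
                if lag_residuals:
                    for i in items:
                        spec.set_residual(
                            item_column(i, t1),
                            item_column(i, t2),
                            free(f"thcov_i{i}_t{t1}_t{t2}"),
                        )

    starts: Dict[str, float] = {}
    for lab in spec.free_params:
        if lab.startswith("lam"):
            starts[lab] = 1.0
        elif lab.startswith("eta_var"):
            starts[lab] = 0.5
        elif lab.startswith("eta_cov"):
            starts[lab] = 0.3
        elif lab.startswith("thcov"):
            starts[lab] = 0.05
    spec.start = starts
    return spec


def build_ladder(
    n_items: int = 12, n_occasions: int = 3, lag_residuals: bool = True
) -> Dict[str, ModelSpec]:
    """Ordered configural -> weak -> strong ModelSpecs."""
    return {
        level: build_measurement_spec(n_items, n_occasions, level, (), lag_residuals)
        for level in ("configural", "weak", "strong")
    }


def measurement_starts(panel: ItemPanel, spec: ModelSpec) -> Dict[str, float]:
    """Data-driven starts: occasion mean into the latent mean, item deviation
    from the occasion mean into the intercept."""
    starts: Dict[str, float] = {}
    occ_means = {}
    for t in range(1, panel.n_occasions + 1):
        cols = panel.occasion_columns(t)
        m = panel.df[cols].mean()
        occ_means[t] = float(m.mean())
        starts[f"eta_mean_t{t}"] = occ_means[t]
        for i, c in enumerate(cols, start=1):
            dev = float(m[c] - occ_means[t])
            starts.setdefault(f"tau_i{i}", dev)
            starts[f"tau_i{i}_t{t}"] = dev
    return {k: v for k, v in starts.items() if k in set(spec.free_params)}


@dataclass
class InvarianceRules:
    delta_cfi_max: float = 0.01
    use_rmsea_ci_overlap: bool = True
    alpha: float = 0.05


@dataclass
class StepDecision:
    level: str
    accepted: bool
    rule: str
    delta_cfi: Optional[float] = None
    rmsea_in_prev_ci: Optional[bool] = None
    sb_T: Optional[float] = None
    sb_df: Optional[int] = None
    sb_p: Optional[float] = None


@dataclass
class InvarianceReport:
    stats: Dict[str, FitStatistics]
    fits: Dict[str, FitResult]
    decisions: List[StepDecision]
    freed_items: List[int] = field(default_factory=list)
    final_level: str = ""
    aborted_at: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "levels": {k: v.to_dict() for k, v in self.stats.items()},
            "decisions": [vars(d) for d in self.decisions],
            "freed_items": self.freed_items,
            "final_level": self.final_level,
            "aborted_at": self.aborted_at,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        dec = {d.level: d for d in self.decisions}
        for level, st in self.stats.items():
            d = dec.get(level)
            rows.append(
                {
                    "model": level,
                    "T": round(st.T, 2),
                    "df": st.df,
                    "c": round(st.c, 3),
                    "rmsea": round(st.rmsea, 4),
                    "rmsea_ci": f"[{st.rmsea_ci[0]:.4f}, {st.rmsea_ci[1]:.4f}]",
                    "cfi": round(st.cfi, 4),
                    "sb_dT": None if d is None or d.sb_T is None else round(d.sb_T, 2),
                    "sb_ddf": None if d is None else d.sb_df,
                    "decision": (
                        "" if d is None else ("accept" if d.accepted else "reject")
                    ),
                }
            )
        return pd.DataFrame(rows)


def _independence_T(panel: ItemPanel, var_names) -> Tuple[float, int]:
    ps = pattern_stats(panel.matrix(var_names))
    ll_ind, k_ind = independence_loglik(ps)
    ll_sat = saturated_loglik(ps)
    p = len(var_names)
    df_base = p * (p + 3) // 2 - k_ind
    return 2.0 * (ll_sat - ll_ind), df_base


def _fit_level(spec, panel, opts_proto: FitOptions, starts=None) -> FitResult:
    opts = FitOptions(
        start=starts,
        max_iter=opts_proto.max_iter,
        tol=opts_proto.tol,
        n_restarts=opts_proto.n_restarts,
        seed=opts_proto.seed,
        compute_se=opts_proto.compute_se,
        robust=opts_proto.robust,
    )
    return fit_ml(spec, panel, opts)


def run_ladder(
    panel: ItemPanel,
    rules: Optional[InvarianceRules] = None,
    opts: Optional[FitOptions] = None,
    lag_residuals: bool = True,
) -> InvarianceReport:
    """Fit and sequentially test the invariance ladder on ``panel``."""
    rules = rules or InvarianceRules()
    opts = opts or FitOptions(compute_se=False)
    ladder = build_ladder(panel.n_items, panel.n_occasions, lag_residuals)
    baseline = _independence_T(panel, ladder["configural"].var_names)

    stats: Dict[str, FitStatistics] = {}
    fits: Dict[str, FitResult] = {}
    decisions: List[StepDecision] = []
    prev_level = None
    warm: Dict[str, float] = {}

    for level, spec in ladder.items():
        starts = measurement_starts(panel, spec)
        starts.update({k: v for k, v in warm.items() if k in set(spec.free_params)})
        fit = _fit_level(spec, panel, opts, starts)
        if not fit.converged:
            log.warning("level %s did not converge: %s", level, fit.message)
            return InvarianceReport(
                stats=stats,
                fits=fits,
                decisions=decisions,
                final_level=prev_level or "",
                aborted_at=level,
            )
        fits[level] = fit
        stats[level] = fit_statistics(fit, baseline)
        warm.update(fit.estimates)

        if prev_level is None:
            decisions.append(StepDecision(level=level, accepted=True, rule="anchor"))
        else:
            decisions.append(
                _decide(stats[prev_level], stats[level], level, rules)
            )
            if not decisions[-1].accepted:
                if level == "strong":
                    partial_spec, freed, partial_fit = partial_search(
                        fits["weak"], spec, rules, panel, opts,
                        baseline=baseline, weak_stats=stats["weak"],
                    )
                    if partial_fit is not None:
                        fits["partial_strong"] = partial_fit
                        stats["partial_strong"] = fit_statistics(partial_fit, baseline)
                        d = _decide(
                            stats["weak"], stats["partial_strong"], "partial_strong", rules
                        )
                        decisions.append(d)
                        return InvarianceReport(
                            stats=stats,
                            fits=fits,
                            decisions=decisions,
                            freed_items=freed,
                            final_level="partial_strong" if d.accepted else "weak",
                        )
                    decisions.append(
                        StepDecision(
                            level="partial_strong",
                            accepted=False,
                            rule="no acceptable partial model",
                        )
                    )
                return InvarianceReport(
                    stats=stats,
                    fits=fits,
                    decisions=decisions,
                    final_level=prev_level,
                )
        prev_level = level

    return InvarianceReport(
        stats=stats, fits=fits, decisions=decisions, final_level=prev_level or ""
    )


def _decide(
    prev: FitStatistics, cur: FitStatistics, level: str, rules: InvarianceRules
) -> StepDecision:
    from scipy import stats as sps

    delta_cfi = prev.cfi - cur.cfi
    # "within the previous CI" counts improvement below the lower bound as fine
    in_ci = cur.rmsea <= prev.rmsea_ci[1]
    try:
        sb_T, sb_df = sb_scaled_diff(cur.T, cur.df, cur.c, prev.T, prev.df, prev.c)
        sb_p = float(sps.chi2.sf(max(sb_T, 0.0), sb_df))
    except ValueError:
        sb_T, sb_df, sb_p = None, None, None
    ok_cfi = delta_cfi <= rules.delta_cfi_max
    ok_ci = in_ci if rules.use_rmsea_ci_overlap else True
    accepted = bool(ok_cfi and ok_ci)
    rule = (
        f"delta_cfi={delta_cfi:.4f}{'<=' if ok_cfi else '>'}{rules.delta_cfi_max}"
        + (f"; rmsea {'inside' if in_ci else 'outside'} previous CI" if rules.use_rmsea_ci_overlap else "")
    )
    return StepDecision(
        level=level,
        accepted=accepted,
        rule=rule,
        delta_cfi=delta_cfi,
        rmsea_in_prev_ci=in_ci,
        sb_T=sb_T,
        sb_df=sb_df,
        sb_p=sb_p,
    )


def intercept_candidates(n_items: int, n_occasions: int, exclude=()) -> List[Candidate]:
    """One release candidate per item: free its intercept at occasions 2..T."""
    out = []
    for i in range(1, n_items + 1):
        if i in exclude:
            continue
        adds = [
            ("tau", item_column(i, t), None) for t in range(2, n_occasions + 1)
        ]
        out.append(Candidate(name=f"item{i}", additions=adds))
    return out


def partial_search(
    weak_fit: FitResult,
    strong_spec: ModelSpec,
    rules: InvarianceRules,
    panel: ItemPanel,
    opts: Optional[FitOptions] = None,
    baseline: Optional[Tuple[float, int]] = None,
    weak_stats: Optional[FitStatistics] = None,
):
    """Greedy partial-invariance search.

    Frees the cross-occasion intercept with the largest modification index,
    one item at a time, until the acceptance rules pass against the weak
    model, or until only one invariant intercept would remain.  Returns
    ``(spec, freed_items, fit)``; ``fit`` is None if no acceptable partial
    model exists.
    """
    opts = opts or FitOptions(compute_se=False)
    n_items = panel.n_items
    n_occ = panel.n_occasions
    if baseline is None:
        baseline = _independence_T(panel, strong_spec.var_names)
    if weak_stats is None:
        weak_stats = fit_statistics(weak_fit, baseline)

    freed: List[int] = []
    current_spec = strong_spec
    # refit the plain strong model warm-started from the weak solution
    fit = fit_ml(
        current_spec,
        panel,
        FitOptions(
            start={**measurement_starts(panel, current_spec), **_usable(weak_fit, current_spec)},
            compute_se=False,
            seed=opts.seed,
            n_restarts=opts.n_restarts,
        ),
    )
    while True:
        if len(freed) >= n_items - 1:
            log.info("partial search floor reached without acceptance")
            return current_spec, freed, None
        cands = intercept_candidates(n_items, n_occ, exclude=freed)
        mi = modification_indices(fit, cands, panel)
        top = mi.iloc[0]
        if not np.isfinite(top["mi"]):
            return current_spec, freed, None
        item = int(str(top["candidate"]).removeprefix("item"))
        freed.append(item)
        current_spec = build_measurement_spec(
            n_items, n_occ, "strong", freed_items=freed,
            lag_residuals=_has_lag(strong_spec),
        )
        fit = fit_ml(
            current_spec,
            panel,
            FitOptions(
                start={
                    **measurement_starts(panel, current_spec),
                    **_usable(fit, current_spec),
                },
                compute_se=False,
                seed=opts.seed,
                n_restarts=opts.n_restarts,
            ),
        )
        if not fit.converged:
            log.warning("partial model with freed %s did not converge", freed)
            return current_spec, freed, None
        st = fit_statistics(fit, baseline)
        d = _decide(weak_stats, st, "partial_strong", rules)
        if d.accepted:
            return current_spec, freed, fit


def _usable(fit: FitResult, spec: ModelSpec) -> Dict[str, float]:
    allowed = set(spec.free_params)
    return {k: v for k, v in fit.estimates.items() if k in allowed}


def _has_lag(spec: ModelSpec) -> bool:
    return any(lab.startswith("thcov") for lab in spec.free_params)
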