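"""Model representation for mean-and-covariance-structure SEM.

A model is written in the LISREL all-y form

    y = tau + Lambda eta + eps,      eps ~ N(0, Theta)
    eta = alpha + B eta + zeta,      zeta ~ N(0, Psi)

with implied moments

    mu    = tau + Lambda (I - B)^-1 alpha
    Sigma = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta.

Observed exogenous covariates are carried as observed variables with an
identity measurement block (loading 1 on their own latent, zero residual),
so regressions of growth factors on covariates live in ``B`` like any other
structural path.

Every matrix cell is a :class:`LinExpr` — an affine expression
``const + sum_k coeff_k * theta_{label_k}`` in named free parameters.  This
uniformly encodes fixed values, free parameters, cross-occasion equality
constraints (shared labels) and the effects-coding linear constraints
(per-factor loadings summing to the number of indicators, intercepts summing
to zero) by eliminating one cell per constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LinExpr",
    "free",
    "fixed",
    "ModelSpec",
    "SingularStructureError",
    "implied_moments",
]


class SingularStructureError(ValueError):
    """(I - B) is singular: a latent block feeds back on itself."""


@dataclass
class LinExpr:
    """Affine expression ``const + sum coeff * theta[label]``."""

    const: float = 0.0
    terms: Dict[str, float] = field(default_factory=dict)

    def copy(self) -> "LinExpr":
        return LinExpr(self.const, dict(self.terms))

    def __add__(self, other: "LinExpr") -> "LinExpr":
        out = self.copy()
        out.const += other.const
        for k, v in other.terms.items():
            out.terms[k] = out.terms.get(k, 0.0) + v
        return out

    def scaled(self, c: float) -> "LinExpr":
        return LinExpr(self.const * c, {k: v * c for k, v in self.terms.items()})

    @property
    def is_fixed(self) -> bool:
        return not self.terms


def free(label: str) -> LinExpr:
    return LinExpr(0.0, {label: 1.0})


def fixed(value: float) -> LinExpr:
    return LinExpr(float(value), {})


_MATRICES = ("lam", "tau", "theta", "beta", "alpha", "psi")
_SYMMETRIC = {"theta", "psi"}


class ModelSpec:
    """Pattern matrices of a mean-and-covariance-structure model.

    Parameters
    ----------
    var_names
        Observed variable names (order defines rows of ``Lambda``).
    latent_names
        Latent variable names (order defines columns of ``Lambda`` and the
        structural matrices).
    """

    def __init__(self, var_names: Sequence[str], latent_names: Sequence[str]):
        self.var_names = list(var_names)
        self.latent_names = list(latent_names)
        p, m = len(self.var_names), len(self.latent_names)
        if len(set(self.var_names)) != p or len(set(self.latent_names)) != m:
            raise ValueError("duplicate variable or latent names")
        self._vidx = {v: i for i, v in enumerate(self.var_names)}
        self._lidx = {l: i for i, l in enumerate(self.latent_names)}
        z = LinExpr()
        self.lam = np.array([[z.copy() for _ in range(m)] for _ in range(p)], dtype=object)
        self.tau = np.array([z.copy() for _ in range(p)], dtype=object)
        self.theta = np.array([[z.copy() for _ in range(m2)] for m2 in [p] * p], dtype=object)
        self.beta = np.array([[z.copy() for _ in range(m)] for _ in range(m)], dtype=object)
        self.alpha = np.array([z.copy() for _ in range(m)], dtype=object)
        self.psi = np.array([[z.copy() for _ in range(m)] for _ in range(m)], dtype=object)
        self.start: Dict[str, float] = {}
        self._compiled = None

    # -- construction helpers -------------------------------------------------

    def _v(self, name: str) -> int:
        return self._vidx[name]

    def _l(self, name: str) -> int:
        return self._lidx[name]

    def set_loading(self, var: str, latent: str, expr: LinExpr) -> None:
        self.lam[self._v(var), self._l(latent)] = expr.copy()
        self._compiled = None

    def set_intercept(self, var: str, expr: LinExpr) -> None:
        self.tau[self._v(var)] = expr.copy()
        self._compiled = None

    def set_residual(self, var1: str, var2: str, expr: LinExpr) -> None:
        i, j = self._v(var1), self._v(var2)
        self.theta[i, j] = expr.copy()
        self.theta[j, i] = expr.copy()
        self._compiled = None

    def set_regression(self, outcome: str, predictor: str, expr: LinExpr) -> None:
        self.beta[self._l(outcome), self._l(predictor)] = expr.copy()
        self._compiled = None

    def set_latent_intercept(self, latent: str, expr: LinExpr) -> None:
        self.alpha[self._l(latent)] = expr.copy()
        self._compiled = None

    def set_latent_cov(self, lat1: str, lat2: str, expr: LinExpr) -> None:
        i, j = self._l(lat1), self._l(lat2)
        self.psi[i, j] = expr.copy()
        self.psi[j, i] = expr.copy()
        self._compiled = None

    def copy(self) -> "ModelSpec":
        out = ModelSpec(self.var_names, self.latent_names)
        for name in _MATRICES:
            arr = getattr(self, name)
            dst = getattr(out, name)
            if arr.size == 0:
                continue
            it = np.nditer(arr, flags=["multi_index", "refs_ok"])
            for _ in it:
                dst[it.multi_index] = arr[it.multi_index].copy()
        out.start = dict(self.start)
        return out

    # -- compiled view --------------------------------------------------------

    @property
    def free_params(self) -> List[str]:
        return self._compile()["labels"]

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def n_moments(self) -> int:
        p = len(self.var_names)
        return p * (p + 3) // 2

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        labels: set = set()
        for name in _MATRICES:
            arr = getattr(self, name)
            for expr in arr.ravel():
                labels.update(expr.terms)
        labels = sorted(labels)
        lab_idx = {l: i for i, l in enumerate(labels)}
        consts = {}
        entries: List[List[Tuple[str, Tuple[int, ...], float]]] = [[] for _ in labels]
        for name in _MATRICES:
            arr = getattr(self, name)
            const = np.zeros(arr.shape)
            if arr.size == 0:
                consts[name] = const
                continue
            it = np.nditer(arr, flags=["multi_index", "refs_ok"])
            for _ in it:
                expr = arr[it.multi_index]
                const[it.multi_index] = expr.const
                for lab, coeff in expr.terms.items():
                    entries[lab_idx[lab]].append((name, it.multi_index, coeff))
            consts[name] = const
        self._compiled = {"labels": labels, "consts": consts, "entries": entries}
        return self._compiled

    def build(self, theta: np.ndarray) -> Dict[str, np.ndarray]:
        """Numeric matrices at parameter vector ``theta`` (free-param order)."""
        c = self._compile()
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(c["labels"]),):
            raise ValueError(
                f"theta has length {theta.shape}, expected {len(c['labels'])}"
            )
        mats = {name: c["consts"][name].copy() for name in _MATRICES}
        for k, cell_list in enumerate(c["entries"]):
            tk = theta[k]
            for name, idx, coeff in cell_list:
                mats[name][idx] += coeff * tk
        return mats

    def chain_gradient(self, grads: Mapping[str, np.ndarray]) -> np.ndarray:
        """Map matrix-space gradients to free-parameter space.

        ``grads[name][i, j]`` is d(objective)/d(cell); symmetric matrices must
        supply the full (symmetrised) matrix — off-diagonal parameters pick up
        both mirrored cells through their two entries.
        """
        c = self._compile()
        g = np.zeros(len(c["labels"]))
        for k, cell_list in enumerate(c["entries"]):
            acc = 0.0
            for name, idx, coeff in cell_list:
                acc += coeff * grads[name][idx]
            g[k] = acc
        return g

    def start_vector(self, overrides: Optional[Mapping[str, float]] = None) -> np.ndarray:
        merged = dict(self.start)
        if overrides:
            merged.update(overrides)
        return np.array([merged.get(lab, 0.0) for lab in self.free_params])

    def fix_params(self, values: Mapping[str, float]) -> "ModelSpec":
        """Return a copy with the given free parameters substituted as constants."""
        out = self.copy()
        for name in _MATRICES:
            arr = getattr(out, name)
            if arr.size == 0:
                continue
            it = np.nditer(arr, flags=["multi_index", "refs_ok"])
            for _ in it:
                expr = arr[it.multi_index]
                for lab in list(expr.terms):
                    if lab in values:
                        expr.const += expr.terms.pop(lab) * values[lab]
        out.start = {k: v for k, v in out.start.items() if k not in values}
        out._compiled = None
        return out

    def labels_in(self, matrices: Iterable[str]) -> set:
        out: set = set()
        for name in matrices:
            arr = getattr(self, name)
            for expr in arr.ravel():
                out.update(expr.terms)
        return out

    # -- implied moments ------------------------------------------------------

    def implied(self, theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        mats = self.build(theta)
        return implied_from_matrices(mats, self.latent_names)


def implied_from_matrices(mats, latent_names=None):
    B = mats["beta"]
    m = B.shape[0]
    if m == 0:
        p = mats["theta"].shape[0]
        Sigma = 0.5 * (mats["theta"] + mats["theta"].T)
        return Sigma, mats["tau"].copy()
    ImB = np.eye(m) - B
    try:
        G = np.linalg.inv(ImB)
    except np.linalg.LinAlgError:
        block = _singular_block(ImB, latent_names)
        raise SingularStructureError(
            f"structural matrix (I - B) is singular; offending latent block: {block}"
        )
    if not np.all(np.isfinite(G)) or np.linalg.cond(ImB) > 1e12:
        block = _singular_block(ImB, latent_names)
        raise SingularStructureError(
            f"structural matrix (I - B) is numerically singular; offending latent block: {block}"
        )
    lam, psi, theta_m = mats["lam"], mats["psi"], mats["theta"]
    M = G @ psi @ G.T
    Sigma = lam @ M @ lam.T + theta_m
    Sigma = 0.5 * (Sigma + Sigma.T)
    mu = mats["tau"] + lam @ (G @ mats["alpha"])
    return Sigma, mu


def _singular_block(ImB, latent_names):
    # name the latents whose rows are (near-)linearly dependent
    u, s, vt = np.linalg.svd(ImB)
    null = np.abs(vt[-1]) > 1e-8
    if latent_names is None:
        return [int(i) for i in np.where(null)[0]]
    return [latent_names[i] for i in np.where(null)[0]]


def implied_moments(theta: np.ndarray, spec: ModelSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Implied covariance ``Sigma`` and mean ``mu`` at ``theta``."""
    return spec.implied(theta)
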