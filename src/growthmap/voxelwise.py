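"""Massively univariate voxelwise stage.

For every in-mask voxel, the (standardized) voxel value is inserted into
the growth model's predictor slot — regressing the latent slope (or
intercept) on baseline local volume — the model is refit warm-started from
the voxel-free base fit, and the Wald statistic ``z = beta/SE`` is
collected into 3D maps.  Suprathreshold voxels are then clustered by
connected components and components at or below the extent threshold are
discarded (strict ``size > min_extent``).

No multiple-comparison correction is applied: the ``p < 0.001`` +
extent rule is an uncorrected exploratory threshold, and the run metadata
says so explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fitting import FitOptions, FitResult, fit_ml
from .growth import SLOPE_FACTOR, VOXEL_VAR, GrowthSpec, build_lgcm
from .modelspec import ModelSpec
from .panel import ItemPanel

__all__ = [
    "StatMap",
    "ClusterTable",
    "map_voxel_predictor",
    "threshold_cluster",
    "voxel_to_world",
    "world_to_voxel",
    "load_volumes",
    "save_statmap",
]

log = logging.getLogger(__name__)

_CONNECTIVITY = {"faces": 1, "faces_edges": 2, "faces_edges_corners": 3}


@dataclass
class StatMap:
    """Per-voxel statistics on a common grid (NaN outside the mask)."""

    beta: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: np.ndarray  # boolean: fit converged at this voxel
    mask: np.ndarray
    affine: np.ndarray
    target: str = "slope"
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {a.shape for a in (self.beta, self.z, self.p, self.converged, self.mask)}
        if len(shapes) != 1:
            raise ValueError("all StatMap arrays must share one shape")

    def convergence_rate(self) -> float:
        m = self.mask.astype(bool)
        return float(self.converged[m].mean()) if m.any() else float("nan")


@dataclass
class ClusterTable:
    """Surviving clusters, disjoint, sizes strictly above the extent threshold."""

    table: pd.DataFrame  # size, peak_stat, peak_x_mm, peak_y_mm, peak_z_mm
    members: List[np.ndarray]  # per cluster: (k, 3) voxel indices
    p_thresh: float
    min_extent: int
    connectivity: str

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def voxel_to_world(index: Sequence[float], affine: np.ndarray) -> np.ndarray:
    """Map a voxel index triplet to world mm through the affine."""
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is singular")
    hom = np.append(np.asarray(index, dtype=float), 1.0)
    return (affine @ hom)[:3]


def world_to_voxel(mm: Sequence[float], affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is singular")
    hom = np.append(np.asarray(mm, dtype=float), 1.0)
    return np.linalg.solve(affine, hom)[:3]


def _structural_labels(spec: ModelSpec) -> List[str]:
    """Free parameters that live in the structural matrices only."""
    measurement = spec.labels_in(("lam", "tau", "theta"))
    structural = spec.labels_in(("beta", "alpha", "psi"))
    return sorted(structural - measurement)


def map_voxel_predictor(
    panel: ItemPanel,
    volumes: np.ndarray,
    mask: np.ndarray,
    base_spec: ModelSpec,
    growth: GrowthSpec,
    covariate_names: Sequence[str] = (),
    target: str = "slope",
    mode: str = "fixed_measurement",
    affine: Optional[np.ndarray] = None,
    standardize_voxels: bool = True,
    opts: Optional[FitOptions] = None,
    mi_spec: Optional[ModelSpec] = None,
) -> StatMap:
    """Fit the voxel-augmented growth model at every in-mask voxel.

    ``volumes`` is (x, y, z, participant), aligned with the panel rows;
    ``base_spec`` is the voxel-free LGCM used for the warm start;
    ``mi_spec`` the measurement spec it was mounted on (required to build
    the voxel-augmented spec).  ``mode`` is ``fixed_measurement`` (pin
    loadings/intercepts/residuals at the base estimates; default) or
    ``full_refit``.
    """
    if target not in ("slope", "intercept"):
        raise ValueError("target must be 'slope' or 'intercept'")
    if mode not in ("fixed_measurement", "full_refit"):
        raise ValueError("mode must be 'fixed_measurement' or 'full_refit'")
    if volumes.shape[-1] != panel.n:
        raise ValueError(
            f"volumes carry {volumes.shape[-1]} participants but panel has {panel.n} "
            "(IDs must align)"
        )
    if not mask.any():
        raise ValueError("empty mask")
    if mi_spec is None:
        raise ValueError("mi_spec (measurement model) is required")
    opts = opts or FitOptions()
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    # base (voxel-free) fit supplies warm starts
    base_fit = fit_ml(
        base_spec,
        panel,
        FitOptions(
            start=_growth_starts(panel, base_spec),
            compute_se=False,
            seed=opts.seed,
            n_restarts=opts.n_restarts,
        ),
    ).require_converged()

    vox_growth = GrowthSpec(
        basis=growth.basis,
        covariates=growth.covariates,
        categorical=growth.categorical,
        predictor_slot=target,
    )
    vox_spec = build_lgcm(mi_spec, vox_growth, covariate_names)
    path_label = "b_slope_voxel" if target == "slope" else "b_int_voxel"

    warm = {k: v for k, v in base_fit.estimates.items() if k in set(vox_spec.free_params)}
    warm.setdefault(f"mean_{VOXEL_VAR}", 0.0)
    warm[f"var_{VOXEL_VAR}"] = 1.0
    warm[path_label] = 0.0

    if mode == "fixed_measurement":
        free_labels = [l for l in _structural_labels(vox_spec) if l in vox_spec.free_params]
    else:
        free_labels = None

    shape = volumes.shape[:3]
    beta = np.full(shape, np.nan)
    zmap = np.full(shape, np.nan)
    pmap = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)

    var_order = list(vox_spec.var_names)
    vox_col = var_order.index(VOXEL_VAR)
    Y_base = np.column_stack(
        [
            panel.matrix([v])[:, 0] if v != VOXEL_VAR else np.zeros(panel.n)
            for v in var_order
        ]
    )

    idx = np.argwhere(mask)
    n_fail = 0
    for i, j, k in idx:
        x = volumes[i, j, k, :].astype(float)
        sd = x.std()
        if standardize_voxels:
            if sd <= 0:
                n_fail += 1
                continue
            x = (x - x.mean()) / sd
        Y = Y_base.copy()
        Y[:, vox_col] = x
        fit = fit_ml(
            vox_spec,
            Y,
            FitOptions(
                start=warm,
                compute_se=True,
                seed=opts.seed,
                n_restarts=1,
                free_labels=free_labels,
                max_iter=opts.max_iter,
            ),
        )
        if not (fit.converged and fit.se_available and fit.se.get(path_label)):
            n_fail += 1
            continue
        b = fit.estimates[path_label]
        se = fit.se[path_label]
        z = b / se
        beta[i, j, k] = b
        zmap[i, j, k] = z
        pmap[i, j, k] = 2.0 * stats.norm.sf(abs(z))
        conv[i, j, k] = True

    frac_fail = n_fail / max(len(idx), 1)
    if frac_fail > 0.05:
        log.warning("%.1f%% of in-mask voxels failed to converge", 100 * frac_fail)
    return StatMap(
        beta=beta,
        z=zmap,
        p=pmap,
        converged=conv,
        mask=mask.astype(bool),
        affine=affine,
        target=target,
        metadata={
            "mode": mode,
            "target": target,
            "standardize_voxels": standardize_voxels,
            "n_voxels": int(len(idx)),
            "n_nonconverged": int(n_fail),
            "multiple_comparison_correction": "NONE (uncorrected exploratory thresholding)",
        },
    )


def _growth_starts(panel: ItemPanel, spec: ModelSpec) -> Dict[str, float]:
    from .invariance import measurement_starts

    starts = measurement_starts(panel, spec)
    occ1 = float(np.nanmean(panel.matrix(panel.occasion_columns(1))))
    occT = float(np.nanmean(panel.matrix(panel.occasion_columns(panel.n_occasions))))
    starts["int_mean"] = occ1
    starts["slope_mean"] = occT - occ1
    for c in panel.df.columns:
        if f"mean_{c}" in spec.free_params:
            starts[f"mean_{c}"] = float(panel.df[c].mean())
            starts[f"var_{c}"] = float(panel.df[c].var())
    return {k: v for k, v in starts.items() if k in set(spec.free_params)}


def threshold_cluster(
    statmap: StatMap,
    p_thresh: float = 0.001,
    min_extent: int = 50,
    connectivity: str = "faces_edges",
) -> ClusterTable:
    """Cluster-extent thresholding of a voxelwise p-map.

    Binarizes ``p < p_thresh`` within the mask (non-converged voxels are
    excluded from inference), labels connected components under the stated
    connectivity, and keeps components with ``size > min_extent`` (strict).
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    supra = (
        (statmap.p < p_thresh)
        & statmap.mask.astype(bool)
        & statmap.converged.astype(bool)
        & np.isfinite(statmap.p)
    )
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_lab = ndimage.label(supra, structure=structure)
    rows = []
    members: List[np.ndarray] = []
    for lab in range(1, n_lab + 1):
        mem = np.argwhere(labels == lab)
        if len(mem) <= min_extent:
            continue
        zvals = statmap.z[tuple(mem.T)]
        peak_i = int(np.argmax(np.abs(zvals)))
        peak_idx = mem[peak_i]
        mm = voxel_to_world(peak_idx, statmap.affine)
        rows.append(
            {
                "size": int(len(mem)),
                "peak_stat": float(zvals[peak_i]),
                "peak_x_mm": float(mm[0]),
                "peak_y_mm": float(mm[1]),
                "peak_z_mm": float(mm[2]),
            }
        )
        members.append(mem)
    order = np.argsort([-r["size"] for r in rows], kind="stable")
    table = pd.DataFrame(
        [rows[i] for i in order],
        columns=["size", "peak_stat", "peak_x_mm", "peak_y_mm", "peak_z_mm"],
    )
    return ClusterTable(
        table=table,
        members=[members[i] for i in order],
        p_thresh=p_thresh,
        min_extent=min_extent,
        connectivity=connectivity,
    )


# -- NIfTI IO ------------------------------------------------------------------


def load_volumes(paths_or_4d, mask_path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load participant volumes (one 4D file or a list of 3D files) + mask.

    Returns ``(volumes, mask, affine)`` with volumes shaped (x, y, z, n).
    """
    import nibabel as nib

    if isinstance(paths_or_4d, (str, bytes)) or hasattr(paths_or_4d, "__fspath__"):
        img = nib.load(str(paths_or_4d))
        vols = np.asarray(img.dataobj, dtype=float)
        if vols.ndim != 4:
            raise ValueError("single-file input must be 4D")
        affine = img.affine
    else:
        imgs = [nib.load(str(p)) for p in paths_or_4d]
        affine = imgs[0].affine
        for im in imgs[1:]:
            if im.shape != imgs[0].shape or not np.allclose(im.affine, affine):
                raise ValueError("participant volumes disagree in shape or affine")
        vols = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs], axis=-1)
    mimg = nib.load(str(mask_path))
    mask = np.asarray(mimg.dataobj) > 0
    if mask.shape != vols.shape[:3]:
        raise ValueError("mask shape does not match volumes")
    return vols, mask, affine


def save_statmap(statmap: StatMap, prefix) -> List[str]:
    """Write beta / z / -log10(p) NIfTI maps plus JSON metadata."""
    import nibabel as nib

    written = []
    arrays = {
        "beta": statmap.beta,
        "z": statmap.z,
        "neglog10p": -np.log10(statmap.p),
    }
    for name, arr in arrays.items():
        path = f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), statmap.affine), path)
        written.append(path)
    meta_path = f"{prefix}_metadata.json"
    meta = dict(statmap.metadata)
    meta["convergence_rate"] = statmap.convergence_rate()
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    written.append(meta_path)
    return written
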