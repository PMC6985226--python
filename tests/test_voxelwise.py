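"""Voxelwise mapping, cluster-extent thresholding, affine geometry."""

import numpy as np
import pytest

from growthmap.fitting import FitOptions
from growthmap.growth import GrowthSpec, build_lgcm
from growthmap.invariance import build_measurement_spec
from growthmap.simulate import SimConfig, gen_item_panel, gen_volumes
from growthmap.voxelwise import (
    StatMap,
    map_voxel_predictor,
    threshold_cluster,
    voxel_to_world,
    world_to_voxel,
)


# -- affine geometry ----------------------------------------------------------


def test_identity_affine_maps_indices_to_themselves():
    assert np.allclose(voxel_to_world((3, 4, 5), np.eye(4)), (3, 4, 5))


def test_translation_affine_shifts_x():
    aff = np.eye(4)
    aff[0, 3] = 10.0
    assert np.allclose(voxel_to_world((1, 2, 3), aff), (11, 2, 3))


def test_affine_roundtrip_identity():
    rng = np.random.default_rng(0)
    aff = np.eye(4)
    aff[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    aff[:3, 3] = rng.normal(size=3) * 10
    for _ in range(5):
        idx = rng.uniform(-20, 20, 3)
        mm = voxel_to_world(idx, aff)
        back = world_to_voxel(mm, aff)
        assert np.allclose(back, idx, atol=1e-9)


def test_singular_affine_rejected():
    aff = np.zeros((4, 4))
    with pytest.raises(ValueError, match="singular"):
        voxel_to_world((0, 0, 0), aff)


# -- clustering ---------------------------------------------------------------


def _statmap_from_binary(supra, z=None):
    shape = supra.shape
    p = np.where(supra, 1e-6, 1.0)
    return StatMap(
        beta=np.zeros(shape),
        z=z if z is not None else np.where(supra, 5.0, 0.0),
        p=p,
        converged=np.ones(shape, dtype=bool),
        mask=np.ones(shape, dtype=bool),
        affine=np.eye(4),
    )


def test_all_nonsignificant_map_yields_empty_table():
    sm = _statmap_from_binary(np.zeros((8, 8, 8), dtype=bool))
    ct = threshold_cluster(sm, 0.001, 50)
    assert len(ct) == 0


def test_two_blobs_extent_threshold_keeps_only_large_one():
    """60- and 40-voxel blobs with extent 50: exactly the 60-voxel cluster
    survives (verified against a flood fill over the same array)."""
    supra = np.zeros((20, 20, 20), dtype=bool)
    supra[2:5, 2:7, 2:6] = True                      # 3*5*4 = 60 voxels
    supra[10:14, 10:15, 10:12] = True                # 4*5*2 = 40 voxels
    sm = _statmap_from_binary(supra)
    ct = threshold_cluster(sm, 0.001, 50, "faces")
    assert len(ct) == 1
    assert int(ct.table.loc[0, "size"]) == 60
    assert _flood_fill_sizes(supra, 1) == [40, 60]


def _flood_fill_sizes(arr, conn_rank):
    """Independent BFS component labelling; returns sorted sizes."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0 or order > conn_rank:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(arr, dtype=bool)
    sizes = []
    coords = np.argwhere(arr)
    coord_set = {tuple(c) for c in coords}
    for c in map(tuple, coords):
        if seen[c]:
            continue
        stack = [c]
        seen[c] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if nb in coord_set and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        sizes.append(size)
    return sorted(sizes)


@pytest.mark.parametrize("connectivity,rank", [
    ("faces", 1), ("faces_edges", 2), ("faces_edges_corners", 3),
])
def test_labeling_matches_bfs_oracle_on_random_arrays(connectivity, rank):
    rng = np.random.default_rng(7)
    for _ in range(3):
        supra = rng.random((15, 15, 15)) < 0.18
        sm = _statmap_from_binary(supra)
        ct = threshold_cluster(sm, 0.001, 0, connectivity)
        ours = sorted(int(s) for s in ct.table["size"])
        assert ours == _flood_fill_sizes(supra, rank)


def test_labeling_matches_skimage():
    from skimage import measure

    rng = np.random.default_rng(8)
    supra = rng.random((12, 12, 12)) < 0.2
    sm = _statmap_from_binary(supra)
    for conn_ours, conn_sk in [("faces", 1), ("faces_edges", 2), ("faces_edges_corners", 3)]:
        ct = threshold_cluster(sm, 0.001, 0, conn_ours)
        lab = measure.label(supra, connectivity=conn_sk)
        sk_sizes = sorted(np.bincount(lab.ravel())[1:].tolist())
        assert sorted(int(s) for s in ct.table["size"]) == sk_sizes


def test_peak_reported_in_world_mm():
    supra = np.zeros((10, 10, 10), dtype=bool)
    supra[4:7, 4:7, 4:7] = True
    z = np.where(supra, 4.0, 0.0)
    z[5, 6, 4] = -9.0  # extreme magnitude, negative sign retained
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = (-9.0, -9.0, -9.0)
    sm = _statmap_from_binary(supra, z=z)
    sm.affine = aff
    ct = threshold_cluster(sm, 0.001, 5, "faces")
    assert len(ct) == 1
    row = ct.table.iloc[0]
    assert row["peak_stat"] == -9.0
    assert (row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"]) == (1.0, 3.0, -1.0)


# -- voxelwise mapping --------------------------------------------------------


@pytest.fixture(scope="module")
def voxel_setup():
    cfg = SimConfig(
        n_per_occasion=(200, 160, 140), n_intermittent=10, drift_items=(),
        n_sites=1, seed=611, grid_shape=(12, 12, 12), effect_center=(6, 6, 6),
        effect_radius=3.0,
    )
    panel, truth = gen_item_panel(cfg)
    slopes = np.asarray(truth["latent_slope"])
    vols, mask, affine, vtruth = gen_volumes(cfg, slopes)
    mi = build_measurement_spec(12, 3, "strong")
    gs = GrowthSpec()
    base = build_lgcm(mi, gs, [])
    return cfg, panel, vols, mask, affine, vtruth, mi, gs, base


def test_participant_mismatch_is_hard_error(voxel_setup):
    cfg, panel, vols, mask, affine, vtruth, mi, gs, base = voxel_setup
    with pytest.raises(ValueError, match="IDs must align"):
        map_voxel_predictor(panel, vols[..., :-5], mask, base, gs, [], mi_spec=mi)


def test_out_of_mask_voxels_missing_coded(voxel_setup):
    cfg, panel, vols, mask, affine, vtruth, mi, gs, base = voxel_setup
    sub = np.zeros_like(mask)
    sub[6, 6, 5:8] = True
    sm = map_voxel_predictor(panel, vols, sub, base, gs, [], mi_spec=mi, affine=affine)
    assert np.isnan(sm.z[~sub]).all()
    assert np.isfinite(sm.z[sub]).all()
    assert ((sm.p[sub] >= 0) & (sm.p[sub] <= 1)).all()


def test_planted_effect_detected_and_modes_agree(voxel_setup):
    """Peak lies in the effect sphere; full_refit and fixed_measurement agree
    in beta sign and in z within 10% on the well-separated planted effect."""
    cfg, panel, vols, mask, affine, vtruth, mi, gs, base = voxel_setup
    sub = np.zeros_like(mask)
    sub[5:8, 5:8, 6] = True          # 9 voxels straddling the region
    sub[1:3, 1:3, 1] |= mask[1:3, 1:3, 1]
    fixed = map_voxel_predictor(
        panel, vols, sub, base, gs, [], target="slope",
        mode="fixed_measurement", mi_spec=mi, affine=affine,
    )
    full = map_voxel_predictor(
        panel, vols, sub, base, gs, [], target="slope",
        mode="full_refit", mi_spec=mi, affine=affine,
    )
    in_region = sub & vtruth["region"]
    assert np.nanmean(fixed.z[in_region]) > 2.0
    peak = np.unravel_index(np.nanargmax(np.abs(np.where(sub, fixed.z, 0))), sub.shape)
    assert vtruth["region"][peak]
    strong = in_region & (np.abs(full.z) > 2.5)
    assert strong.any()
    assert np.sign(fixed.beta[strong]).tolist() == np.sign(full.beta[strong]).tolist()
    rel = np.abs(fixed.z[strong] - full.z[strong]) / np.abs(full.z[strong])
    assert np.nanmax(rel) < 0.10


def test_voxelwise_independence(voxel_setup):
    """Perturbing one voxel's data changes only that voxel's outputs."""
    cfg, panel, vols, mask, affine, vtruth, mi, gs, base = voxel_setup
    sub = np.zeros_like(mask)
    sub[6, 6, 4:8] = True
    sm1 = map_voxel_predictor(panel, vols, sub, base, gs, [], mi_spec=mi)
    vols2 = vols.copy()
    vols2[6, 6, 5, :] = np.random.default_rng(3).normal(size=vols.shape[-1])
    sm2 = map_voxel_predictor(panel, vols2, sub, base, gs, [], mi_spec=mi)
    changed = sub.copy()
    changed[6, 6, 5] = False
    assert np.allclose(sm1.z[changed], sm2.z[changed], equal_nan=True)
    assert not np.isclose(sm1.z[6, 6, 5], sm2.z[6, 6, 5])


def test_metadata_declares_uncorrected_inference(voxel_setup):
    cfg, panel, vols, mask, affine, vtruth, mi, gs, base = voxel_setup
    sub = np.zeros_like(mask)
    sub[6, 6, 6] = True
    sm = map_voxel_predictor(panel, vols, sub, base, gs, [], mi_spec=mi)
    assert "correction" in " ".join(sm.metadata).lower() or any(
        "correction" in k for k in sm.metadata
    )
    assert "NONE" in sm.metadata["multiple_comparison_correction"]
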