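"""Feature extraction vs independent pixel-enumeration oracles, plus the
spec'd trivial identities and invariances."""

import math

import numpy as np
import pytest

import oracles
from stiffmorph import profiling
from stiffmorph.catalog import CONTEXT_DENSITY_RADII_UM, ZERNIKE_ORDERS
from conftest import make_disk


def close(a, b, tol=1e-9):
    if isinstance(a, float) and math.isnan(a):
        return isinstance(b, float) and math.isnan(b)
    return math.isclose(a, b, rel_tol=tol, abs_tol=tol)


def _toy_library():
    rng = np.random.default_rng(5)
    disk = make_disk(8)
    rect = np.zeros((14, 24), bool)
    rect[2:12, 2:22] = True
    blob = np.zeros((25, 25), bool)
    rr, cc = np.mgrid[0:25, 0:25]
    blob |= ((rr - 12.0) ** 2 / 64 + (cc - 12.0) ** 2 / 36) <= 1.0
    blob[3:9, 14:23] = True
    blob[16:23, 3:8] = True
    rand = rng.random((21, 21)) > 0.45
    # keep the largest connected component so the object is contiguous
    from scipy import ndimage

    lab, n = ndimage.label(rand)
    sizes = ndimage.sum(rand, lab, range(1, n + 1))
    rand = lab == (1 + int(np.argmax(sizes)))
    return [disk, rect, blob, rand]


@pytest.mark.parametrize("idx", range(4))
def test_shape_features_match_pixel_enumeration_oracle(idx):
    mask = _toy_library()[idx]
    px = 0.5
    ours = profiling.shape_features(mask, px)
    ref = oracles.shape_oracle(mask, px)
    for k, v in ref.items():
        assert close(ours[k], v), f"{k}: {ours[k]} != {v}"


@pytest.mark.parametrize("idx", range(3))
def test_zernike_magnitudes_match_oracle(idx):
    mask = _toy_library()[idx]
    ours = profiling.zernike_magnitudes(mask)
    ref = oracles.zernike_oracle(mask, ZERNIKE_ORDERS)
    for k, v in ref.items():
        assert close(ours[k], v), k


@pytest.mark.parametrize("idx", range(3))
def test_intensity_radial_features_match_oracle(idx):
    mask = _toy_library()[idx]
    rng = np.random.default_rng(idx)
    channel = rng.integers(10, 4000, size=mask.shape).astype(float)
    px = 0.5
    ours = profiling.intensity_features(mask, channel, px)
    ref = oracles.intensity_oracle(mask, channel, px)
    for k, v in ref.items():
        assert close(ours[k], v), f"{k}: {ours[k]} != {v}"
    ours_r = profiling.radial_distribution(mask, channel)
    ref_r = oracles.radial_oracle(mask, channel)
    for k, v in ref_r.items():
        assert close(ours_r[k], v), k


@pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (1, -1), (0, 3), (3, -3)])
def test_glcm_and_haralick_match_oracle(offset):
    mask = _toy_library()[2]
    rng = np.random.default_rng(3)
    channel = rng.integers(0, 900, size=mask.shape).astype(float)
    levels = np.zeros(mask.shape, dtype=np.intp)
    vals = channel[mask]
    levels[mask] = np.minimum(
        ((vals - vals.min()) / (vals.max() - vals.min()) * 64).astype(int), 63
    )
    ours_glcm = profiling._masked_glcm(levels, mask, offset, 64)
    ref_glcm = oracles.glcm_oracle(mask, channel, offset)
    np.testing.assert_allclose(ours_glcm, ref_glcm, atol=1e-12)
    ours = profiling._haralick_stats(ours_glcm)
    ref = oracles.haralick_oracle(ref_glcm)
    for k, v in ref.items():
        assert close(ours[k], v), f"{k}: {ours[k]} != {v}"


def test_context_features_match_oracle():
    labels = np.zeros((30, 30), dtype=np.int32)
    labels[2:10, 2:10] = 1
    labels[2:10, 10:16] = 2  # touches cell 1
    labels[20:27, 18:27] = 3  # isolated
    for target in (1, 2, 3):
        ours = profiling.context_features(labels, target, 0.5)
        ref = oracles.context_oracle(labels, target, 0.5, CONTEXT_DENSITY_RADII_UM)
        for k, v in ref.items():
            assert close(ours[k], v), f"cell {target} {k}: {ours[k]} != {v}"
    assert profiling.context_features(labels, 3, 0.5)["ctx_neighbor_count"] == 0
    assert profiling.context_features(labels, 1, 0.5)["ctx_neighbor_count"] == 1


def test_single_cell_scene_context_sentinels():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[5:12, 5:12] = 1
    ctx = profiling.context_features(labels, 1, 1.0)
    assert ctx["ctx_neighbor_count"] == 0
    assert math.isnan(ctx["ctx_nn1_dist"])


# --- trivial identities -----------------------------------------------------

def test_disk_circularity_near_one_and_identity():
    disk = make_disk(50)
    f = profiling.shape_features(disk, 1.0)
    assert 0.95 <= f["circularity"] <= 1.05
    assert math.isclose(f["circularity"] * f["compactness"], 1.0, rel_tol=1e-12)
    assert math.isclose(f["solidity"], 1.0, abs_tol=0.05)


def test_rectangle_eccentricity_and_solidity():
    rect = np.zeros((104, 14), bool)
    rect[2:102, 2:12] = True
    f = profiling.shape_features(rect, 1.0)
    assert abs(f["eccentricity"] - 0.995) < 0.003
    assert math.isclose(f["solidity"], 1.0, rel_tol=1e-12)


def test_ncr_and_polarity_examples():
    assert profiling.ncr(50.0, 100.0) == 0.5
    assert profiling.ncr(70.0, 70.0) == 1.0
    with pytest.raises(profiling.InvalidObjectError):
        profiling.ncr(50.0, 0.0)
    assert profiling.polarity(np.zeros(2), np.zeros(2)) == 0.0
    assert math.isclose(profiling.polarity((0, 0), (3, 4), 0.25), 1.25)


def test_polarity_bounded_by_max_radius(toy_cell):
    cell, nucleus, _ = toy_cell
    f = profiling.shape_features(cell, 1.0)
    cc = profiling._pixel_coords(cell).mean(axis=0)
    nc = profiling._pixel_coords(nucleus).mean(axis=0)
    assert profiling.polarity(cc, nc, 1.0) <= f["radius_max"]


def test_edge_fraction_extremes_and_uniform_disk():
    disk = make_disk(10)
    b = profiling.boundary_mask(disk)
    edge_only = np.where(b, 7.0, 0.0)
    assert profiling.edge_fraction(disk, edge_only) == 100.0
    interior_only = np.where(disk & ~b, 3.0, 0.0)
    assert profiling.edge_fraction(disk, interior_only) == 0.0
    uniform = np.ones(disk.shape)
    expect = 100.0 * b.sum() / disk.sum()
    assert math.isclose(profiling.edge_fraction(disk, uniform), expect)
    with pytest.warns(UserWarning):
        assert math.isnan(profiling.edge_fraction(disk, np.zeros(disk.shape)))


def test_mean_intensity_times_area_is_integrated(toy_cell):
    cell, _, channel = toy_cell
    f = profiling.intensity_features(cell, channel, 0.7)
    area_um2 = cell.sum() * 0.7**2
    assert math.isclose(f["mean"] * area_um2, f["integrated"], rel_tol=1e-12)


def test_uniform_intensity_edge_equals_interior_mean(toy_cell):
    cell, _, _ = toy_cell
    f = profiling.intensity_features(cell, np.full(cell.shape, 5.0), 1.0)
    assert math.isclose(f["edge_mean_px"], f["mean"] * 1.0)  # both 5.0 per px
    assert math.isclose(f["edge_interior_ratio"], 1.0)


def test_radial_fractions_sum_to_one(toy_cell):
    cell, _, channel = toy_cell
    r = profiling.radial_distribution(cell, channel)
    assert math.isclose(sum(r[f"radial_frac_b{b}"] for b in range(1, 6)), 1.0)
    # all intensity at the centroid pixel -> innermost bin gets everything
    coords = profiling._pixel_coords(cell)
    cr, cc = coords.mean(axis=0).round().astype(int)
    point = np.zeros(cell.shape)
    point[cr, cc] = 9.0
    r2 = profiling.radial_distribution(cell, point)
    assert math.isclose(r2["radial_frac_b1"], 1.0)


def test_texture_constant_patch_degenerate():
    patch = make_disk(6)
    f = profiling.texture_features(patch, np.full(patch.shape, 3.0))
    assert f["txt_asm_d1"] == 1.0
    assert f["txt_contrast_d1"] == 0.0
    assert f["txt_correlation_d1"] == 0.0


def test_checkerboard_contrast_matches_hand_enumeration():
    mask = np.ones((8, 8), bool)
    rr, cc = np.mgrid[0:8, 0:8]
    channel = ((rr + cc) % 2).astype(float)
    ref = oracles.haralick_oracle(oracles.glcm_oracle(mask, channel, (0, 1)))
    glcm = profiling._masked_glcm(
        np.where(channel > 0, 63, 0).astype(np.intp), mask, (0, 1), 64
    )
    ours = profiling._haralick_stats(glcm)
    assert math.isclose(ours["contrast"], ref["contrast"], rel_tol=1e-12)
    # horizontal neighbours always differ on a checkerboard
    assert math.isclose(ours["contrast"], 63.0**2)


def test_texture_rotation_invariance_under_90deg():
    mask = _toy_library()[2]
    rng = np.random.default_rng(9)
    channel = rng.random(mask.shape)
    a = profiling.texture_features(mask, channel)
    b = profiling.texture_features(np.rot90(mask), np.rot90(channel))
    for k in a:
        assert math.isclose(a[k], b[k], rel_tol=1e-9, abs_tol=1e-9), k


def test_cross_channel_features_examples(toy_cell):
    cell, _, channel = toy_cell
    f = profiling.cross_channel_features(cell, channel, channel, 1.0)
    assert math.isclose(f["cvr"], 1.0)
    assert math.isclose(f["ck_vim_corr"], 1.0)
    f2 = profiling.cross_channel_features(
        cell, np.full(cell.shape, 6.0), np.full(cell.shape, 3.0), 1.0
    )
    assert math.isclose(f2["cvr"], 2.0)


def test_shape_features_translation_and_rotation_invariance():
    blob = _toy_library()[2]
    base = profiling.shape_features(blob, 1.0)
    shifted = np.zeros((40, 40), bool)
    shifted[9 : 9 + blob.shape[0], 5 : 5 + blob.shape[1]] = blob
    trans = profiling.shape_features(shifted, 1.0)
    for k in base:
        assert close(base[k], trans[k]), k
    rot = profiling.shape_features(np.rot90(blob), 1.0)
    # orientation and the bbox sides are frame-dependent; everything else is
    # invariant under exact 90-degree rotation
    skip = {"orientation", "bbox_height", "bbox_width"}
    for k in set(base) - skip:
        assert math.isclose(base[k], rot[k], rel_tol=1e-9, abs_tol=1e-9), k


def test_small_object_rejected():
    tiny = np.zeros((5, 5), bool)
    tiny[2, 2:4] = True
    with pytest.raises(profiling.InvalidObjectError):
        profiling.shape_features(tiny, 1.0)


def test_profile_cell_row_has_exact_catalogue_shape(toy_cell):
    cell, nucleus, channel = toy_cell
    feats = profiling.profile_cell(
        cell, nucleus, 1.0, {"ecad": channel}, ("ecad",)
    )
    from stiffmorph.catalog import morphology_feature_names, staining_feature_names

    expected = set(morphology_feature_names()) - {
        n for n in morphology_feature_names() if n.startswith("ctx_")
    }
    expected |= set(staining_feature_names("ECAD"))
    assert set(feats) == expected


def test_assemble_table_empty_and_mismatch(toy_cell):
    import pandas as pd

    t = profiling.assemble_table([], [], "ECAD")
    assert len(t) == 0 and len(t.columns) == 5 + 150 + 69
    with pytest.raises(AssertionError):
        profiling.assemble_table([{"bogus": 1.0}], [{}], "ECAD")
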