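import math

import numpy as np
import pytest
from scipy import ndimage

from conftest import make_disk
from stiffmorph import segmentation
from stiffmorph.synthetic import SceneSpec, generate_scene


def test_smooth_conserves_intensity_and_units():
    rng = np.random.default_rng(0)
    img = rng.random((64, 64)) * 1000
    out = segmentation.smooth(img, sigma_um=0.25, pixel_size_um=0.25)  # sigma = 1 px
    assert out.shape == img.shape
    assert abs(out.sum() - img.sum()) / img.sum() < 1e-3
    const = segmentation.smooth(np.full((32, 32), 7.0), 0.5, 0.25)
    np.testing.assert_allclose(const, 7.0)
    with pytest.raises(ValueError):
        segmentation.smooth(img, -1.0, 0.25)


def test_smooth_single_pixel_matches_direct_convolution():
    img = np.zeros((41, 41))
    img[20, 20] = 1.0
    out = segmentation.smooth(img, sigma_um=1.0, pixel_size_um=1.0)
    # direct truncated discrete Gaussian (scipy truncates at 4 sigma)
    ax = np.arange(-4, 5)
    k = np.exp(-(ax**2) / 2.0)
    k /= k.sum()
    expect = np.outer(k, k)
    np.testing.assert_allclose(out[16:25, 16:25], expect, atol=1e-12)


def test_threshold_recovers_bimodal_plateau_vs_exhaustive_otsu():
    img = np.full((40, 40), 10.0)
    img[10:30, 10:30] = 200.0
    mask = segmentation.threshold_objects(img, pixel_size_um=1.0)
    np.testing.assert_array_equal(mask, img > 100)
    # exhaustive between-class-variance search agrees with the split
    vals = img.ravel().astype(int)
    best_t, best_v = None, -1
    for t in range(int(vals.min()), int(vals.max())):
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        v = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    assert (img > best_t).sum() == mask.sum()


def test_threshold_empty_on_flat_image():
    with pytest.warns(UserWarning):
        mask = segmentation.threshold_objects(np.zeros((16, 16)), 1.0)
    assert not mask.any()


def test_threshold_fills_holes_and_removes_specks():
    img = np.full((60, 60), 5.0)
    img[10:40, 10:40] = 200.0
    img[20:23, 20:23] = 5.0  # hole -> filled
    img[50:52, 50:52] = 200.0  # 4 px speck < 20 um^2 -> removed
    mask = segmentation.threshold_objects(img, pixel_size_um=1.0)
    assert mask[21, 21]
    assert not mask[50:52, 50:52].any()


def _two_cells_scene():
    cell = np.zeros((60, 60), bool)
    cell[5:25, 5:25] = True
    cell[35:55, 30:55] = True
    nuc = np.zeros((60, 60), bool)
    nuc[12:18, 12:18] = True
    nuc[42:48, 40:46] = True
    return cell, nuc


def test_label_and_pair_basic():
    cell, nuc = _two_cells_scene()
    res = segmentation.label_and_pair(cell, nuc)
    assert len(res.pairing) == 2
    assert res.retained == {1, 2}
    for cid, nid in res.pairing.items():
        assert ((res.nucleus_labels == cid) & ~(res.cell_labels == cid)).sum() == 0


def test_nucleus_over_background_is_unassigned():
    cell, nuc = _two_cells_scene()
    nuc[28:31, 28:31] = True  # centroid over background
    res = segmentation.label_and_pair(cell, nuc)
    assert len(res.pairing) == 2  # stray nucleus ignored
    assert res.retained == {1, 2}


def test_cell_without_nucleus_excluded_but_context():
    cell, nuc = _two_cells_scene()
    nuc[42:48, 40:46] = False
    res = segmentation.label_and_pair(cell, nuc)
    assert len(res.retained) == 1
    assert len(res.context_set) == 2
    assert "no_nucleus" in res.exclusion_reason.values()


def test_multi_nucleus_component_split_by_watershed():
    cell = np.zeros((40, 80), bool)
    cell[10:30, 10:70] = True  # one merged component
    nuc = np.zeros((40, 80), bool)
    nuc[17:23, 20:26] = True
    nuc[17:23, 54:60] = True
    res = segmentation.label_and_pair(cell, nuc)
    assert len(res.pairing) == 2
    # labels partition the foreground
    assert ((res.cell_labels > 0) == cell).all()


def test_border_cell_excluded_but_in_context():
    cell = np.zeros((50, 50), bool)
    cell[0:12, 20:32] = True  # touches border
    cell[25:40, 20:35] = True
    nuc = np.zeros((50, 50), bool)
    nuc[4:8, 24:28] = True
    nuc[30:35, 25:30] = True
    res = segmentation.label_and_pair(cell, nuc)
    res = segmentation.apply_retention_rules(res, cell.shape)
    assert len(res.retained) == 1
    assert len(res.context_set) == 2
    assert "border" in res.exclusion_reason.values()


def test_retention_is_idempotent():
    cell, nuc = _two_cells_scene()
    res = segmentation.label_and_pair(cell, nuc)
    res = segmentation.apply_retention_rules(res, cell.shape)
    res = segmentation.flag_clumped(res)
    snapshot = (set(res.retained), set(res.clumped), dict(res.exclusion_reason))
    res = segmentation.apply_retention_rules(res, cell.shape)
    res = segmentation.flag_clumped(res)
    assert snapshot == (set(res.retained), set(res.clumped), dict(res.exclusion_reason))


def _touching_row(n, w=12):
    """n abutting square cells in a row, each with a nucleus."""
    cell = np.zeros((30, 10 + n * w), bool)
    nuc = np.zeros_like(cell)
    for i in range(n):
        c0 = 5 + i * w
        cell[8 : 8 + w, c0 : c0 + w] = True
        nuc[12:16, c0 + 4 : c0 + 8] = True
    return cell, nuc


def test_touching_group_of_5_flagged_clumped():
    cell, nuc = _touching_row(5)
    res = segmentation.label_and_pair(cell, nuc)
    res = segmentation.apply_retention_rules(res, cell.shape)
    res = segmentation.flag_clumped(res)
    assert len(res.clumped) == 5
    assert len(res.retained) == 0


def test_touching_pair_is_overlap_not_clump():
    cell, nuc = _touching_row(2)
    res = segmentation.label_and_pair(cell, nuc)
    res = segmentation.apply_retention_rules(res, cell.shape)
    res = segmentation.flag_clumped(res)
    assert len(res.clumped) == 0
    assert len(res.retained) == 0
    assert list(res.exclusion_reason.values()).count("overlap") == 2


def test_synthetic_scene_segmentation_fidelity():
    """On one synthetic scene: union-mask IoU >= 95%, pairing recall >= 95%,
    per-cell areas within 5% of ground truth."""
    spec = SceneSpec(
        stiffness_kpa=16.0,
        staining_group="ECAD",
        n_cells=8,
        morph_mixture=(0.25, 0.25, 0.5),
        pixel_size_um=1.0,
        image_shape=(256, 256),
        seed=7,
    )
    image, gt, *_ = generate_scene(spec)
    res = segmentation.segment_scene(image.channels, 1.0)
    seg_union = res.cell_labels > 0
    gt_union = gt.cell_labels > 0
    iou = (seg_union & gt_union).sum() / (seg_union | gt_union).sum()
    assert iou >= 0.95

    matched = 0
    for cid in res.retained:
        mask = res.cell_labels == cid
        overlap = gt.cell_labels[mask]
        overlap = overlap[overlap != 0]
        if len(overlap) == 0:
            continue
        gt_lab = np.bincount(overlap).argmax()
        gt_area = (gt.cell_labels == gt_lab).sum()
        if abs(mask.sum() - gt_area) / gt_area < 0.05:
            matched += 1
    assert matched / len(gt.table) >= 0.95


def test_labels_partition_thresholded_foreground():
    cell, nuc = _two_cells_scene()
    res = segmentation.label_and_pair(cell, nuc)
    assert ((res.cell_labels > 0) == cell).all()
    ids = set(np.unique(res.cell_labels)) - {0}
    assert ids == res.context_set
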