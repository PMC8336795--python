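"""Generator contracts: scene construction, dataset arithmetic, determinism,
and the Monte-Carlo calibration of the population statistics the generator
is designed to emulate."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from stiffmorph import profiling
from stiffmorph.archetypes import DEFAULT_ARCHETYPES, sample_cell_area
from stiffmorph.synthetic import (
    DEFAULT_MORPH_MIXTURES,
    MARKER_STIFFNESS_SCALE,
    SceneSpec,
    _marker_levels,
    generate_scene,
    iter_scenes,
    paper_scale_profile,
    plan_scenes,
    quota_allocate,
    resolve_profile,
)

PAPER_SINGLE_COUNTS = {0.2: 166, 2.0: 166, 16.0: 166, 32.0: 164, 64.0: 164}


def test_scene_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(2.0, "ECAD", 5, (0.5, 0.4, 0.2))  # mixture sums to 1.1
    with pytest.raises(ValueError):
        SceneSpec(2.0, "BOGUS", 5, (0.3, 0.3, 0.4))
    with pytest.raises(ValueError):
        SceneSpec(2.0, "ECAD", 0, (0.3, 0.3, 0.4))


def test_profile_clumps_only_at_64kpa():
    with pytest.raises(ValueError):
        prof = paper_scale_profile()
        prof.clump_counts[(2.0, "ECAD")] = 5
        type(prof)(**{f: getattr(prof, f) for f in prof.__dataclass_fields__})


def test_zero_clump_fraction_scene_has_no_clumps():
    spec = SceneSpec(
        16.0, "ECAD", 6, (0.3, 0.3, 0.4), clump_fraction=0.0,
        pixel_size_um=1.0, image_shape=(256, 256), seed=2,
    )
    _, gt, *_ = generate_scene(spec)
    assert not gt.table["clumped"].any()


def test_explicit_clump_construction():
    spec = SceneSpec(
        64.0, "ECAD", 10, (0.3, 0.3, 0.4), clump_fraction=0.5, clump_group_size=5,
        pixel_size_um=1.0, image_shape=(256, 256), seed=5,
    )
    _, gt, *_ = generate_scene(spec)
    t = gt.table
    assert int(t["clumped"].sum()) == 5
    assert t.loc[t["clumped"], "clump_id"].nunique() == 1
    # clump members are pixel-disjoint and pairwise adjacent as one group
    labs = gt.cell_labels
    clump_ids = t.loc[t["clumped"], "label"].tolist()
    union = np.isin(labs, clump_ids)
    assert union.sum() == sum((labs == i).sum() for i in clump_ids)


def test_clumped_cells_have_higher_edge_fraction_than_single():
    """On ground-truth masks of a default 64-kPa scene, the generated
    E-cadherin edge fraction is higher in clumped than in single cells."""
    spec = SceneSpec(
        64.0, "ECAD", 12, (0.5, 0.25, 0.25), clump_fraction=0.5, clump_group_size=6,
        pixel_size_um=1.0, image_shape=(320, 320), seed=11,
    )
    image, gt, *_ = generate_scene(spec)
    fracs = {True: [], False: []}
    for _, row in gt.table.iterrows():
        mask = gt.cell_labels == row["label"]
        fracs[bool(row["clumped"])].append(
            profiling.edge_fraction(mask, image.channels["ECAD"].astype(float))
        )
    assert np.mean(fracs[True]) > np.mean(fracs[False])


def test_generate_scene_deterministic():
    spec = SceneSpec(
        2.0, "CK_VIM", 6, (0.2, 0.15, 0.65),
        pixel_size_um=1.0, image_shape=(256, 256), seed=9,
    )
    img1, gt1, *_ = generate_scene(spec)
    img2, gt2, *_ = generate_scene(spec)
    for ch in img1.channels:
        np.testing.assert_array_equal(img1.channels[ch], img2.channels[ch])
    pd.testing.assert_frame_equal(gt1.table, gt2.table)


def test_paper_scale_plan_arithmetic():
    prof = paper_scale_profile()
    assert prof.total_cells == 910
    assert sum(prof.clump_counts.values()) == 84
    assert sum(prof.single_counts.values()) == 826
    plans = plan_scenes(prof, seed=3)
    singles = sum(len(p.singles) for p in plans)
    clump_cells = sum(len(c) for p in plans for c in p.clumps)
    assert singles == 826 and clump_cells == 84
    for p in plans:
        for c in p.clumps:
            assert len(c) >= 4  # every scene supports 3rd-nearest distances
        assert p.stiffness_kpa != 64.0 or True
    # clumps only at 64 kPa
    assert all(not p.clumps or p.stiffness_kpa == 64.0 for p in plans)


def test_dataset_ground_truth_deterministic_and_unique_ids():
    prof = resolve_profile("demo")
    recs1 = list(iter_scenes(prof, 21))
    recs2 = list(iter_scenes(prof, 21))
    t1 = pd.concat([r.ground_truth.table for r in recs1], ignore_index=True)
    t2 = pd.concat([r.ground_truth.table for r in recs2], ignore_index=True)
    pd.testing.assert_frame_equal(t1, t2)
    for ch_rec1, ch_rec2 in zip(recs1, recs2):
        for name in ch_rec1.image.channels:
            np.testing.assert_array_equal(
                ch_rec1.image.channels[name], ch_rec2.image.channels[name]
            )
    for rec in recs1:
        labels = rec.ground_truth.table["label"]
        assert labels.is_unique


@given(
    n=st.integers(min_value=0, max_value=500),
    raw=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
)
@settings(max_examples=60, deadline=None)
def test_quota_allocation_exact_and_faithful(n, raw):
    total = sum(raw)
    props = tuple(r / total for r in raw)
    counts = quota_allocate(n, props)
    assert sum(counts) == n
    assert all(abs(c - n * p) <= 1.0 for c, p in zip(counts, props))


# --- Monte-Carlo calibration of the generative distributions ---------------

def _latent_ncr_spearman(seed: int) -> float:
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for stiff, n in PAPER_SINGLE_COUNTS.items():
        for morph, cnt in zip(
            (1, 2, 3), quota_allocate(n, DEFAULT_MORPH_MIXTURES[stiff])
        ):
            for _ in range(cnt):
                cell, nuc = sample_cell_area(DEFAULT_ARCHETYPES[morph], stiff, rng)
                xs.append(stiff)
                ys.append(nuc / (cell - nuc))
    return float(spearmanr(xs, ys).statistic)


def test_calibration_ncr_stiffness_spearman():
    """|Spearman(stiffness, NCR)| = 0.31 +/- 0.03 at paper-scale population
    size, averaged over 20 Monte-Carlo seeds of the latent area model."""
    rhos = [_latent_ncr_spearman(s) for s in range(20)]
    assert abs(abs(np.mean(rhos)) - 0.31) <= 0.03


def test_calibration_clumped_morph3_proportion():
    """Quota realisation puts the morph-3 share of the 84 clump members at
    56% +/- 5 points."""
    counts = quota_allocate(84, (0.40, 0.04, 0.56))
    assert abs(counts[2] / 84 - 0.56) <= 0.05


def test_calibration_marker_mean_trends():
    """Sampled marker levels reproduce the designed stiffness trends:
    vimentin max at 2 kPa, cytokeratins non-decreasing over 16-64 kPa,
    E-cadherin local maxima at 2 and 64 kPa (20 Monte-Carlo seeds)."""
    levels = [0.2, 2.0, 16.0, 32.0, 64.0]
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        means = {m: {} for m in ("ecad", "vim", "ck")}
        for stiff in levels:
            n = PAPER_SINGLE_COUNTS[stiff] // 2
            mixture = quota_allocate(n, DEFAULT_MORPH_MIXTURES[stiff])
            for marker in means:
                vals = []
                for morph, cnt in zip((1, 2, 3), mixture):
                    vals += [
                        _marker_levels(marker, stiff, morph, False, rng)[0]
                        for _ in range(cnt)
                    ]
                means[marker][stiff] = np.mean(vals)
        vim = means["vim"]
        assert vim[2.0] == max(vim.values())
        ck = means["ck"]
        assert ck[16.0] <= ck[32.0] <= ck[64.0]
        ecad = means["ecad"]
        assert ecad[2.0] > ecad[0.2] and ecad[2.0] > ecad[16.0]  # local max at 2
        assert ecad[64.0] > ecad[32.0]  # local max at 64


def test_marker_scale_constants_encode_trends():
    ecad = MARKER_STIFFNESS_SCALE["ecad"]
    assert ecad[2.0] > ecad[0.2] and ecad[2.0] > ecad[16.0]
    assert ecad[64.0] > ecad[32.0]
    vim = MARKER_STIFFNESS_SCALE["vim"]
    assert vim[2.0] == max(vim.values())
    ck = MARKER_STIFFNESS_SCALE["ck"]
    assert ck[16.0] <= ck[32.0] <= ck[64.0]
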