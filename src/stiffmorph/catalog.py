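"""Feature catalogue: the fixed, version-stamped set of per-cell measurements.

The morphology + context block holds exactly 150 features:

* 35 scalar shape descriptors for each of the three objects
  (cell, nucleus, cytoplasm = cell minus nucleus) -> 105,
* a 25-term Zernike-magnitude block (degree <= 8) for the cell outline,
* 5 engineered features (NCR, polarity, nucleus/cell area ratio,
  cytoplasm area fraction, perimeter/area ratio),
* 15 contextual features computed against every cell in the scene
  (including border/excluded cells).

Each marker channel contributes exactly 69 features (17 intensity + 9 edge +
2 mass displacement + 15 radial + 26 texture); the two-marker staining group
adds 2 cross-channel features (CVR and the per-cell CK-vimentin pixel
correlation) for a total of 140.  No feature encodes absolute image
coordinates, and all geometric quantities are reported in physical units
(um, um^2) or dimensionless.
"""

from __future__ import annotations

CATALOG_VERSION = "1.0"

#: 35 scalar shape descriptors, computed per object.
SHAPE_DESCRIPTORS: tuple[str, ...] = (
    "area",
    "perimeter",
    "circularity",
    "compactness",
    "roundness",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "equivalent_diameter",
    "feret_max",
    "feret_min",
    "feret_ratio",
    "orientation",
    "radius_mean",
    "radius_median",
    "radius_max",
    "radius_min",
    "radius_sd",
    "radius_cv",
    "convex_area",
    "convex_perimeter",
    "convexity",
    "bbox_height",
    "bbox_width",
    "bbox_aspect",
    "hu1",
    "hu2",
    "hu3",
    "hu4",
    "hu5",
    "hu6",
    "hu7",
)

OBJECTS: tuple[str, ...] = ("cell", "nucleus", "cyto")

#: (n, m) orders of the Zernike magnitude block: all n <= 8, m >= 0, n-m even.
ZERNIKE_ORDERS: tuple[tuple[int, int], ...] = tuple(
    (n, m) for n in range(9) for m in range(n % 2, n + 1, 2)
)

ENGINEERED_FEATURES: tuple[str, ...] = (
    "ncr",
    "polarity",
    "nucleus_cell_area_ratio",
    "cytoplasm_area_fraction",
    "cell_perimeter_area_ratio",
)

CONTEXT_FEATURES: tuple[str, ...] = (
    "ctx_neighbor_count",
    "ctx_shared_boundary_pct",
    "ctx_shared_boundary_um",
    "ctx_nn1_dist",
    "ctx_nn2_dist",
    "ctx_nn3_dist",
    "ctx_nn_mean3",
    "ctx_density_r25",
    "ctx_density_r50",
    "ctx_density_r75",
    "ctx_density_r100",
    "ctx_density_r150",
    "ctx_density_r200",
    "ctx_inv_dist_sum",
    "ctx_nn1_area_ratio",
)

#: Radii (um) of the local-density context counts.
CONTEXT_DENSITY_RADII_UM: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0)

INTENSITY_FEATURES: tuple[str, ...] = (
    "integrated",
    "mean",
    "std",
    "cv",
    "min",
    "p10",
    "q1",
    "median",
    "q3",
    "p90",
    "max",
    "iqr",
    "range",
    "mad",
    "skewness",
    "kurtosis",
    "top10_mass_frac",
)

EDGE_FEATURES: tuple[str, ...] = (
    "edge_integrated",
    "edge_mean_px",
    "mean_edge_intensity",
    "edge_std",
    "edge_min",
    "edge_max",
    "edge_median",
    "edge_fraction",
    "edge_interior_ratio",
)

MASS_FEATURES: tuple[str, ...] = ("mass_displacement_um", "mass_displacement_norm")

N_RADIAL_BINS = 5
RADIAL_FEATURES: tuple[str, ...] = tuple(
    f"radial_{stat}_b{b + 1}"
    for stat in ("frac", "meanfrac", "cv")
    for b in range(N_RADIAL_BINS)
)

HARALICK_STATS: tuple[str, ...] = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_avg",
    "sum_var",
    "sum_entropy",
    "entropy",
    "diff_var",
    "diff_entropy",
    "imc1",
    "imc2",
)
TEXTURE_OFFSETS_PX: tuple[int, ...] = (1, 3)
TEXTURE_FEATURES: tuple[str, ...] = tuple(
    f"txt_{stat}_d{d}" for d in TEXTURE_OFFSETS_PX for stat in HARALICK_STATS
)

CROSS_CHANNEL_FEATURES: tuple[str, ...] = ("cvr", "ck_vim_corr")

#: Marker channels per staining group.
STAINING_GROUPS: dict[str, tuple[str, ...]] = {
    "ECAD": ("ecad",),
    "CK_VIM": ("ck", "vim"),
}

METADATA_COLUMNS: tuple[str, ...] = (
    "cell_id",
    "scene_id",
    "stiffness_kpa",
    "staining_group",
    "clumped",
)


def morphology_feature_names() -> list[str]:
    """The 150 morphology + context feature names, in catalogue order."""
    names = [f"{obj}_{d}" for obj in OBJECTS for d in SHAPE_DESCRIPTORS]
    names += [f"cell_zernike_{n}_{m}" for n, m in ZERNIKE_ORDERS]
    names += list(ENGINEERED_FEATURES)
    names += list(CONTEXT_FEATURES)
    return names


def marker_feature_names(channel: str) -> list[str]:
    """The 69 per-channel marker feature names for one channel prefix."""
    per_channel = (
        list(INTENSITY_FEATURES)
        + list(EDGE_FEATURES)
        + list(MASS_FEATURES)
        + list(RADIAL_FEATURES)
        + list(TEXTURE_FEATURES)
    )
    return [f"{channel}_{name}" for name in per_channel]


def staining_feature_names(staining_group: str) -> list[str]:
    """All marker feature names for a staining group (69 or 140)."""
    channels = STAINING_GROUPS[staining_group]
    names: list[str] = []
    for ch in channels:
        names += marker_feature_names(ch)
    if len(channels) == 2:
        names += list(CROSS_CHANNEL_FEATURES)
    return names


def validate_catalog() -> None:
    """Hard consistency check of the printed catalogue totals (150/69/140)."""
    morph = morphology_feature_names()
    if len(morph) != 150:
        raise AssertionError(f"morphology+context catalogue has {len(morph)} != 150 names")
    single = staining_feature_names("ECAD")
    if len(single) != 69:
        raise AssertionError(f"single-marker catalogue has {len(single)} != 69 names")
    double = staining_feature_names("CK_VIM")
    if len(double) != 140:
        raise AssertionError(f"two-marker catalogue has {len(double)} != 140 names")
    all_names = morph + double + staining_feature_names("ECAD")
    if len(set(morph + double)) != len(morph + double):
        raise AssertionError("duplicate feature names in catalogue")
    del all_names
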