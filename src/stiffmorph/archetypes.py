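"""Morphological archetypes of the three cell morphs and the star-convex shape model.

The generator emulates three recurring morphological states of mesenchymal
breast-carcinoma cells cultured on substrates of graded stiffness:

* morph 1 -- irregular-shaped cells with 2-5 lamellipodial lobes and a rough
  boundary (low circularity, intermediate footprint),
* morph 2 -- large flattened cells (large area, smooth outline, mild
  elongation),
* morph 3 -- small compact roundish cells (small area, near-circular).

Cell outlines are star-convex radial polygons ``r(theta) = r0 * (1 + lobes +
roughness)`` which guarantees simple (non-self-intersecting) closed contours
with controllable circularity. The nucleus is an ellipse placed fully inside
the cell with a small centroid offset (cell polarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STIFFNESS_LEVELS = (0.2, 2.0, 16.0, 32.0, 64.0)

#: Vertices used to trace the radial outline of every cell.
N_OUTLINE_VERTICES = 256

#: Nucleus cross-sectional area (um^2): lognormal, nearly stiffness-invariant.
NUCLEUS_AREA_MEDIAN_UM2 = 55.0
NUCLEUS_AREA_SIGMA_LOG = 0.12
NUCLEUS_AREA_BOUNDS_UM2 = (35.0, 85.0)
NUCLEUS_AXIS_RATIO_RANGE = (0.75, 1.0)

#: Stiffness-dependent scale factor applied to the cytoplasm area.  Tuned once
#: so that, together with the default morph mixtures, the absolute Spearman
#: correlation between stiffness and the nuclear-cytoplasmic ratio is ~0.31 at
#: the paper-scale population size (n = 826 single cells).  The profile
#: (dip at 0.2-2 kPa, maximum at 32 kPa, relaxation at 64 kPa) also reproduces
#: the reported NCR trend: widest/highest NCR at 2 kPa, minimum at 32 kPa.
CYTOPLASM_STIFFNESS_SCALE = {
    0.2: 0.88,
    2.0: 0.72,
    16.0: 1.08,
    32.0: 1.26,
    64.0: 1.08,
}


@dataclass(frozen=True)
class MorphArchetype:
    """Generative parameters of one morphological cell type.

    ``area_range`` bounds the sampled cell footprint (um^2, log-uniform), so a
    sampled shape's area is guaranteed to lie inside it.  ``n_protrusions``
    gives the admissible number of lamellipodial lobes (inclusive range).
    """

    morph_id: int
    area_range: tuple[float, float]
    boundary_model: str  # lobed-irregular | smooth-large | smooth-small-round
    n_protrusions: tuple[int, int]
    eccentricity_range: tuple[float, float]
    lobe_amplitude: tuple[float, float] = (0.0, 0.0)
    lobe_width_rad: tuple[float, float] = (0.4, 0.8)
    roughness: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.area_range[0] > 0 and self.area_range[1] > self.area_range[0]):
            raise ValueError(
                f"degenerate area_range {self.area_range!r} for morph {self.morph_id}"
            )
        if not (0.0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1.0):
            raise ValueError("eccentricity_range must lie within [0, 1)")
        if self.n_protrusions[0] < 0:
            raise ValueError("n_protrusions must be non-negative")


#: Default archetypes.  Areas in um^2.  morph 3's area range lies strictly
#: below morph 2's; only morph 1 carries protrusions.
DEFAULT_ARCHETYPES: dict[int, MorphArchetype] = {
    1: MorphArchetype(
        morph_id=1,
        area_range=(900.0, 2200.0),
        boundary_model="lobed-irregular",
        n_protrusions=(2, 5),
        eccentricity_range=(0.60, 0.90),
        lobe_amplitude=(0.45, 0.65),
        lobe_width_rad=(0.22, 0.45),
        roughness=(0.110, 0.170),
    ),
    2: MorphArchetype(
        morph_id=2,
        area_range=(1800.0, 3600.0),
        boundary_model="smooth-large",
        n_protrusions=(0, 0),
        eccentricity_range=(0.30, 0.75),
        roughness=(0.008, 0.020),
    ),
    3: MorphArchetype(
        morph_id=3,
        area_range=(180.0, 450.0),
        boundary_model="smooth-small-round",
        n_protrusions=(0, 0),
        eccentricity_range=(0.05, 0.50),
        roughness=(0.004, 0.015),
    ),
}


@dataclass
class CellShape:
    """One sampled cell: outline polygon plus nucleus ellipse (um, centred)."""

    morph_id: int
    vertices: np.ndarray  # (N, 2) closed implicitly (last connects to first)
    area_um2: float
    nucleus_center: np.ndarray  # (2,) offset from cell origin
    nucleus_axes: tuple[float, float]  # semi-axes (major, minor), um
    nucleus_angle: float  # radians
    nucleus_area_um2: float = field(init=False)

    def __post_init__(self) -> None:
        self.nucleus_area_um2 = float(np.pi * self.nucleus_axes[0] * self.nucleus_axes[1])

    @property
    def max_radius_um(self) -> float:
        return float(np.hypot(self.vertices[:, 0], self.vertices[:, 1]).max())


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as an (N, 2) vertex array."""
    x, y = vertices[:, 0], vertices[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def _radial_profile(
    arch: MorphArchetype, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unit radial profile r(theta)/r0 for one sampled cell."""
    theta = np.linspace(0.0, 2.0 * np.pi, N_OUTLINE_VERTICES, endpoint=False)
    ecc = rng.uniform(*arch.eccentricity_range)
    axis_ratio = float(np.sqrt(1.0 - ecc**2))  # b/a of the base ellipse
    # Base ellipse with unit geometric-mean radius.
    a = 1.0 / np.sqrt(axis_ratio)
    b = axis_ratio * a
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    modulation = np.zeros_like(theta)
    n_lobes = int(rng.integers(arch.n_protrusions[0], arch.n_protrusions[1] + 1))
    if n_lobes > 0:
        centers = (
            np.arange(n_lobes) * 2.0 * np.pi / n_lobes
            + rng.uniform(0, 2.0 * np.pi)
            + rng.normal(0.0, 0.25, n_lobes)
        )
        for c in centers:
            amp = rng.uniform(*arch.lobe_amplitude)
            width = rng.uniform(*arch.lobe_width_rad)
            modulation += amp * np.exp((np.cos(theta - c) - 1.0) / width**2)

    rough = rng.uniform(*arch.roughness)
    if rough > 0:
        for m in range(6, 12):
            modulation += rng.normal(0.0, rough) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))

    r = r * np.maximum(1.0 + modulation, 0.45)
    phi = rng.uniform(0, 2.0 * np.pi)  # random orientation of the whole cell
    return theta + phi, r, phi


def sample_cell_area(
    arch: MorphArchetype, stiffness_kpa: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Sample (cell area, nucleus area) in um^2 for one cell.

    The cell area is log-uniform within the archetype's range; the cytoplasm
    component is additionally scaled by the stiffness factor (clipped back into
    the archetype range so the area-range contract holds).
    """
    nucleus = float(
        np.clip(
            NUCLEUS_AREA_MEDIAN_UM2 * np.exp(rng.normal(0.0, NUCLEUS_AREA_SIGMA_LOG)),
            *NUCLEUS_AREA_BOUNDS_UM2,
        )
    )
    lo, hi = arch.area_range
    base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    scale = CYTOPLASM_STIFFNESS_SCALE.get(float(stiffness_kpa), 1.0)
    cell = nucleus + (base - nucleus) * scale
    cell = float(np.clip(cell, lo, hi))
    if cell <= nucleus + 20.0:  # keep a sane cytoplasm for the smallest cells
        cell = nucleus + 20.0
    return cell, nucleus


def sample_cell_shape(
    archetype: MorphArchetype,
    stiffness_kpa: float,
    rng_seed: int | np.random.Generator,
) -> CellShape:
    """Sample one cell outline plus nucleus for an archetype.

    Reproducible: the same (archetype, stiffness, seed) yields identical
    vertices. The returned polygon's area equals the sampled target area
    exactly (radial rescaling), and the nucleus ellipse lies fully inside the
    outline with a positive clearance.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    target_area, nucleus_area = sample_cell_area(archetype, stiffness_kpa, rng)
    theta, runit, phi = _radial_profile(archetype, rng)
    if archetype.boundary_model == "lobed-irregular":
        # Constructive irregularity guarantee: if a draw happens to be too
        # smooth, superimpose extra high-frequency ripple until the analytic
        # circularity of the outline is below 0.45 (so the rasterised value
        # stays clearly below the smooth morphs).
        for attempt in range(6):
            verts = np.column_stack([runit * np.cos(theta), runit * np.sin(theta)])
            perim = float(
                np.sqrt(((np.roll(verts, -1, axis=0) - verts) ** 2).sum(axis=1)).sum()
            )
            circ = 4.0 * np.pi * polygon_area(verts) / perim**2
            if circ <= 0.45:
                break
            mode = 13 + attempt
            runit = runit * np.maximum(
                1.0 + 0.07 * np.cos(mode * theta + rng.uniform(0, 2 * np.pi)), 0.45
            )
    vertices = np.column_stack([runit * np.cos(theta), runit * np.sin(theta)])
    vertices *= np.sqrt(target_area / polygon_area(vertices))

    radii = np.hypot(vertices[:, 0], vertices[:, 1])
    theta_mod = np.mod(theta, 2.0 * np.pi)
    order = np.argsort(theta_mod)
    theta_s, radii_s = theta_mod[order], radii[order]

    axis_ratio = rng.uniform(*NUCLEUS_AXIS_RATIO_RANGE)
    nuc_minor = float(np.sqrt(nucleus_area * axis_ratio / np.pi))
    nuc_major = float(nuc_minor / axis_ratio)
    # Align the nucleus with the cell's long axis (with a small jitter): the
    # central body is widest there, which is also where nuclei sit in
    # elongated cells.
    nuc_angle = float(phi + rng.normal(0.0, 0.15))

    def fits(center: np.ndarray, scale: float) -> bool:
        t = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
        ca, sa = np.cos(nuc_angle), np.sin(nuc_angle)
        bx = center[0] + scale * (nuc_major * np.cos(t) * ca - nuc_minor * np.sin(t) * sa)
        by = center[1] + scale * (nuc_major * np.cos(t) * sa + nuc_minor * np.sin(t) * ca)
        ang = np.mod(np.arctan2(by, bx), 2.0 * np.pi)
        rad = np.hypot(bx, by)
        r_out = np.interp(ang, theta_s, radii_s, period=2.0 * np.pi)
        return bool(np.all(rad <= r_out - 0.8))

    # Nucleus offset from the cell origin = cell polarity; walk the desired
    # offset inward (then shrink the nucleus as a last resort) until the
    # ellipse is fully contained with ~1 um clearance.
    direction = rng.uniform(0, 2.0 * np.pi)
    offset_target = rng.uniform(0.0, 0.5) * max(
        float(np.median(radii)) - nuc_major, 0.0
    )
    center = np.zeros(2)
    scale = 1.0
    placed = False
    for factor in (1.0, 0.7, 0.5, 0.3, 0.15, 0.0):
        cand = offset_target * factor * np.array(
            [np.cos(direction), np.sin(direction)]
        )
        if fits(cand, 1.0):
            center, placed = cand, True
            break
    if not placed:
        for scale in (0.95, 0.9, 0.85, 0.8, 0.7, 0.6, 0.5):
            if fits(np.zeros(2), scale):
                placed = True
                break
        center = np.zeros(2)
    nuc_major *= scale
    nuc_minor *= scale

    return CellShape(
        morph_id=archetype.morph_id,
        vertices=vertices,
        area_um2=target_area,
        nucleus_center=center,
        nucleus_axes=(nuc_major, nuc_minor),
        nucleus_angle=nuc_angle,
    )
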