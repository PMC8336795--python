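"""Synthetic multi-channel fluorescence scenes with per-cell ground truth.

The generator emulates the statistical structure of a stiffness-profiling
experiment on mesenchymal breast-carcinoma cells: five substrate stiffness
levels (0.2, 2, 16, 32, 64 kPa), two staining groups (E-cadherin vs
cytokeratin + vimentin, each alongside DNA and membrane channels), three
morphological archetypes with stiffness-dependent mixtures (morph 3 peaking
at 2 kPa), multicellular clumps only on the 64-kPa substrate, and
stiffness-dependent biomarker levels (E-cadherin maxima at 2 and 64 kPa,
vimentin peak at 2 kPa, cytokeratins rising over 16-64 kPa, elevated
edge-localised E-cadherin in clumped and 2-kPa cells).

Morph mixtures are realised by largest-remainder quota allocation, so the
packaged "paper-scale" profile deterministically contains 910 cells, of which
84 (all at 64 kPa) are clump members and 826 form the single-cell set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from . import profiling
from .archetypes import (
    DEFAULT_ARCHETYPES,
    STIFFNESS_LEVELS,
    CellShape,
    MorphArchetype,
    sample_cell_shape,
)
from .catalog import STAINING_GROUPS

# ---------------------------------------------------------------------------
# rendering constants (16-bit counts)
# ---------------------------------------------------------------------------

BG_LEVEL = 1000.0
DNA_FG = 30000.0
MEM_FG = 22000.0
MARKER_BG = 500.0
MARKER_BASE = 8000.0
#: Gaussian read noise, ~2% of the image dynamic range.
NOISE_SIGMA = 600.0
#: Width of the bright boundary band carrying the edge-localised signal (px).
EDGE_BAND_PX = 2
#: Per-cell lognormal variation of marker levels (sigma of log).
MARKER_CELL_SIGMA = 0.25

#: Stiffness -> mean-intensity multipliers per marker.  E-cadherin has local
#: maxima at 2 and 64 kPa; vimentin peaks at 2 kPa; cytokeratins rise
#: monotonically over 16-64 kPa (so the CK/vimentin ratio dips at 2 kPa).
MARKER_STIFFNESS_SCALE: dict[str, dict[float, float]] = {
    "ecad": {0.2: 1.0, 2.0: 1.6, 16.0: 0.9, 32.0: 0.8, 64.0: 1.4},
    "vim": {0.2: 1.0, 2.0: 1.7, 16.0: 1.25, 32.0: 1.1, 64.0: 1.05},
    "ck": {0.2: 1.0, 2.0: 0.95, 16.0: 1.0, 32.0: 1.3, 64.0: 1.6},
}
#: Small round cells carry a higher E-cadherin mean intensity.
ECAD_MORPH3_SCALE = 1.3
#: Clump members express less total E-cadherin but relocate it to the surface.
ECAD_CLUMPED_LEVEL_SCALE = 0.7

DEFAULT_EDGE_MULT = 1.3
ECAD_EDGE_MULT_2KPA = 2.2
ECAD_EDGE_MULT_CLUMPED = 3.2
VIM_CK_EDGE_MULT = 1.2

#: Default morph mixtures (morph1, morph2, morph3) per stiffness level,
#: encoding the observed composition trend with its extrema at 2 kPa.
DEFAULT_MORPH_MIXTURES: dict[float, tuple[float, float, float]] = {
    0.2: (0.35, 0.25, 0.40),
    2.0: (0.20, 0.15, 0.65),
    16.0: (0.45, 0.30, 0.25),
    32.0: (0.45, 0.35, 0.20),
    64.0: (0.50, 0.25, 0.25),
}
#: Clump composition (morph1, morph2, morph3): morph 3 prevails at 56%.
DEFAULT_CLUMP_MIXTURE: tuple[float, float, float] = (0.40, 0.04, 0.56)

PLACEMENT_MARGIN_PX = 2
PLACEMENT_GAP_PX = 4
PLACEMENT_TRIES = 400


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap within the bounds."""


# ---------------------------------------------------------------------------
# specs and ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class MultiChannelImage:
    """Pixel grid with named channels and a physical pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SceneGroundTruth:
    """Per-cell ground-truth records plus the true label masks of one scene."""

    table: pd.DataFrame
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray


@dataclass
class SceneSpec:
    """Generative parameters for one synthetic field of view."""

    stiffness_kpa: float
    staining_group: str
    n_cells: int
    morph_mixture: tuple[float, float, float]
    clump_fraction: float = 0.0
    clump_mixture: tuple[float, float, float] = DEFAULT_CLUMP_MIXTURE
    pixel_size_um: float = 0.25
    image_shape: tuple[int, int] = (1024, 1024)
    seed: int = 0
    clump_group_size: int = 5
    archetypes: dict[int, MorphArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )

    def __post_init__(self) -> None:
        if self.staining_group not in STAINING_GROUPS:
            raise ValueError(f"unknown staining group {self.staining_group!r}")
        for mix in (self.morph_mixture, self.clump_mixture):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mixture {mix} does not sum to 1")
        if not 0.0 <= self.clump_fraction <= 1.0:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


def quota_allocate(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of ``n`` items to ``proportions``."""
    raw = [n * p for p in proportions]
    counts = [int(math.floor(r)) for r in raw]
    rest = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rest]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# rasterisation and placement
# ---------------------------------------------------------------------------

def rasterise_shape(
    shape: CellShape, pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise one cell outline and nucleus on a tight local canvas.

    Returns (cell_mask, nucleus_mask); the nucleus mask is clipped into the
    cell mask.  A pixel belongs to the cell if its centre is inside the
    polygon.
    """
    from skimage.draw import polygon as draw_polygon

    r_max = shape.max_radius_um / pixel_size_um
    half = int(math.ceil(r_max)) + 2
    size = 2 * half + 1
    verts = shape.vertices / pixel_size_um + half
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=(size, size))
    cell = np.zeros((size, size), dtype=bool)
    cell[rr, cc] = True

    gr, gc = np.mgrid[0:size, 0:size]
    nc = shape.nucleus_center / pixel_size_um + half
    a, b = (ax / pixel_size_um for ax in shape.nucleus_axes)
    ca, sa = math.cos(shape.nucleus_angle), math.sin(shape.nucleus_angle)
    dr0, dc0 = gr - nc[0], gc - nc[1]
    u = dr0 * ca + dc0 * sa
    v = -dr0 * sa + dc0 * ca
    nucleus = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    nucleus &= cell
    return cell, nucleus


def _disk(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius**2


def _assemble_clump(
    masks: list[tuple[np.ndarray, np.ndarray]], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Attach clump members so each touches the group (gap <= 1 px).

    Returns (member_label_canvas, nucleus_label_canvas, combined_mask) on a
    local canvas, or None if attachment fails.  Members are slid inward along
    a random direction from a random already-placed anchor until just before
    overlap, which leaves a 0-1 px gap (touching under the 8-neighbourhood
    rule used by the clump detector).
    """
    sizes = [m[0].shape[0] for m in masks]
    canvas_size = int(sum(sizes)) + 8
    labels = np.zeros((canvas_size, canvas_size), dtype=np.int32)
    nuclei = np.zeros_like(labels)
    centers: list[np.ndarray] = []
    eight = np.ones((3, 3), dtype=bool)

    def full_mask(idx: int, center: np.ndarray) -> np.ndarray | None:
        cell = masks[idx][0]
        h = cell.shape[0] // 2
        r0, c0 = int(round(center[0])) - h, int(round(center[1])) - h
        if (
            r0 < 1
            or c0 < 1
            or r0 + cell.shape[0] > canvas_size - 1
            or c0 + cell.shape[1] > canvas_size - 1
        ):
            return None
        out = np.zeros((canvas_size, canvas_size), dtype=bool)
        out[r0 : r0 + cell.shape[0], c0 : c0 + cell.shape[1]] = cell
        return out

    def blit(idx: int, center: np.ndarray) -> None:
        cell, nuc = masks[idx]
        h = cell.shape[0] // 2
        r0, c0 = int(round(center[0])) - h, int(round(center[1])) - h
        labels[r0 : r0 + cell.shape[0], c0 : c0 + cell.shape[1]][cell] = idx + 1
        nuclei[r0 : r0 + nuc.shape[0], c0 : c0 + nuc.shape[1]][nuc] = idx + 1
        centers.append(np.asarray(center, dtype=float))

    mid = canvas_size // 2
    blit(0, np.array([mid, mid], dtype=float))
    for idx in range(1, len(masks)):
        placed = False
        for _ in range(80):
            anchor = centers[int(rng.integers(len(centers)))]
            phi = rng.uniform(0, 2 * np.pi)
            direction = np.array([math.cos(phi), math.sin(phi)])
            d_start = max(sizes) // 2 + sizes[idx] // 2 + 3
            d_hit = None
            for d in range(d_start, -1, -1):
                fm = full_mask(idx, anchor + direction * d)
                if fm is None:
                    d_hit = None
                    break
                if (fm & (labels != 0)).any():
                    d_hit = d
                    break
            if d_hit is None or d_hit >= d_start:
                continue
            cand = anchor + direction * (d_hit + 1)
            fm = full_mask(idx, cand)
            if fm is None or (fm & (labels != 0)).any():
                continue
            touching = (
                ndimage.binary_dilation(fm, structure=eight) & (labels != 0)
            ).any()
            if not touching:
                continue
            blit(idx, cand)
            placed = True
            break
        if not placed:
            return None
    combined = labels != 0
    rr, cc = np.nonzero(combined)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    return labels[r0:r1, c0:c1], nuclei[r0:r1, c0:c1], combined[r0:r1, c0:c1]


def _chain_clump(
    masks: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic fallback clump layout: members chained along one axis.

    Each member slides towards the previous one until just before overlap,
    guaranteeing a touching chain for any member shapes.
    """
    sizes = [m[0].shape[0] for m in masks]
    canvas_size = int(sum(sizes)) + 8
    labels = np.zeros((canvas_size, canvas_size), dtype=np.int32)
    nuclei = np.zeros_like(labels)
    mid = canvas_size // 2

    def blit(idx: int, center: tuple[int, int]) -> None:
        cell, nuc = masks[idx]
        h = cell.shape[0] // 2
        r0, c0 = center[0] - h, center[1] - h
        labels[r0 : r0 + cell.shape[0], c0 : c0 + cell.shape[1]][cell] = idx + 1
        nuclei[r0 : r0 + nuc.shape[0], c0 : c0 + nuc.shape[1]][nuc] = idx + 1

    def overlaps(idx: int, center: tuple[int, int]) -> bool:
        cell = masks[idx][0]
        h = cell.shape[0] // 2
        r0, c0 = center[0] - h, center[1] - h
        region = labels[r0 : r0 + cell.shape[0], c0 : c0 + cell.shape[1]]
        return bool((region[cell] != 0).any())

    # Snake layout (alternate right/down attachments) keeps the bounding box
    # compact enough to fit a scene even for large member chains.
    start = max(sizes[0] // 2 + 2, canvas_size // 4)
    cur = (start, start)
    blit(0, cur)
    for idx in range(1, len(masks)):
        step = (0, 1) if idx % 2 else (1, 0)
        d_max = sizes[idx - 1] // 2 + sizes[idx] // 2 + 2
        d = d_max
        while d > 1 and not overlaps(
            idx, (cur[0] + step[0] * (d - 1), cur[1] + step[1] * (d - 1))
        ):
            d -= 1
        cur = (cur[0] + step[0] * d, cur[1] + step[1] * d)
        blit(idx, cur)
    combined = labels != 0
    rr, cc = np.nonzero(combined)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    return labels[r0:r1, c0:c1], nuclei[r0:r1, c0:c1], combined[r0:r1, c0:c1]


def assemble_clump(
    masks: list[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
    retries: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clump layout with random attachment, falling back to a chain."""
    for _ in range(retries):
        out = _assemble_clump(masks, rng)
        if out is not None:
            return out
    return _chain_clump(masks)


def _place_on_scene(
    occupancy: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    margin: int = PLACEMENT_MARGIN_PX,
    gap: int = PLACEMENT_GAP_PX,
    tries: int = PLACEMENT_TRIES,
) -> tuple[int, int] | None:
    """Find a top-left offset where ``mask`` fits with the required gap."""
    h, w = mask.shape
    H, W = occupancy.shape
    if H - 2 * margin < h or W - 2 * margin < w:
        return None
    # Pad before dilating so the exclusion halo is not clipped at the bbox.
    dilated = ndimage.binary_dilation(np.pad(mask, gap), structure=_disk(gap))
    ph, pw = dilated.shape
    for _ in range(tries):
        r0 = int(rng.integers(margin, H - margin - h + 1))
        c0 = int(rng.integers(margin, W - margin - w + 1))
        rr0, cc0 = r0 - gap, c0 - gap
        sub = occupancy[
            max(rr0, 0) : min(rr0 + ph, H), max(cc0, 0) : min(cc0 + pw, W)
        ]
        dsub = dilated[
            max(rr0, 0) - rr0 : max(rr0, 0) - rr0 + sub.shape[0],
            max(cc0, 0) - cc0 : max(cc0, 0) - cc0 + sub.shape[1],
        ]
        if not (sub & dsub).any():
            occupancy[r0 : r0 + h, c0 : c0 + w] |= mask
            return r0, c0
    return None


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _marker_levels(
    marker: str,
    stiffness: float,
    morph_id: int,
    clumped: bool,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(interior level, edge multiplier) for one cell and marker."""
    level = MARKER_BASE * MARKER_STIFFNESS_SCALE[marker][float(stiffness)]
    edge_mult = DEFAULT_EDGE_MULT if marker == "ecad" else VIM_CK_EDGE_MULT
    if marker == "ecad":
        if morph_id == 3:
            level *= ECAD_MORPH3_SCALE
        if clumped:
            level *= ECAD_CLUMPED_LEVEL_SCALE
            edge_mult = ECAD_EDGE_MULT_CLUMPED
        elif float(stiffness) == 2.0:
            edge_mult = ECAD_EDGE_MULT_2KPA
    level *= math.exp(rng.normal(0.0, MARKER_CELL_SIGMA))
    return level, edge_mult


def _plan_cells(spec: SceneSpec) -> tuple[list[int], list[list[int]]]:
    """Realise the scene's morph mixture by quota into singles and clumps."""
    n_clumped = int(round(spec.clump_fraction * spec.n_cells))
    n_single = spec.n_cells - n_clumped
    singles: list[int] = []
    for morph, cnt in zip((1, 2, 3), quota_allocate(n_single, spec.morph_mixture)):
        singles += [morph] * cnt
    clump_cells: list[int] = []
    for morph, cnt in zip((1, 2, 3), quota_allocate(n_clumped, spec.clump_mixture)):
        clump_cells += [morph] * cnt
    clumps = [
        clump_cells[i : i + spec.clump_group_size]
        for i in range(0, len(clump_cells), spec.clump_group_size)
    ]
    clumps = [c for c in clumps if c]
    return singles, clumps


def generate_scene(
    spec: SceneSpec,
    *,
    singles: list[int] | None = None,
    clumps: list[list[int]] | None = None,
    allow_partial: bool = False,
) -> tuple[MultiChannelImage, SceneGroundTruth, list[int], list[list[int]]]:
    """Generate one scene.

    Returns (image, ground truth, spilled singles, spilled clumps).

    ``singles``/``clumps`` override the mixture realisation with explicit
    per-cell morph ids.  With ``allow_partial`` cells that cannot be placed
    are returned for the caller to spill into a fresh scene instead of
    raising ``PlacementError``.
    """
    rng = np.random.default_rng(spec.seed)
    if singles is None or clumps is None:
        singles, clumps = _plan_cells(spec)

    H, W = spec.image_shape
    px = spec.pixel_size_um
    markers = STAINING_GROUPS[spec.staining_group]

    # Sample all shapes first (determinism does not depend on placement).
    single_shapes = [
        sample_cell_shape(spec.archetypes[m], spec.stiffness_kpa, rng) for m in singles
    ]
    clump_shapes = [
        [sample_cell_shape(spec.archetypes[m], spec.stiffness_kpa, rng) for m in group]
        for group in clumps
    ]

    occupancy = np.zeros((H, W), dtype=bool)
    cell_labels = np.zeros((H, W), dtype=np.int32)
    nucleus_labels = np.zeros((H, W), dtype=np.int32)
    records: list[dict] = []
    spilled_singles: list[int] = []
    spilled_clumps: list[list[int]] = []
    next_label = 1

    def add_cell(
        cell: np.ndarray, nuc: np.ndarray, r0: int, c0: int, shape: CellShape,
        clump_id: int,
    ) -> None:
        nonlocal next_label
        lab = next_label
        next_label += 1
        cell_labels[r0 : r0 + cell.shape[0], c0 : c0 + cell.shape[1]][cell] = lab
        nucleus_labels[r0 : r0 + nuc.shape[0], c0 : c0 + nuc.shape[1]][nuc] = lab
        rr, cc = np.nonzero(cell_labels == lab)
        rec = {
            "label": lab,
            "morph_id": shape.morph_id,
            "clumped": clump_id >= 0,
            "clump_id": clump_id,
            "centroid_row": float(rr.mean()),
            "centroid_col": float(cc.mean()),
            "area_px": int(len(rr)),
            "area_um2": shape.area_um2,
            "nucleus_area_um2": shape.nucleus_area_um2,
        }
        for marker in markers:
            level, edge_mult = _marker_levels(
                marker, spec.stiffness_kpa, shape.morph_id, clump_id >= 0, rng
            )
            rec[f"{marker}_level"] = level
            rec[f"{marker}_edge_mult"] = edge_mult
        records.append(rec)

    # Clumps first (largest footprint), then singles largest-first.
    for group, shapes in zip(clumps, clump_shapes):
        masks = [rasterise_shape(s, px) for s in shapes]
        labs, nucs, combined = assemble_clump(masks, rng)
        pos = _place_on_scene(occupancy, combined, rng)
        if pos is None:
            if not allow_partial:
                raise PlacementError("could not place clump")
            spilled_clumps.append(group)
            continue
        r0, c0 = pos
        cid = max([r["clump_id"] for r in records], default=-1) + 1
        for j, shape in enumerate(shapes, start=1):
            add_cell(labs == j, nucs == j, r0, c0, shape, cid)

    order = sorted(
        range(len(single_shapes)), key=lambda i: -single_shapes[i].area_um2
    )
    for i in order:
        shape = single_shapes[i]
        cell, nuc = rasterise_shape(shape, px)
        pos = _place_on_scene(occupancy, cell, rng)
        if pos is None:
            if not allow_partial:
                raise PlacementError(
                    f"could not place cell of {shape.area_um2:.0f} um^2 "
                    f"after {PLACEMENT_TRIES} tries"
                )
            spilled_singles.append(singles[i])
            continue
        add_cell(cell, nuc, pos[0], pos[1], shape, -1)

    image = _render_channels(spec, cell_labels, nucleus_labels, records, rng)
    gt = SceneGroundTruth(
        table=pd.DataFrame(records),
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
    )
    return image, gt, spilled_singles, spilled_clumps


def _render_channels(
    spec: SceneSpec,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    records: list[dict],
    rng: np.random.Generator,
) -> MultiChannelImage:
    markers = STAINING_GROUPS[spec.staining_group]
    H, W = cell_labels.shape
    dna = np.full((H, W), BG_LEVEL)
    mem = np.full((H, W), BG_LEVEL)
    marker_imgs = {m: np.full((H, W), MARKER_BG) for m in markers}

    for rec in records:
        lab = rec["label"]
        cell = cell_labels == lab
        nuc = nucleus_labels == lab
        dna[nuc] = DNA_FG * math.exp(rng.normal(0.0, 0.10))
        level_mem = MEM_FG * math.exp(rng.normal(0.0, 0.08))
        mem[cell] = level_mem
        mem[nuc] = level_mem * 0.85
        eroded = ndimage.binary_erosion(cell, iterations=EDGE_BAND_PX)
        band = cell & ~eroded
        for m in markers:
            marker_imgs[m][cell] = rec[f"{m}_level"]
            marker_imgs[m][band] = rec[f"{m}_level"] * rec[f"{m}_edge_mult"]

    channels: dict[str, np.ndarray] = {}
    for name, img in [("DNA", dna), ("MEMBRANE", mem)] + [
        (m.upper(), marker_imgs[m]) for m in markers
    ]:
        noisy = img + rng.normal(0.0, NOISE_SIGMA, size=img.shape)
        channels[name] = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
    return MultiChannelImage(channels=channels, pixel_size_um=spec.pixel_size_um)


# ---------------------------------------------------------------------------
# dataset profiles
# ---------------------------------------------------------------------------

@dataclass
class DatasetProfile:
    """Named configuration for a full multi-condition dataset."""

    name: str
    single_counts: dict[tuple[float, str], int]
    clump_counts: dict[tuple[float, str], int]
    pixel_size_um: float = 1.0
    image_shape: tuple[int, int] = (256, 256)
    cells_per_scene: int = 7
    morph_mixtures: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MORPH_MIXTURES)
    )
    clump_mixture: tuple[float, float, float] = DEFAULT_CLUMP_MIXTURE
    archetypes: dict[int, MorphArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )

    def __post_init__(self) -> None:
        for (stiff, _), n in self.clump_counts.items():
            if n > 0 and stiff != 64.0:
                raise ValueError("default profiles only allow clumps at 64 kPa")

    @property
    def total_cells(self) -> int:
        return sum(self.single_counts.values()) + sum(self.clump_counts.values())


def paper_scale_profile() -> DatasetProfile:
    """The packaged paper-scale profile: 910 cells, 84 clumped, 826 single.

    The printed totals fix only the overall arithmetic; the remainder is
    split as evenly as possible across the 10 stiffness x staining
    conditions (the first six conditions absorb the remainder of 826 / 10),
    and the 84 clump members sit at 64 kPa, 42 per staining group.
    """
    conditions = [
        (s, g) for s in STIFFNESS_LEVELS for g in ("ECAD", "CK_VIM")
    ]
    base, rest = divmod(826, len(conditions))
    single_counts = {
        cond: base + (1 if i < rest else 0) for i, cond in enumerate(conditions)
    }
    clump_counts = {cond: 0 for cond in conditions}
    clump_counts[(64.0, "ECAD")] = 42
    clump_counts[(64.0, "CK_VIM")] = 42
    return DatasetProfile(
        name="paper-scale", single_counts=single_counts, clump_counts=clump_counts
    )


def demo_profile(cells_per_condition: int = 12) -> DatasetProfile:
    """A small profile for quick runs: no clumps except a single 64-kPa group."""
    conditions = [(s, g) for s in STIFFNESS_LEVELS for g in ("ECAD", "CK_VIM")]
    single_counts = {cond: cells_per_condition for cond in conditions}
    clump_counts = {cond: 0 for cond in conditions}
    clump_counts[(64.0, "ECAD")] = 5
    return DatasetProfile(
        name="demo", single_counts=single_counts, clump_counts=clump_counts
    )


PROFILES = {"paper-scale": paper_scale_profile, "demo": demo_profile}


def resolve_profile(profile: str | DatasetProfile) -> DatasetProfile:
    if isinstance(profile, DatasetProfile):
        return profile
    try:
        return PROFILES[profile]()
    except KeyError as exc:
        raise ValueError(
            f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
        ) from exc


def _partition_clump_sizes(n: int, rng: np.random.Generator) -> list[int]:
    """Split ``n`` clump members into groups of 4-7 cells (last may reach 9)."""
    sizes: list[int] = []
    rem = n
    while rem > 11:
        s = int(rng.integers(4, 8))
        sizes.append(s)
        rem -= s
    if 0 < rem < 4:
        if sizes:
            sizes[-1] += rem
        else:
            sizes.append(rem)
    elif 4 <= rem <= 7:
        sizes.append(rem)
    elif rem > 0:
        sizes += [rem // 2, rem - rem // 2]
    return sizes


@dataclass
class ScenePlan:
    scene_id: str
    stiffness_kpa: float
    staining_group: str
    singles: list[int]
    clumps: list[list[int]]
    seed: int


def plan_scenes(profile: DatasetProfile, seed: int) -> list[ScenePlan]:
    """Deterministically split the profile's cell quotas into scene plans."""
    ss = np.random.SeedSequence(seed)
    plan_rng = np.random.default_rng(ss.spawn(1)[0])
    plans: list[ScenePlan] = []
    for stiff in STIFFNESS_LEVELS:
        for group in ("ECAD", "CK_VIM"):
            n_single = profile.single_counts.get((stiff, group), 0)
            n_clump = profile.clump_counts.get((stiff, group), 0)
            singles: list[int] = []
            for morph, cnt in zip(
                (1, 2, 3), quota_allocate(n_single, profile.morph_mixtures[stiff])
            ):
                singles += [morph] * cnt
            perm = plan_rng.permutation(len(singles))
            singles = [singles[i] for i in perm]

            clump_cells: list[int] = []
            for morph, cnt in zip(
                (1, 2, 3), quota_allocate(n_clump, profile.clump_mixture)
            ):
                clump_cells += [morph] * cnt
            perm = plan_rng.permutation(len(clump_cells))
            clump_cells = [clump_cells[i] for i in perm]
            clump_sizes = _partition_clump_sizes(n_clump, plan_rng)
            clump_groups: list[list[int]] = []
            pos = 0
            for s in clump_sizes:
                clump_groups.append(clump_cells[pos : pos + s])
                pos += s

            k = profile.cells_per_scene
            # Balanced chunks (sizes differ by <= 1) so every scene keeps
            # enough cells for the 3rd-nearest-neighbour context features.
            if singles:
                n_scenes_cond = max(int(math.ceil(len(singles) / k)), 1)
                base, extra = divmod(len(singles), n_scenes_cond)
                chunks = []
                pos = 0
                for i in range(n_scenes_cond):
                    size = base + (1 if i < extra else 0)
                    chunks.append(singles[pos : pos + size])
                    pos += size
            else:
                chunks = []
            tag = group.lower()
            idx = 0
            for chunk in chunks:
                plans.append(
                    ScenePlan(
                        scene_id=f"{stiff:g}kpa_{tag}_{idx:02d}",
                        stiffness_kpa=stiff,
                        staining_group=group,
                        singles=chunk,
                        clumps=[],
                        seed=0,
                    )
                )
                idx += 1
            for clump in clump_groups:
                plans.append(
                    ScenePlan(
                        scene_id=f"{stiff:g}kpa_{tag}_{idx:02d}",
                        stiffness_kpa=stiff,
                        staining_group=group,
                        singles=[],
                        clumps=[clump],
                        seed=0,
                    )
                )
                idx += 1
    children = ss.spawn(len(plans) + 1)[1:]
    for plan, child in zip(plans, children):
        plan.seed = int(child.generate_state(1)[0] % (2**31))
    return plans


@dataclass
class SceneRecord:
    scene_id: str
    stiffness_kpa: float
    staining_group: str
    image: MultiChannelImage
    ground_truth: SceneGroundTruth


def iter_scenes(
    profile: str | DatasetProfile, seed: int
) -> Iterator[SceneRecord]:
    """Generate every scene of a dataset profile, spilling placement overflow.

    Cells that cannot be placed in their planned scene are re-queued into
    fresh scenes of the same condition, so the profile's cell counts are
    realised exactly.
    """
    profile = resolve_profile(profile)
    plans = plan_scenes(profile, seed)
    for plan_idx, plan in enumerate(plans):
        image = gt = None
        for attempt in range(20):
            scene_seed = (
                plan.seed
                if attempt == 0
                else int(
                    np.random.SeedSequence([seed, plan_idx, attempt]).generate_state(1)[0]
                    % (2**31)
                )
            )
            spec = SceneSpec(
                stiffness_kpa=plan.stiffness_kpa,
                staining_group=plan.staining_group,
                n_cells=max(len(plan.singles) + sum(len(c) for c in plan.clumps), 1),
                morph_mixture=(1.0, 0.0, 0.0),
                pixel_size_um=profile.pixel_size_um,
                image_shape=profile.image_shape,
                seed=scene_seed,
                archetypes=profile.archetypes,
            )
            image, gt, sp_singles, sp_clumps = generate_scene(
                spec, singles=plan.singles, clumps=plan.clumps, allow_partial=True
            )
            if not sp_singles and not sp_clumps:
                break
            # A placement failure invalidates the whole attempt: re-draw the
            # scene with a derived seed so its planned cell list stays intact.
            image = gt = None
        if gt is None:
            raise PlacementError(
                f"scene {plan.scene_id}: could not place its planned cells in "
                f"20 attempts; reduce cells_per_scene or enlarge image_shape"
            )
        if len(gt.table) == 0:
            continue
        yield SceneRecord(
            scene_id=plan.scene_id,
            stiffness_kpa=plan.stiffness_kpa,
            staining_group=plan.staining_group,
            image=image,
            ground_truth=gt,
        )


def generate_dataset(
    profile: str | DatasetProfile, seed: int
) -> tuple[list[SceneRecord], pd.DataFrame]:
    """Materialise all scenes plus the dataset-level ground-truth table."""
    scenes = list(iter_scenes(profile, seed))
    return scenes, ground_truth_table(scenes)


def ground_truth_table(scenes: list[SceneRecord]) -> pd.DataFrame:
    frames = []
    cell_id = 1
    for rec in scenes:
        t = rec.ground_truth.table.copy()
        t.insert(0, "cell_id", np.arange(cell_id, cell_id + len(t)))
        cell_id += len(t)
        t.insert(1, "scene_id", rec.scene_id)
        t.insert(2, "stiffness_kpa", rec.stiffness_kpa)
        t.insert(3, "staining_group", rec.staining_group)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# image-free fast path
# ---------------------------------------------------------------------------

def generate_feature_table(
    profile: str | DatasetProfile, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell feature rows computed on ground-truth masks (no scenes).

    Each cell (or clump) is rasterised alone on a tight local canvas, its
    marker patch rendered, and the real profiling feature functions applied,
    so the fast path shares the image path's feature distributions while
    skipping scene assembly and segmentation.  Centroid-based context
    features for single cells are drawn from a field-of-view position model
    instead of an actual placement.

    Returns (feature table, ground-truth table) with the same schema as the
    full pipeline.
    """
    profile = resolve_profile(profile)
    plans = plan_scenes(profile, seed)
    rows: list[dict[str, float]] = []
    meta: list[dict] = []
    gt_rows: list[dict] = []
    cell_id = 1
    px = profile.pixel_size_um
    H, W = profile.image_shape

    for plan in plans:
        rng = np.random.default_rng(plan.seed)
        markers = STAINING_GROUPS[plan.staining_group]
        n_cells = len(plan.singles) + sum(len(c) for c in plan.clumps)

        # entries: (info, feats, entity index, offset within entity)
        scene_entries: list[tuple[dict, dict[str, float], int, np.ndarray]] = []
        entity_radii: list[float] = []  # px, for the size-aware position model

        for group_idx, group in enumerate(plan.clumps):
            shapes = [
                sample_cell_shape(profile.archetypes[m], plan.stiffness_kpa, rng)
                for m in group
            ]
            masks = [rasterise_shape(s, px) for s in shapes]
            labs, nucs, _ = assemble_clump(masks, rng)
            centroids = {}
            areas = {}
            for j in range(1, len(shapes) + 1):
                rr, cc = np.nonzero(labs == j)
                centroids[j] = np.array([rr.mean(), cc.mean()])
                areas[j] = len(rr)
            mean_centroid = np.mean(list(centroids.values()), axis=0)
            entity = len(entity_radii)
            entity_radii.append(max(labs.shape) / 2.0)
            for j, shape in enumerate(shapes, start=1):
                cell_mask = labs == j
                nuc_mask = nucs == j
                channels = _render_cell_patch(
                    cell_mask, markers, plan.stiffness_kpa, shape.morph_id, True, rng
                )
                feats = profiling.profile_cell(
                    cell_mask, nuc_mask, px, channels["imgs"], markers
                )
                feats.update(
                    profiling.context_features(
                        labs, j, px, centroids=centroids, areas=areas
                    )
                )
                scene_entries.append(
                    (
                        {
                            "morph_id": shape.morph_id,
                            "clumped": True,
                            "clump_id": group_idx,
                            "area_um2": shape.area_um2,
                            "nucleus_area_um2": shape.nucleus_area_um2,
                            **channels["levels"],
                        },
                        feats,
                        entity,
                        centroids[j] - mean_centroid,
                    )
                )

        for morph in plan.singles:
            shape = sample_cell_shape(profile.archetypes[morph], plan.stiffness_kpa, rng)
            cell_mask, nuc_mask = rasterise_shape(shape, px)
            channels = _render_cell_patch(
                cell_mask, markers, plan.stiffness_kpa, shape.morph_id, False, rng
            )
            feats = profiling.profile_cell(
                cell_mask, nuc_mask, px, channels["imgs"], markers
            )
            entity = len(entity_radii)
            entity_radii.append(math.sqrt(shape.area_um2 / math.pi) / px)
            scene_entries.append(
                (
                    {
                        "morph_id": shape.morph_id,
                        "clumped": False,
                        "clump_id": -1,
                        "area_um2": shape.area_um2,
                        "nucleus_area_um2": shape.nucleus_area_um2,
                        **channels["levels"],
                    },
                    feats,
                    entity,
                    np.zeros(2),
                )
            )

        # Size-aware pseudo-placement mirroring the scene placement gaps,
        # used only for the centroid-based context of single cells.
        entity_pos = _sample_positions_sized(entity_radii, (H, W), rng)
        all_pos = np.array(
            [entity_pos[e] + off for (_, _, e, off) in scene_entries]
        )
        all_areas = np.array([e[0]["area_um2"] / px**2 for e in scene_entries])
        for i, (info, feats, _, _) in enumerate(scene_entries):
            if not info["clumped"]:
                feats.update(_centroid_context(i, all_pos, all_areas, px))
            meta.append(
                {
                    "cell_id": cell_id,
                    "scene_id": plan.scene_id,
                    "stiffness_kpa": plan.stiffness_kpa,
                    "staining_group": plan.staining_group,
                    "clumped": info["clumped"],
                }
            )
            gt_rows.append(
                {
                    "cell_id": cell_id,
                    "scene_id": plan.scene_id,
                    "stiffness_kpa": plan.stiffness_kpa,
                    "staining_group": plan.staining_group,
                    **info,
                }
            )
            rows.append(feats)
            cell_id += 1

    tables = []
    gt = pd.DataFrame(gt_rows)
    meta_df = pd.DataFrame(meta)
    for group in meta_df["staining_group"].unique():
        sel = meta_df["staining_group"] == group
        sub_rows = [rows[i] for i in np.nonzero(sel.values)[0]]
        sub_meta = [meta[i] for i in np.nonzero(sel.values)[0]]
        tables.append(profiling.assemble_table(sub_rows, sub_meta, group))
    table = pd.concat(tables, ignore_index=True).sort_values("cell_id")
    return table.reset_index(drop=True), gt


def _sample_positions_sized(
    radii_px: list[float], shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Greedy sequential positions with size-dependent separation.

    Mirrors the scene placement statistics (gap >= PLACEMENT_GAP_PX between
    object envelopes, larger objects placed first) without rasterising.
    """
    order = np.argsort(radii_px)[::-1]
    pos = np.full((len(radii_px), 2), np.nan)
    for idx in order:
        r_i = radii_px[idx]
        relax = 1.0
        for attempt in range(300):
            r = rng.uniform(r_i + PLACEMENT_MARGIN_PX, shape[0] - r_i - PLACEMENT_MARGIN_PX)
            c = rng.uniform(r_i + PLACEMENT_MARGIN_PX, shape[1] - r_i - PLACEMENT_MARGIN_PX)
            ok = True
            for jdx in order:
                if jdx == idx or np.isnan(pos[jdx, 0]):
                    continue
                min_d = (r_i + radii_px[jdx] + PLACEMENT_GAP_PX) * relax
                if (r - pos[jdx, 0]) ** 2 + (c - pos[jdx, 1]) ** 2 < min_d**2:
                    ok = False
                    break
            if ok:
                pos[idx] = (r, c)
                break
            if attempt % 60 == 59:
                relax *= 0.85
        if np.isnan(pos[idx, 0]):
            pos[idx] = (
                rng.uniform(PLACEMENT_MARGIN_PX, shape[0] - PLACEMENT_MARGIN_PX),
                rng.uniform(PLACEMENT_MARGIN_PX, shape[1] - PLACEMENT_MARGIN_PX),
            )
    return pos


def _centroid_context(
    i: int, positions: np.ndarray, areas_px: np.ndarray, pixel_size_um: float
) -> dict[str, float]:
    from .catalog import CONTEXT_DENSITY_RADII_UM

    out = {
        "ctx_neighbor_count": 0.0,
        "ctx_shared_boundary_pct": 0.0,
        "ctx_shared_boundary_um": 0.0,
    }
    others = np.delete(np.arange(len(positions)), i)
    if len(others) == 0:
        out.update(
            ctx_nn1_dist=float("nan"),
            ctx_nn2_dist=float("nan"),
            ctx_nn3_dist=float("nan"),
            ctx_nn_mean3=float("nan"),
            ctx_inv_dist_sum=0.0,
            ctx_nn1_area_ratio=float("nan"),
        )
        for r in CONTEXT_DENSITY_RADII_UM:
            out[f"ctx_density_r{int(r)}"] = 0.0
        return out
    d = (
        np.sqrt(((positions[others] - positions[i]) ** 2).sum(axis=1))
        * pixel_size_um
    )
    order = np.argsort(d)
    ds = d[order]
    nn = [float(ds[k]) if k < len(ds) else float("nan") for k in range(3)]
    finite = [v for v in nn if not math.isnan(v)]
    out["ctx_nn1_dist"], out["ctx_nn2_dist"], out["ctx_nn3_dist"] = nn
    out["ctx_nn_mean3"] = float(np.mean(finite))
    for r in CONTEXT_DENSITY_RADII_UM:
        out[f"ctx_density_r{int(r)}"] = float((d <= r).sum())
    out["ctx_inv_dist_sum"] = float((1.0 / d[d > 0]).sum())
    out["ctx_nn1_area_ratio"] = float(
        areas_px[others[order[0]]] / areas_px[i]
    )
    return out


def _render_cell_patch(
    cell_mask: np.ndarray,
    markers: tuple[str, ...],
    stiffness: float,
    morph_id: int,
    clumped: bool,
    rng: np.random.Generator,
) -> dict:
    """Marker channel patches for one isolated cell (fast path)."""
    imgs: dict[str, np.ndarray] = {}
    levels: dict[str, float] = {}
    eroded = ndimage.binary_erosion(cell_mask, iterations=EDGE_BAND_PX)
    band = cell_mask & ~eroded
    for m in markers:
        level, edge_mult = _marker_levels(m, stiffness, morph_id, clumped, rng)
        img = np.full(cell_mask.shape, MARKER_BG)
        img[cell_mask] = level
        img[band] = level * edge_mult
        img += rng.normal(0.0, NOISE_SIGMA, size=img.shape)
        imgs[m] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        levels[f"{m}_level"] = level
        levels[f"{m}_edge_mult"] = edge_mult
    return {"imgs": imgs, "levels": levels}
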