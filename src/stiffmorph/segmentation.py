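"""Cell/nucleus segmentation and the retention rules of the profiling workflow.

The workflow mirrors a manual confocal segmentation protocol with a
reproducible automatic rule: Gaussian noise reduction (sigma = 0.25 um),
global Otsu thresholding of the membrane and DNA channels, 8-connected
labelling, nucleus-centroid pairing, nucleus-seeded watershed splitting of
multi-nucleus components, and rule-based retention:

* cells touching the image border are excluded from the single-cell analysis
  set but kept as context for neighbour statistics;
* touching groups of >= ``clump_min_size`` cells are flagged "clumped" --
  profiled, but partitioned out of the single-cell analysis set;
* touching pairs and other multi-nucleus merges below the clump size are
  treated as unresolvable overlaps and excluded (kept as context);
* cells without a detected nucleus are excluded (kept as context).

Every exclusion carries a reason code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

SMOOTH_SIGMA_UM = 0.25
MIN_OBJECT_UM2 = 20.0
CLUMP_MIN_SIZE = 3
EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class SegmentationResult:
    """Paired cell/nucleus label masks plus retention bookkeeping."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    pairing: dict[int, int]
    retained: set[int] = field(default_factory=set)
    context_set: set[int] = field(default_factory=set)
    clumped: set[int] = field(default_factory=set)
    exclusion_reason: dict[int, str] = field(default_factory=dict)

    @property
    def profiled(self) -> set[int]:
        """Cells that get a feature row: single-cell set plus clumped cells."""
        return self.retained | self.clumped


def smooth(image: np.ndarray, sigma_um: float, pixel_size_um: float) -> np.ndarray:
    """Gaussian noise reduction with a physically specified kernel width."""
    if sigma_um <= 0:
        raise ValueError(f"sigma_um must be positive, got {sigma_um}")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    sigma_px = sigma_um / pixel_size_um
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma_px, mode="reflect")


def threshold_objects(
    channel: np.ndarray,
    pixel_size_um: float,
    min_object_um2: float = MIN_OBJECT_UM2,
) -> np.ndarray:
    """Global Otsu foreground mask with hole filling and small-object removal."""
    channel = np.asarray(channel, dtype=float)
    if channel.max() == channel.min():
        warnings.warn("threshold_objects: zero dynamic range; returning empty mask")
        return np.zeros(channel.shape, dtype=bool)
    mask = channel > threshold_otsu(channel)
    mask = ndimage.binary_fill_holes(mask)
    min_px = max(int(np.ceil(min_object_um2 / pixel_size_um**2)), 1)
    labels, n = ndimage.label(mask, structure=EIGHT_CONN)
    if n:
        sizes = ndimage.sum(mask, labels, np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_px) + 1
        if len(small):
            mask &= ~np.isin(labels, small)
    return mask


def label_and_pair(cell_mask: np.ndarray, nucleus_mask: np.ndarray) -> SegmentationResult:
    """Label cells and nuclei, pair them, and split multi-nucleus components.

    Each nucleus is assigned to the cell component containing its centroid.
    Components holding >= 2 nuclei are split by nucleus-seeded watershed on
    the distance transform (the split members later either form a clump or
    are excluded as overlaps).  Cells without a nucleus stay in the context
    set only.
    """
    if cell_mask.shape != nucleus_mask.shape:
        raise ValueError("cell and nucleus masks must share a shape")
    comp_labels, n_comp = ndimage.label(cell_mask, structure=EIGHT_CONN)
    nuc_labels, n_nuc = ndimage.label(nucleus_mask, structure=EIGHT_CONN)

    nuclei_of: dict[int, list[int]] = {}
    for nuc_id in range(1, n_nuc + 1):
        rr, cc = np.nonzero(nuc_labels == nuc_id)
        cr, cc_ = int(round(rr.mean())), int(round(cc.mean()))
        comp = int(comp_labels[cr, cc_])
        if comp == 0:
            continue  # nucleus centroid over background: unassigned
        nuclei_of.setdefault(comp, []).append(nuc_id)

    cell_labels = np.zeros_like(comp_labels)
    pairing: dict[int, int] = {}
    exclusion: dict[int, str] = {}
    context: set[int] = set()
    retained: set[int] = set()
    next_id = 1
    for comp in range(1, n_comp + 1):
        comp_mask = comp_labels == comp
        nucs = nuclei_of.get(comp, [])
        if len(nucs) == 0:
            cell_labels[comp_mask] = next_id
            context.add(next_id)
            exclusion[next_id] = "no_nucleus"
            next_id += 1
        elif len(nucs) == 1:
            cell_labels[comp_mask] = next_id
            pairing[next_id] = nucs[0]
            context.add(next_id)
            retained.add(next_id)
            next_id += 1
        else:
            markers = np.zeros_like(comp_labels)
            for j, nuc_id in enumerate(nucs, start=1):
                markers[(nuc_labels == nuc_id) & comp_mask] = j
            dist = ndimage.distance_transform_edt(comp_mask)
            split = watershed(-dist, markers=markers, mask=comp_mask)
            for j, nuc_id in enumerate(nucs, start=1):
                region = split == j
                if not region.any():
                    continue
                cell_labels[region] = next_id
                pairing[next_id] = nuc_id
                context.add(next_id)
                retained.add(next_id)
                next_id += 1

    # Relabel nuclei by their paired cell id for a consistent mask pair.
    nucleus_out = np.zeros_like(nuc_labels)
    for cell_id, nuc_id in pairing.items():
        nucleus_out[(nuc_labels == nuc_id) & (cell_labels == cell_id)] = cell_id

    return SegmentationResult(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_out,
        pairing=pairing,
        retained=retained,
        context_set=context,
        exclusion_reason=exclusion,
    )


def _touching_groups(cell_labels: np.ndarray) -> list[set[int]]:
    """Connected components of the cell-touching graph (touch distance 1 px)."""
    labels = np.asarray(cell_labels)
    ids = [int(v) for v in np.unique(labels) if v != 0]
    adjacency: dict[int, set[int]] = {i: set() for i in ids}
    padded = np.pad(labels, 1, constant_values=0)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = padded[
                1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc
            ]
            both = (labels != 0) & (shifted != 0) & (labels != shifted)
            for a, b in zip(labels[both].ravel(), shifted[both].ravel()):
                adjacency[int(a)].add(int(b))
    groups: list[set[int]] = []
    seen: set[int] = set()
    for i in ids:
        if i in seen:
            continue
        stack, group = [i], {i}
        while stack:
            j = stack.pop()
            for k in adjacency[j]:
                if k not in group:
                    group.add(k)
                    stack.append(k)
        seen |= group
        groups.append(group)
    return groups


def apply_retention_rules(
    result: SegmentationResult,
    image_shape: tuple[int, int],
    clump_min_size: int = CLUMP_MIN_SIZE,
) -> SegmentationResult:
    """Exclude border-touching cells and sub-clump overlaps from ``retained``.

    Excluded cells remain in the context set (they still count for neighbour
    statistics).  Idempotent.
    """
    labels = result.cell_labels
    border_ids = set()
    for sl in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border_ids |= {int(v) for v in np.unique(sl) if v != 0}
    for cid in border_ids & result.retained:
        result.retained.discard(cid)
        result.exclusion_reason.setdefault(cid, "border")

    for group in _touching_groups(labels):
        if 2 <= len(group) < clump_min_size:
            for cid in group & result.retained:
                result.retained.discard(cid)
                result.exclusion_reason.setdefault(cid, "overlap")
    return result


def flag_clumped(
    result: SegmentationResult, clump_min_size: int = CLUMP_MIN_SIZE
) -> SegmentationResult:
    """Flag touching groups of >= ``clump_min_size`` cells as clumped.

    Clumped cells are profiled but partitioned out of the single-cell
    analysis set; members previously excluded (border, missing nucleus) stay
    excluded.
    """
    for group in _touching_groups(result.cell_labels):
        if len(group) >= clump_min_size:
            for cid in group:
                if cid in result.retained or cid in result.clumped:
                    result.retained.discard(cid)
                    result.clumped.add(cid)
                    result.exclusion_reason.setdefault(cid, "clumped")
    return result


def segment_scene(
    channels: dict[str, np.ndarray],
    pixel_size_um: float,
    *,
    sigma_um: float = SMOOTH_SIGMA_UM,
    min_object_um2: float = MIN_OBJECT_UM2,
    clump_min_size: int = CLUMP_MIN_SIZE,
) -> SegmentationResult:
    """Full segmentation of one scene from its DNA and MEMBRANE channels."""
    mem = smooth(channels["MEMBRANE"], sigma_um, pixel_size_um)
    dna = smooth(channels["DNA"], sigma_um, pixel_size_um)
    cell_mask = threshold_objects(mem, pixel_size_um, min_object_um2)
    nucleus_mask = threshold_objects(dna, pixel_size_um, min_object_um2)
    nucleus_mask &= cell_mask
    result = label_and_pair(cell_mask, nucleus_mask)
    result = apply_retention_rules(
        result, cell_mask.shape, clump_min_size=clump_min_size
    )
    result = flag_clumped(result, clump_min_size=clump_min_size)
    return result
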