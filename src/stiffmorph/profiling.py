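"""Per-cell feature extraction on labelled masks and fluorescence channels.

All geometric features are computed from first principles on pixel sets
(point-mass convention: each pixel contributes its centre coordinate), so the
same quantities can be re-derived by direct pixel enumeration.  Conventions
fixed here and used throughout the package:

* boundary pixels: object pixels with at least one 4-connected neighbour
  outside the object;
* perimeter: 4-direction Crofton estimator,
  ``P = pi/8 * (c_h + c_v + (c_d1 + c_d2)/sqrt(2))`` where ``c_*`` count
  0<->1 transitions along rows, columns and the two diagonal families (the
  estimator is unbiased enough that a rasterised disk has circularity ~1);
* convex hull: taken over pixel *corners*, so convex objects have solidity 1;
* radius statistics: distances from the unweighted pixel centroid to boundary
  pixel centres (population SD);
* cytoplasm (cell minus nucleus): boundary-derived descriptors (perimeter,
  circularity, radius statistics, ...) use the outer (cell) boundary only.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from . import catalog
from .catalog import (
    CONTEXT_DENSITY_RADII_UM,
    HARALICK_STATS,
    N_RADIAL_BINS,
    TEXTURE_OFFSETS_PX,
    ZERNIKE_ORDERS,
)

MIN_OBJECT_PX = 8
GLCM_LEVELS = 64


class InvalidObjectError(ValueError):
    """Raised when an object is too small or degenerate for profiling."""


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Object pixels with >= 1 four-connected neighbour outside the object."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return m & ~interior


def perimeter_crofton4(mask: np.ndarray) -> float:
    """4-direction Crofton perimeter estimate, in pixel units."""
    m = np.pad(np.asarray(mask, dtype=bool), 1, constant_values=False)
    c_h = int(np.count_nonzero(m[:, 1:] ^ m[:, :-1]))
    c_v = int(np.count_nonzero(m[1:, :] ^ m[:-1, :]))
    c_d1 = int(np.count_nonzero(m[1:, 1:] ^ m[:-1, :-1]))
    c_d2 = int(np.count_nonzero(m[1:, :-1] ^ m[:-1, 1:]))
    return float(np.pi / 8.0 * (c_h + c_v + (c_d1 + c_d2) / np.sqrt(2.0)))


def _pixel_coords(mask: np.ndarray) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    return np.column_stack([rr, cc]).astype(float)


def _convex_hull_corner_points(mask: np.ndarray) -> np.ndarray:
    """Hull vertices over the corner points of the object's boundary pixels."""
    b = boundary_mask(mask)
    rr, cc = np.nonzero(b)
    corners = np.concatenate(
        [
            np.column_stack([rr + dr, cc + dc])
            for dr in (-0.5, 0.5)
            for dc in (-0.5, 0.5)
        ]
    )
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def _hull_metrics(hull_pts: np.ndarray) -> tuple[float, float, float, float]:
    """(area, perimeter, feret_max, feret_min) of a convex polygon (px units)."""
    x, y = hull_pts[:, 0], hull_pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    edges = np.roll(hull_pts, -1, axis=0) - hull_pts
    perim = float(np.sqrt((edges**2).sum(axis=1)).sum())
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(axis=2)).max())
    lengths = np.sqrt((edges**2).sum(axis=1))
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
    proj = hull_pts @ normals.T  # (points, edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(area), perim, feret_max, float(widths.min())


def shape_features(
    mask: np.ndarray,
    pixel_size_um: float,
    *,
    boundary: np.ndarray | None = None,
    perimeter_px: float | None = None,
) -> dict[str, float]:
    """The 35 scalar shape descriptors of one object mask (physical units).

    ``boundary`` and ``perimeter_px`` override the boundary pixel set and the
    perimeter estimate; this is how the cytoplasm (annular) object is measured
    against the outer cell boundary only.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < MIN_OBJECT_PX:
        raise InvalidObjectError(f"object has {n} px < {MIN_OBJECT_PX}")
    px = float(pixel_size_um)

    coords = _pixel_coords(mask)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    mu20 = float((d[:, 0] ** 2).mean())
    mu02 = float((d[:, 1] ** 2).mean())
    mu11 = float((d[:, 0] * d[:, 1]).mean())
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4.0 * mu11**2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    lam2 = max(lam2, 0.0)
    eccentricity = math.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    orientation = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)

    area = n * px**2
    perim_px = perimeter_crofton4(mask) if perimeter_px is None else float(perimeter_px)
    perimeter = perim_px * px
    circularity = 4.0 * math.pi * area / perimeter**2
    compactness = perimeter**2 / (4.0 * math.pi * area)
    roundness = 4.0 * n / (math.pi * major**2) if major > 0 else 0.0

    bmask = boundary_mask(mask) if boundary is None else np.asarray(boundary, bool)
    bcoords = _pixel_coords(bmask)
    radii = np.sqrt(((bcoords - centroid) ** 2).sum(axis=1)) * px
    r_mean = float(radii.mean())
    r_sd = float(radii.std())

    hull_pts = _convex_hull_corner_points(mask)
    hull_area_px, hull_perim_px, feret_max_px, feret_min_px = _hull_metrics(hull_pts)

    rr, cc = np.nonzero(mask)
    bbox_h = int(rr.max() - rr.min() + 1)
    bbox_w = int(cc.max() - cc.min() + 1)

    # Hu invariant moments (dimensionless; point-mass pixel-centre convention).
    hu = _hu_moments(coords, centroid, n)

    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": circularity,
        "compactness": compactness,
        "roundness": roundness,
        "eccentricity": eccentricity,
        "solidity": n / hull_area_px,
        "extent": n / (bbox_h * bbox_w),
        "major_axis_length": major * px,
        "minor_axis_length": minor * px,
        "aspect_ratio": major / minor if minor > 0 else 0.0,
        "equivalent_diameter": 2.0 * math.sqrt(area / math.pi),
        "feret_max": feret_max_px * px,
        "feret_min": feret_min_px * px,
        "feret_ratio": feret_min_px / feret_max_px,
        "orientation": orientation,
        "radius_mean": r_mean,
        "radius_median": float(np.median(radii)),
        "radius_max": float(radii.max()),
        "radius_min": float(radii.min()),
        "radius_sd": r_sd,
        "radius_cv": r_sd / r_mean if r_mean > 0 else 0.0,
        "convex_area": hull_area_px * px**2,
        "convex_perimeter": hull_perim_px * px,
        "convexity": hull_perim_px / perim_px,
        "bbox_height": bbox_h * px,
        "bbox_width": bbox_w * px,
        "bbox_aspect": max(bbox_h, bbox_w) / min(bbox_h, bbox_w),
        "hu1": hu[0],
        "hu2": hu[1],
        "hu3": hu[2],
        "hu4": hu[3],
        "hu5": hu[4],
        "hu6": hu[5],
        "hu7": hu[6],
    }


def _hu_moments(coords: np.ndarray, centroid: np.ndarray, n: int) -> np.ndarray:
    """Hu invariants on the signed-log scale, ``-sign(h) * log10(|h|)``.

    The raw invariants span many orders of magnitude (heavy tails that
    dominate z-scored distances); the signed-log transform is the standard
    normalisation for comparing them.  h = 0 maps to 0.
    """
    raw = _hu_moments_raw(coords, centroid, n)
    out = np.zeros_like(raw)
    nz = raw != 0
    out[nz] = -np.sign(raw[nz]) * np.log10(np.abs(raw[nz]))
    return out


def _hu_moments_raw(coords: np.ndarray, centroid: np.ndarray, n: int) -> np.ndarray:
    x = coords[:, 0] - centroid[0]
    y = coords[:, 1] - centroid[1]

    def mu(p: int, q: int) -> float:
        return float(((x**p) * (y**q)).sum())

    def eta(p: int, q: int) -> float:
        return mu(p, q) / n ** (1 + (p + q) / 2.0)

    e20, e02, e11 = eta(2, 0), eta(0, 2), eta(1, 1)
    e30, e03, e21, e12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    h1 = e20 + e02
    h2 = (e20 - e02) ** 2 + 4 * e11**2
    h3 = (e30 - 3 * e12) ** 2 + (3 * e21 - e03) ** 2
    h4 = (e30 + e12) ** 2 + (e21 + e03) ** 2
    h5 = (e30 - 3 * e12) * (e30 + e12) * (
        (e30 + e12) ** 2 - 3 * (e21 + e03) ** 2
    ) + (3 * e21 - e03) * (e21 + e03) * (3 * (e30 + e12) ** 2 - (e21 + e03) ** 2)
    h6 = (e20 - e02) * ((e30 + e12) ** 2 - (e21 + e03) ** 2) + 4 * e11 * (
        e30 + e12
    ) * (e21 + e03)
    h7 = (3 * e21 - e03) * (e30 + e12) * (
        (e30 + e12) ** 2 - 3 * (e21 + e03) ** 2
    ) - (e30 - 3 * e12) * (e21 + e03) * (3 * (e30 + e12) ** 2 - (e21 + e03) ** 2)
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def zernike_magnitudes(mask: np.ndarray, degree: int = 8) -> dict[str, float]:
    """Zernike moment magnitudes |A_nm| of the object silhouette, n <= degree.

    Pixel centres are mapped to the unit disk centred at the unweighted
    centroid and scaled by the maximum boundary radius; the moment is
    ``A_nm = (n+1)/pi * mean_pixels[R_nm(rho) * exp(-i m phi)]``.  Magnitudes
    are translation- and rotation-invariant.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = _pixel_coords(mask)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    r = np.sqrt((d**2).sum(axis=1))
    bmask = boundary_mask(mask)
    bcoords = _pixel_coords(bmask)
    r_max = float(np.sqrt(((bcoords - centroid) ** 2).sum(axis=1)).max())
    if r_max <= 0:
        r_max = 1.0
    rho = np.minimum(r / r_max, 1.0)
    phi = np.arctan2(d[:, 1], d[:, 0])

    out: dict[str, float] = {}
    for n, m in ZERNIKE_ORDERS:
        rad = _zernike_radial(n, m, rho)
        re = float((rad * np.cos(m * phi)).mean())
        im = float((rad * np.sin(m * phi)).mean())
        out[f"cell_zernike_{n}_{m}"] = (n + 1) / np.pi * math.hypot(re, im)
    return out


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        coef = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out += coef * rho ** (n - 2 * s)
    return out


# ---------------------------------------------------------------------------
# engineered features
# ---------------------------------------------------------------------------

def ncr(nucleus_area: float, cytoplasm_area: float) -> float:
    """Nuclear-cytoplasmic ratio = nucleus area / cytoplasm area."""
    if nucleus_area <= 0 or cytoplasm_area <= 0:
        raise InvalidObjectError("NCR requires positive nucleus and cytoplasm areas")
    return nucleus_area / cytoplasm_area


def polarity(
    cell_centroid: np.ndarray, nucleus_centroid: np.ndarray, pixel_size_um: float = 1.0
) -> float:
    """Cell polarity: distance between cell and nucleus centroids (um)."""
    diff = np.asarray(cell_centroid, float) - np.asarray(nucleus_centroid, float)
    return float(np.sqrt((diff**2).sum())) * pixel_size_um


# ---------------------------------------------------------------------------
# intensity / edge / radial / texture features
# ---------------------------------------------------------------------------

def intensity_features(
    mask: np.ndarray,
    channel: np.ndarray,
    pixel_size_um: float,
    *,
    boundary: np.ndarray | None = None,
    perimeter_um: float | None = None,
) -> dict[str, float]:
    """Intensity, edge and mass-displacement statistics of one object.

    ``mean`` is the integrated intensity normalised by the object area (um^2);
    ``mean_edge_intensity`` the boundary-pixel intensity normalised by the
    perimeter (um).  Percentile statistics are per-pixel values.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise InvalidObjectError("empty mask")
    vals = np.asarray(channel, dtype=float)[mask]
    total = float(vals.sum())
    px = float(pixel_size_um)
    area_um2 = n * px**2

    bmask = boundary_mask(mask) if boundary is None else np.asarray(boundary, bool)
    bvals = np.asarray(channel, dtype=float)[bmask]
    edge_total = float(bvals.sum())
    perim = (
        perimeter_crofton4(mask) * px if perimeter_um is None else float(perimeter_um)
    )

    mean_px = total / n
    std = float(vals.std())
    med = float(np.median(vals))
    q1, q3 = (float(q) for q in np.percentile(vals, [25, 75]))
    p10, p90 = (float(q) for q in np.percentile(vals, [10, 90]))
    mad = float(np.median(np.abs(vals - med)))
    m2 = float(((vals - mean_px) ** 2).mean())
    if m2 > 0:
        m3 = float(((vals - mean_px) ** 3).mean())
        m4 = float(((vals - mean_px) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    k = max(int(math.ceil(0.1 * n)), 1)
    top10 = float(np.sort(vals)[-k:].sum()) / total if total > 0 else 0.0

    # Mass displacement: intensity-weighted vs unweighted centroid distance.
    coords = _pixel_coords(mask)
    centroid = coords.mean(axis=0)
    if total > 0:
        wcentroid = (coords * vals[:, None]).sum(axis=0) / total
        mass_disp = float(np.sqrt(((wcentroid - centroid) ** 2).sum())) * px
    else:
        mass_disp = 0.0
    bcoords = _pixel_coords(bmask)
    r_max = float(np.sqrt(((bcoords - centroid) ** 2).sum(axis=1)).max()) * px

    n_edge = int(bmask.sum())
    interior_mean = (total - edge_total) / max(n - n_edge, 1)
    out = {
        "integrated": total,
        "mean": total / area_um2,
        "std": std,
        "cv": std / mean_px if mean_px > 0 else 0.0,
        "min": float(vals.min()),
        "p10": p10,
        "q1": q1,
        "median": med,
        "q3": q3,
        "p90": p90,
        "max": float(vals.max()),
        "iqr": q3 - q1,
        "range": float(vals.max() - vals.min()),
        "mad": mad,
        "skewness": skew,
        "kurtosis": kurt,
        "top10_mass_frac": top10,
        "edge_integrated": edge_total,
        "edge_mean_px": edge_total / n_edge if n_edge else 0.0,
        "mean_edge_intensity": edge_total / perim if perim > 0 else 0.0,
        "edge_std": float(bvals.std()) if n_edge else 0.0,
        "edge_min": float(bvals.min()) if n_edge else 0.0,
        "edge_max": float(bvals.max()) if n_edge else 0.0,
        "edge_median": float(np.median(bvals)) if n_edge else 0.0,
        "edge_fraction": edge_fraction(mask, channel, boundary=bmask),
        "edge_interior_ratio": (
            (edge_total / n_edge) / interior_mean if n_edge and interior_mean > 0 else 0.0
        ),
        "mass_displacement_um": mass_disp,
        "mass_displacement_norm": mass_disp / r_max if r_max > 0 else 0.0,
    }
    return out


def edge_fraction(
    mask: np.ndarray, channel: np.ndarray, *, boundary: np.ndarray | None = None
) -> float:
    """Percentage of the object's total signal located on its boundary pixels.

    ``100 * (sum over boundary pixels) / (sum over all object pixels)``; NaN
    (flagged missing) when the total intensity is zero.
    """
    mask = np.asarray(mask, dtype=bool)
    bmask = boundary_mask(mask) if boundary is None else np.asarray(boundary, bool)
    ch = np.asarray(channel, dtype=float)
    total = float(ch[mask].sum())
    if total <= 0:
        warnings.warn("edge_fraction: zero total intensity; returning NaN")
        return float("nan")
    return 100.0 * float(ch[bmask].sum()) / total


def radial_distribution(
    mask: np.ndarray, channel: np.ndarray, n_bins: int = N_RADIAL_BINS
) -> dict[str, float]:
    """Radial intensity distribution in equal-width rings (centroid->boundary).

    Per ring: fraction of the integrated intensity, mean per-pixel intensity
    relative to the object mean, and the intensity CV within the ring.  Empty
    rings contribute zeros; fractions over all rings sum to 1.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(channel, dtype=float)[mask]
    total = float(vals.sum())
    coords = _pixel_coords(mask)
    centroid = coords.mean(axis=0)
    r = np.sqrt(((coords - centroid) ** 2).sum(axis=1))
    bmask = boundary_mask(mask)
    bcoords = _pixel_coords(bmask)
    r_max = float(np.sqrt(((bcoords - centroid) ** 2).sum(axis=1)).max())
    if r_max <= 0:
        r_max = 1.0
    bins = np.minimum((r / r_max * n_bins).astype(int), n_bins - 1)
    overall_mean = vals.mean() if len(vals) else 0.0

    out: dict[str, float] = {}
    for b in range(n_bins):
        sel = vals[bins == b]
        if len(sel) == 0 or total <= 0:
            frac, meanfrac, cv = 0.0, 0.0, 0.0
        else:
            frac = float(sel.sum()) / total
            meanfrac = float(sel.mean()) / overall_mean if overall_mean > 0 else 0.0
            cv = float(sel.std() / sel.mean()) if sel.mean() > 0 else 0.0
        out[f"radial_frac_b{b + 1}"] = frac
        out[f"radial_meanfrac_b{b + 1}"] = meanfrac
        out[f"radial_cv_b{b + 1}"] = cv
    return out


def _masked_glcm(
    levels: np.ndarray, inside: np.ndarray, offset: tuple[int, int], n_levels: int
) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix over pairs inside the object."""
    dr, dc = offset
    h, w = inside.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    ok = inside[r0, c0] & inside[r1, c1]
    a = levels[r0, c0][ok]
    b = levels[r1, c1][ok]
    glcm = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(glcm, (a, b), 1.0)
    glcm += glcm.T
    s = glcm.sum()
    if s > 0:
        glcm /= s
    return glcm


def _haralick_stats(p: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of one normalised GLCM (natural logs).

    Degenerate 0/0 cases (constant-intensity objects) are defined as 0.
    """
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    px_ = p.sum(axis=1)
    py_ = p.sum(axis=0)
    mu_x = float((i * px_).sum())
    mu_y = float((i * py_).sum())
    var_x = float(((i - mu_x) ** 2 * px_).sum())
    var_y = float(((i - mu_y) ** 2 * py_).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / math.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    k_sum = np.arange(2 * n - 1, dtype=float)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    sum_avg = float((k_sum * p_sum).sum())
    sum_entropy = float(-(p_sum[p_sum > 0] * np.log(p_sum[p_sum > 0])).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())

    k_diff = np.arange(n, dtype=float)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_entropy = float(-(p_diff[p_diff > 0] * np.log(p_diff[p_diff > 0])).sum())

    entropy = float(-(p[p > 0] * np.log(p[p > 0])).sum())
    hx = float(-(px_[px_ > 0] * np.log(px_[px_ > 0])).sum())
    hy = float(-(py_[py_ > 0] * np.log(py_[py_ > 0])).sum())
    pxy = np.outer(px_, py_)
    nz = (p > 0) | (pxy > 0)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p[nz] * log_pxy[nz]).sum())
    hxy2 = float(-(pxy[pxy > 0] * np.log(pxy[pxy > 0])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - entropy)), 0.0))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_avg": sum_avg,
        "sum_var": sum_var,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "diff_var": diff_var,
        "diff_entropy": diff_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def texture_features(
    mask: np.ndarray,
    channel: np.ndarray,
    offsets: tuple[int, ...] = TEXTURE_OFFSETS_PX,
    n_levels: int = GLCM_LEVELS,
) -> dict[str, float]:
    """Direction-averaged Haralick texture features at the given offsets.

    Intensities are quantised to ``n_levels`` over the object's min-max range;
    the 13 statistics are averaged over the 4 principal directions per offset.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < MIN_OBJECT_PX:
        raise InvalidObjectError(f"object has {n} px < {MIN_OBJECT_PX}")
    ch = np.asarray(channel, dtype=float)
    vals = ch[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        levels = np.zeros(mask.shape, dtype=np.intp)
        levels[mask] = np.minimum(
            ((vals - vmin) / (vmax - vmin) * n_levels).astype(int), n_levels - 1
        )
    else:
        levels = np.zeros(mask.shape, dtype=np.intp)

    out: dict[str, float] = {}
    for d in offsets:
        dirs = [(0, d), (d, 0), (d, d), (d, -d)]
        acc: dict[str, float] = {s: 0.0 for s in HARALICK_STATS}
        for off in dirs:
            stats = _haralick_stats(_masked_glcm(levels, mask, off, n_levels))
            for s in HARALICK_STATS:
                acc[s] += stats[s]
        for s in HARALICK_STATS:
            out[f"txt_{s}_d{d}"] = acc[s] / len(dirs)
    return out


def cross_channel_features(
    mask: np.ndarray,
    channel_ck: np.ndarray,
    channel_vim: np.ndarray,
    pixel_size_um: float,
) -> dict[str, float]:
    """CVR (cytokeratin/vimentin mean-intensity ratio) and pixel correlation."""
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(channel_ck, float)[mask]
    b = np.asarray(channel_vim, float)[mask]
    mean_ck = a.mean()
    mean_vim = b.mean()
    if mean_vim <= 0:
        warnings.warn("CVR: vimentin mean intensity is zero; returning NaN")
        cvr = float("nan")
    else:
        cvr = float(mean_ck / mean_vim)
    sa, sb = a.std(), b.std()
    corr = float(((a - mean_ck) * (b - mean_vim)).mean() / (sa * sb)) if sa > 0 and sb > 0 else 0.0
    return {"cvr": cvr, "ck_vim_corr": corr}


# ---------------------------------------------------------------------------
# context features
# ---------------------------------------------------------------------------

def context_features(
    cell_labels: np.ndarray,
    target_label: int,
    pixel_size_um: float,
    *,
    centroids: dict[int, np.ndarray] | None = None,
    areas: dict[int, int] | None = None,
) -> dict[str, float]:
    """Neighbourhood context of one cell against every cell in the scene.

    The label mask must contain *all* cells (the context set, including
    border-excluded ones).  Touch distance is 1 px (8-neighbourhood).  In a
    single-cell scene the nearest-distance features are missing (NaN) and the
    counts are 0.
    """
    labels = np.asarray(cell_labels)
    px = float(pixel_size_um)
    if centroids is None or areas is None:
        centroids, areas = scene_centroids_and_areas(labels)

    mask = labels == target_label
    padded = np.pad(labels, 1, constant_values=0)
    stacked = np.stack(
        [
            padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        ]
    )
    bmask = boundary_mask(mask)
    neigh = stacked[:, bmask]
    other = (neigh != 0) & (neigh != target_label)
    touching = np.unique(neigh[other])
    shared_px = int(other.any(axis=0).sum())
    n_boundary = int(bmask.sum())

    others = [lab for lab in centroids if lab != target_label]
    out: dict[str, float] = {
        "ctx_neighbor_count": float(len(touching)),
        "ctx_shared_boundary_pct": 100.0 * shared_px / n_boundary if n_boundary else 0.0,
        "ctx_shared_boundary_um": shared_px * px,
    }
    if not others:
        out.update(
            {
                "ctx_nn1_dist": float("nan"),
                "ctx_nn2_dist": float("nan"),
                "ctx_nn3_dist": float("nan"),
                "ctx_nn_mean3": float("nan"),
                "ctx_inv_dist_sum": 0.0,
                "ctx_nn1_area_ratio": float("nan"),
            }
        )
        for r in CONTEXT_DENSITY_RADII_UM:
            out[f"ctx_density_r{int(r)}"] = 0.0
        return out

    c0 = centroids[target_label]
    dists = np.array(
        [np.sqrt(((centroids[lab] - c0) ** 2).sum()) * px for lab in others]
    )
    order = np.argsort(dists)
    sorted_d = dists[order]
    nn = [float(sorted_d[i]) if i < len(sorted_d) else float("nan") for i in range(3)]
    finite = [v for v in nn if not math.isnan(v)]
    out["ctx_nn1_dist"], out["ctx_nn2_dist"], out["ctx_nn3_dist"] = nn
    out["ctx_nn_mean3"] = float(np.mean(finite)) if finite else float("nan")
    for r in CONTEXT_DENSITY_RADII_UM:
        out[f"ctx_density_r{int(r)}"] = float((dists <= r).sum())
    out["ctx_inv_dist_sum"] = float((1.0 / dists[dists > 0]).sum())
    nn1_lab = others[int(order[0])]
    out["ctx_nn1_area_ratio"] = areas[nn1_lab] / areas[target_label]
    return out


def scene_centroids_and_areas(
    labels: np.ndarray,
) -> tuple[dict[int, np.ndarray], dict[int, int]]:
    centroids: dict[int, np.ndarray] = {}
    areas: dict[int, int] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rr, cc = np.nonzero(labels == lab)
        centroids[int(lab)] = np.array([rr.mean(), cc.mean()])
        areas[int(lab)] = len(rr)
    return centroids, areas


# ---------------------------------------------------------------------------
# per-cell assembly
# ---------------------------------------------------------------------------

def profile_cell(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size_um: float,
    channels: dict[str, np.ndarray] | None = None,
    marker_channels: tuple[str, ...] = (),
) -> dict[str, float]:
    """All catalogue features of one cell (morphology block + marker blocks).

    ``cell_mask``/``nucleus_mask`` are boolean arrays over the same grid;
    marker channels are looked up in ``channels`` by lower-case name.
    """
    cell_mask = np.asarray(cell_mask, bool)
    nucleus_mask = np.asarray(nucleus_mask, bool) & cell_mask
    cyto_mask = cell_mask & ~nucleus_mask
    px = float(pixel_size_um)

    cell_boundary = boundary_mask(cell_mask)
    cell_perim_px = perimeter_crofton4(cell_mask)

    feats: dict[str, float] = {}
    cell_f = shape_features(cell_mask, px)
    nuc_f = shape_features(nucleus_mask, px)
    cyto_f = shape_features(
        cyto_mask, px, boundary=cell_boundary, perimeter_px=cell_perim_px
    )
    for obj, f in (("cell", cell_f), ("nucleus", nuc_f), ("cyto", cyto_f)):
        for k, v in f.items():
            feats[f"{obj}_{k}"] = v
    feats.update(zernike_magnitudes(cell_mask))

    cell_coords = _pixel_coords(cell_mask)
    nuc_coords = _pixel_coords(nucleus_mask)
    feats["ncr"] = ncr(nuc_f["area"], cyto_f["area"])
    feats["polarity"] = polarity(cell_coords.mean(axis=0), nuc_coords.mean(axis=0), px)
    feats["nucleus_cell_area_ratio"] = nuc_f["area"] / cell_f["area"]
    feats["cytoplasm_area_fraction"] = cyto_f["area"] / cell_f["area"]
    feats["cell_perimeter_area_ratio"] = cell_f["perimeter"] / cell_f["area"]

    if channels is not None:
        for ch_name in marker_channels:
            ch = channels[ch_name]
            block = intensity_features(
                cell_mask,
                ch,
                px,
                boundary=cell_boundary,
                perimeter_um=cell_perim_px * px,
            )
            block.update(radial_distribution(cell_mask, ch))
            block.update(texture_features(cell_mask, ch))
            for k, v in block.items():
                feats[f"{ch_name}_{k}"] = v
        if "ck" in marker_channels and "vim" in marker_channels:
            feats.update(
                cross_channel_features(cell_mask, channels["ck"], channels["vim"], px)
            )
    return feats


def assemble_table(
    rows: list[dict[str, float]],
    metadata: list[dict],
    staining_group: str,
) -> pd.DataFrame:
    """Build a FeatureTable and enforce the catalogue count contract.

    Raises if any row deviates from the expected 150 (+69/+140) columns; this
    guards against silent catalogue drift.  Zero-variance columns are *not*
    dropped here (that happens at the analysis/z-scoring stage).
    """
    catalog.validate_catalog()
    expected = catalog.morphology_feature_names() + catalog.staining_feature_names(
        staining_group
    )
    if rows:
        for r in rows:
            missing = set(expected) - set(r)
            extra = set(r) - set(expected)
            if missing or extra:
                raise AssertionError(
                    f"catalogue mismatch: missing={sorted(missing)[:5]} "
                    f"extra={sorted(extra)[:5]}"
                )
    table = pd.DataFrame(
        [{**m, **{k: r[k] for k in expected}} for m, r in zip(metadata, rows)],
        columns=list(catalog.METADATA_COLUMNS) + expected,
    )
    return table
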