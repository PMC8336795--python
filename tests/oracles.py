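"""Independent brute-force oracles for the feature definitions.

Everything here is computed by direct pixel enumeration (plain Python loops
over pixel lists), re-deriving each documented convention from scratch:
4-connected boundary, 4-direction Crofton perimeter via explicit transition
counting per line, corner-point convex hull via a hand-written monotone
chain, point-mass moments, explicit Zernike radial sums, per-pair GLCM
accumulation, and O(n^2) rank/distance statistics.  These oracles are the
reference the vectorised implementations are tested against.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# geometry oracles
# ---------------------------------------------------------------------------

def boundary_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, bool)
    out = []
    H, W = m.shape
    for r in range(H):
        for c in range(W):
            if not m[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if rr < 0 or rr >= H or cc < 0 or cc >= W or not m[rr, cc]:
                    out.append((r, c))
                    break
    return out


def crofton_perimeter(mask: np.ndarray) -> float:
    """Count 0<->1 transitions along rows, columns and both diagonals."""
    m = np.pad(np.asarray(mask, bool), 1, constant_values=False).astype(int)
    H, W = m.shape
    c_h = sum(
        1 for r in range(H) for c in range(W - 1) if m[r, c] != m[r, c + 1]
    )
    c_v = sum(
        1 for r in range(H - 1) for c in range(W) if m[r, c] != m[r + 1, c]
    )
    c_d1 = sum(
        1
        for r in range(H - 1)
        for c in range(W - 1)
        if m[r, c] != m[r + 1, c + 1]
    )
    c_d2 = sum(
        1
        for r in range(H - 1)
        for c in range(1, W)
        if m[r, c] != m[r + 1, c - 1]
    )
    return math.pi / 8.0 * (c_h + c_v + (c_d1 + c_d2) / math.sqrt(2.0))


def monotone_chain_hull(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def hull_of_mask(mask: np.ndarray) -> list[tuple[float, float]]:
    corners = []
    for r, c in boundary_pixels(mask):
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                corners.append((r + dr, c + dc))
    return monotone_chain_hull(corners)


def polygon_area(poly: list[tuple[float, float]]) -> float:
    s = 0.0
    for i in range(len(poly)):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % len(poly)]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def polygon_perimeter(poly: list[tuple[float, float]]) -> float:
    return sum(
        math.dist(poly[i], poly[(i + 1) % len(poly)]) for i in range(len(poly))
    )


def feret_extremes(poly: list[tuple[float, float]]) -> tuple[float, float]:
    fmax = 0.0
    for i in range(len(poly)):
        for j in range(i + 1, len(poly)):
            fmax = max(fmax, math.dist(poly[i], poly[j]))
    fmin = math.inf
    for i in range(len(poly)):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % len(poly)]
        ex, ey = x1 - x0, y1 - y0
        norm = math.hypot(ex, ey)
        nx, ny = -ey / norm, ex / norm
        projs = [p[0] * nx + p[1] * ny for p in poly]
        fmin = min(fmin, max(projs) - min(projs))
    return fmax, fmin


def shape_oracle(
    mask: np.ndarray,
    px: float,
    boundary: np.ndarray | None = None,
    perimeter_px: float | None = None,
) -> dict[str, float]:
    m = np.asarray(mask, bool)
    pix = [(r, c) for r in range(m.shape[0]) for c in range(m.shape[1]) if m[r, c]]
    n = len(pix)
    cr = sum(p[0] for p in pix) / n
    cc = sum(p[1] for p in pix) / n
    mu20 = sum((p[0] - cr) ** 2 for p in pix) / n
    mu02 = sum((p[1] - cc) ** 2 for p in pix) / n
    mu11 = sum((p[0] - cr) * (p[1] - cc) for p in pix) / n
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = max((mu20 + mu02 - common) / 2, 0.0)
    ecc = math.sqrt(1 - lam2 / lam1) if lam1 > 0 else 0.0
    major, minor = 4 * math.sqrt(lam1), 4 * math.sqrt(lam2)
    orientation = 0.5 * math.atan2(2 * mu11, mu20 - mu02)

    area = n * px**2
    per_px = crofton_perimeter(m) if perimeter_px is None else perimeter_px
    perimeter = per_px * px

    if boundary is None:
        bpix = boundary_pixels(m)
    else:
        b = np.asarray(boundary, bool)
        bpix = [(r, c) for r in range(b.shape[0]) for c in range(b.shape[1]) if b[r, c]]
    radii = [math.hypot(p[0] - cr, p[1] - cc) * px for p in bpix]
    r_mean = sum(radii) / len(radii)
    r_sd = math.sqrt(sum((r - r_mean) ** 2 for r in radii) / len(radii))

    hull = hull_of_mask(m)
    hull_area = polygon_area(hull)
    hull_per = polygon_perimeter(hull)
    fmax, fmin = feret_extremes(hull)

    rows = [p[0] for p in pix]
    cols = [p[1] for p in pix]
    bh = max(rows) - min(rows) + 1
    bw = max(cols) - min(cols) + 1

    def mu(p, q):
        return sum((x - cr) ** p * (y - cc) ** q for x, y in pix)

    def eta(p, q):
        return mu(p, q) / n ** (1 + (p + q) / 2)

    e20, e02, e11 = eta(2, 0), eta(0, 2), eta(1, 1)
    e30, e03, e21, e12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    hu_raw = [
        e20 + e02,
        (e20 - e02) ** 2 + 4 * e11**2,
        (e30 - 3 * e12) ** 2 + (3 * e21 - e03) ** 2,
        (e30 + e12) ** 2 + (e21 + e03) ** 2,
        (e30 - 3 * e12) * (e30 + e12) * ((e30 + e12) ** 2 - 3 * (e21 + e03) ** 2)
        + (3 * e21 - e03) * (e21 + e03) * (3 * (e30 + e12) ** 2 - (e21 + e03) ** 2),
        (e20 - e02) * ((e30 + e12) ** 2 - (e21 + e03) ** 2)
        + 4 * e11 * (e30 + e12) * (e21 + e03),
        (3 * e21 - e03) * (e30 + e12) * ((e30 + e12) ** 2 - 3 * (e21 + e03) ** 2)
        - (e30 - 3 * e12) * (e21 + e03) * (3 * (e30 + e12) ** 2 - (e21 + e03) ** 2),
    ]
    # signed-log scale, matching the documented feature definition
    hu = [0.0 if h == 0 else -math.copysign(1.0, h) * math.log10(abs(h)) for h in hu_raw]

    sorted_r = sorted(radii)
    mid = len(sorted_r) // 2
    r_med = (
        sorted_r[mid]
        if len(sorted_r) % 2
        else (sorted_r[mid - 1] + sorted_r[mid]) / 2
    )
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": 4 * math.pi * area / perimeter**2,
        "compactness": perimeter**2 / (4 * math.pi * area),
        "roundness": 4 * n / (math.pi * major**2) if major > 0 else 0.0,
        "eccentricity": ecc,
        "solidity": n / hull_area,
        "extent": n / (bh * bw),
        "major_axis_length": major * px,
        "minor_axis_length": minor * px,
        "aspect_ratio": major / minor if minor > 0 else 0.0,
        "equivalent_diameter": 2 * math.sqrt(area / math.pi),
        "feret_max": fmax * px,
        "feret_min": fmin * px,
        "feret_ratio": fmin / fmax,
        "orientation": orientation,
        "radius_mean": r_mean,
        "radius_median": r_med,
        "radius_max": max(radii),
        "radius_min": min(radii),
        "radius_sd": r_sd,
        "radius_cv": r_sd / r_mean if r_mean > 0 else 0.0,
        "convex_area": hull_area * px**2,
        "convex_perimeter": hull_per * px,
        "convexity": hull_per / per_px,
        "bbox_height": bh * px,
        "bbox_width": bw * px,
        "bbox_aspect": max(bh, bw) / min(bh, bw),
        **{f"hu{i+1}": hu[i] for i in range(7)},
    }


def zernike_oracle(mask: np.ndarray, orders) -> dict[str, float]:
    m = np.asarray(mask, bool)
    pix = [(r, c) for r in range(m.shape[0]) for c in range(m.shape[1]) if m[r, c]]
    n_pix = len(pix)
    cr = sum(p[0] for p in pix) / n_pix
    cc = sum(p[1] for p in pix) / n_pix
    bpix = boundary_pixels(m)
    r_max = max(math.hypot(p[0] - cr, p[1] - cc) for p in bpix) or 1.0

    def radial(n, mm, rho):
        s = 0.0
        for k in range((n - mm) // 2 + 1):
            s += (
                (-1) ** k
                * math.factorial(n - k)
                / (
                    math.factorial(k)
                    * math.factorial((n + mm) // 2 - k)
                    * math.factorial((n - mm) // 2 - k)
                )
            ) * rho ** (n - 2 * k)
        return s

    out = {}
    for n, mm in orders:
        re = im = 0.0
        for r, c in pix:
            dy, dx = r - cr, c - cc
            rho = min(math.hypot(dy, dx) / r_max, 1.0)
            phi = math.atan2(dx, dy)
            rad = radial(n, mm, rho)
            re += rad * math.cos(mm * phi)
            im -= rad * math.sin(mm * phi)
        re /= n_pix
        im /= n_pix
        out[f"cell_zernike_{n}_{mm}"] = (n + 1) / math.pi * math.hypot(re, im)
    return out


# ---------------------------------------------------------------------------
# intensity / texture oracles
# ---------------------------------------------------------------------------

def intensity_oracle(
    mask: np.ndarray, channel: np.ndarray, px: float,
    boundary: np.ndarray | None = None, perimeter_um: float | None = None,
) -> dict[str, float]:
    m = np.asarray(mask, bool)
    ch = np.asarray(channel, float)
    pix = [(r, c) for r in range(m.shape[0]) for c in range(m.shape[1]) if m[r, c]]
    vals = [ch[r, c] for r, c in pix]
    n = len(vals)
    total = sum(vals)
    mean_px = total / n
    var = sum((v - mean_px) ** 2 for v in vals) / n
    std = math.sqrt(var)

    if boundary is None:
        bpix = boundary_pixels(m)
    else:
        b = np.asarray(boundary, bool)
        bpix = [(r, c) for r in range(b.shape[0]) for c in range(b.shape[1]) if b[r, c]]
    bvals = [ch[r, c] for r, c in bpix]
    edge_total = sum(bvals)
    perim = crofton_perimeter(m) * px if perimeter_um is None else perimeter_um

    def percentile(sorted_v, q):
        # numpy 'linear' convention
        idx = (len(sorted_v) - 1) * q / 100.0
        lo = int(math.floor(idx))
        hi = int(math.ceil(idx))
        frac = idx - lo
        return sorted_v[lo] * (1 - frac) + sorted_v[hi] * frac

    sv = sorted(vals)
    med = percentile(sv, 50)
    q1, q3 = percentile(sv, 25), percentile(sv, 75)
    p10, p90 = percentile(sv, 10), percentile(sv, 90)
    mad = percentile(sorted(abs(v - med) for v in vals), 50)
    m3 = sum((v - mean_px) ** 3 for v in vals) / n
    m4 = sum((v - mean_px) ** 4 for v in vals) / n
    skew = m3 / var**1.5 if var > 0 else 0.0
    kurt = m4 / var**2 - 3 if var > 0 else 0.0
    k = max(int(math.ceil(0.1 * n)), 1)
    top10 = sum(sv[-k:]) / total if total > 0 else 0.0

    cr = sum(p[0] for p in pix) / n
    cc = sum(p[1] for p in pix) / n
    if total > 0:
        wr = sum(p[0] * ch[p[0], p[1]] for p in pix) / total
        wc = sum(p[1] * ch[p[0], p[1]] for p in pix) / total
        mass = math.hypot(wr - cr, wc - cc) * px
    else:
        mass = 0.0
    r_max = max(math.hypot(p[0] - cr, p[1] - cc) for p in bpix) * px

    n_edge = len(bvals)
    bs = sorted(bvals)
    interior_n = max(n - n_edge, 1)
    interior_mean = (total - edge_total) / interior_n
    bmean = edge_total / n_edge
    bvar = sum((v - bmean) ** 2 for v in bvals) / n_edge
    return {
        "integrated": total,
        "mean": total / (n * px**2),
        "std": std,
        "cv": std / mean_px if mean_px > 0 else 0.0,
        "min": min(vals),
        "p10": p10,
        "q1": q1,
        "median": med,
        "q3": q3,
        "p90": p90,
        "max": max(vals),
        "iqr": q3 - q1,
        "range": max(vals) - min(vals),
        "mad": mad,
        "skewness": skew,
        "kurtosis": kurt,
        "top10_mass_frac": top10,
        "edge_integrated": edge_total,
        "edge_mean_px": edge_total / n_edge,
        "mean_edge_intensity": edge_total / perim if perim > 0 else 0.0,
        "edge_std": math.sqrt(bvar),
        "edge_min": min(bvals),
        "edge_max": max(bvals),
        "edge_median": percentile(bs, 50),
        "edge_fraction": 100.0 * edge_total / total if total > 0 else float("nan"),
        "edge_interior_ratio": bmean / interior_mean if interior_mean > 0 else 0.0,
        "mass_displacement_um": mass,
        "mass_displacement_norm": mass / r_max if r_max > 0 else 0.0,
    }


def radial_oracle(mask: np.ndarray, channel: np.ndarray, n_bins: int = 5) -> dict[str, float]:
    m = np.asarray(mask, bool)
    ch = np.asarray(channel, float)
    pix = [(r, c) for r in range(m.shape[0]) for c in range(m.shape[1]) if m[r, c]]
    n = len(pix)
    cr = sum(p[0] for p in pix) / n
    cc = sum(p[1] for p in pix) / n
    bpix = boundary_pixels(m)
    r_max = max(math.hypot(p[0] - cr, p[1] - cc) for p in bpix) or 1.0
    vals = [ch[r, c] for r, c in pix]
    total = sum(vals)
    overall_mean = total / n
    bins: dict[int, list[float]] = {b: [] for b in range(n_bins)}
    for (r, c), v in zip(pix, vals):
        b = min(int(math.hypot(r - cr, c - cc) / r_max * n_bins), n_bins - 1)
        bins[b].append(v)
    out = {}
    for b in range(n_bins):
        sel = bins[b]
        if not sel or total <= 0:
            frac = meanfrac = cv = 0.0
        else:
            s = sum(sel)
            frac = s / total
            bm = s / len(sel)
            meanfrac = bm / overall_mean if overall_mean > 0 else 0.0
            bv = sum((v - bm) ** 2 for v in sel) / len(sel)
            cv = math.sqrt(bv) / bm if bm > 0 else 0.0
        out[f"radial_frac_b{b+1}"] = frac
        out[f"radial_meanfrac_b{b+1}"] = meanfrac
        out[f"radial_cv_b{b+1}"] = cv
    return out


def glcm_oracle(
    mask: np.ndarray, channel: np.ndarray, offset: tuple[int, int], n_levels: int = 64
) -> np.ndarray:
    m = np.asarray(mask, bool)
    ch = np.asarray(channel, float)
    vals = [ch[r, c] for r in range(m.shape[0]) for c in range(m.shape[1]) if m[r, c]]
    vmin, vmax = min(vals), max(vals)

    def level(v):
        if vmax == vmin:
            return 0
        return min(int((v - vmin) / (vmax - vmin) * n_levels), n_levels - 1)

    p = np.zeros((n_levels, n_levels))
    dr, dc = offset
    H, W = m.shape
    for r in range(H):
        for c in range(W):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and m[r, c] and m[rr, cc]:
                a, b = level(ch[r, c]), level(ch[rr, cc])
                p[a, b] += 1
                p[b, a] += 1
    s = p.sum()
    return p / s if s > 0 else p


def haralick_oracle(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    px_ = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py_ = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px_[i] for i in range(n))
    mu_y = sum(j * py_[j] for j in range(n))
    var_x = sum((i - mu_x) ** 2 * px_[i] for i in range(n))
    var_y = sum((j - mu_y) ** 2 * py_[j] for j in range(n))

    asm = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    corr = (
        (sum(i * j * p[i, j] for i in range(n) for j in range(n)) - mu_x * mu_y)
        / math.sqrt(var_x * var_y)
        if var_x > 0 and var_y > 0
        else 0.0
    )
    variance = sum((i - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    sum_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    sum_entropy = -sum(v * math.log(v) for v in p_sum if v > 0)
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    diff_avg = sum(k * p_diff[k] for k in range(n))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(n))
    diff_entropy = -sum(v * math.log(v) for v in p_diff if v > 0)
    entropy = -sum(
        p[i, j] * math.log(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
    )
    hx = -sum(v * math.log(v) for v in px_ if v > 0)
    hy = -sum(v * math.log(v) for v in py_ if v > 0)
    hxy1 = -sum(
        p[i, j] * math.log(px_[i] * py_[j])
        for i in range(n)
        for j in range(n)
        if px_[i] * py_[j] > 0 and p[i, j] > 0
    )
    hxy2 = -sum(
        px_[i] * py_[j] * math.log(px_[i] * py_[j])
        for i in range(n)
        for j in range(n)
        if px_[i] * py_[j] > 0
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(1 - math.exp(-2 * (hxy2 - entropy)), 0.0))
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
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


# ---------------------------------------------------------------------------
# context oracle
# ---------------------------------------------------------------------------

def context_oracle(labels: np.ndarray, target: int, px: float, density_radii) -> dict[str, float]:
    labels = np.asarray(labels)
    H, W = labels.shape
    cells: dict[int, list[tuple[int, int]]] = {}
    for r in range(H):
        for c in range(W):
            if labels[r, c]:
                cells.setdefault(int(labels[r, c]), []).append((r, c))
    bpix = boundary_pixels(labels == target)
    shared = 0
    touch_ids = set()
    for r, c in bpix:
        near = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and labels[rr, cc] not in (0, target):
                    near.add(int(labels[rr, cc]))
        if near:
            shared += 1
            touch_ids |= near
    cent = {
        k: (sum(p[0] for p in v) / len(v), sum(p[1] for p in v) / len(v))
        for k, v in cells.items()
    }
    others = [k for k in cells if k != target]
    dists = sorted(
        (math.dist(cent[k], cent[target]) * px, k) for k in others
    )
    out = {
        "ctx_neighbor_count": float(len(touch_ids)),
        "ctx_shared_boundary_pct": 100.0 * shared / len(bpix),
        "ctx_shared_boundary_um": shared * px,
    }
    nn = [dists[i][0] if i < len(dists) else float("nan") for i in range(3)]
    out["ctx_nn1_dist"], out["ctx_nn2_dist"], out["ctx_nn3_dist"] = nn
    finite = [v for v in nn if not math.isnan(v)]
    out["ctx_nn_mean3"] = sum(finite) / len(finite) if finite else float("nan")
    for rad in density_radii:
        out[f"ctx_density_r{int(rad)}"] = float(sum(1 for d, _ in dists if d <= rad))
    out["ctx_inv_dist_sum"] = sum(1.0 / d for d, _ in dists if d > 0)
    if dists:
        out["ctx_nn1_area_ratio"] = len(cells[dists[0][1]]) / len(cells[target])
    else:
        out["ctx_nn1_area_ratio"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def midranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    rx, ry = midranks(x), midranks(y)
    return pearson_oracle(rx, ry)


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def kendall_oracle(x, y) -> float:
    """Tau-b with tie correction, by explicit pair enumeration."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


def dcor_oracle(x, y) -> float:
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(mat):
        row = [sum(mat[i]) / n for i in range(n)]
        col = [sum(mat[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [
            [mat[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)
        ]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvx * dvy))


def welch_oracle(a, b) -> tuple[float, float, float]:
    """(t, df, two-sided p) by the explicit Welch-Satterthwaite formulas."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def silhouette_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    svals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            svals.append(0.0)
            continue
        a = sum(math.dist(X[i], X[j]) for j in same) / len(same)
        b = math.inf
        for lab in set(labels.tolist()) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            b = min(b, sum(math.dist(X[i], X[j]) for j in other) / len(other))
        svals.append((b - a) / max(a, b))
    return sum(svals) / n


def davies_bouldin_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    labs = sorted(set(labels.tolist()))
    cents = {
        lab: X[labels == lab].mean(axis=0) for lab in labs
    }
    scatter = {
        lab: np.mean(
            [math.dist(x, cents[lab]) for x in X[labels == lab]]
        )
        for lab in labs
    }
    total = 0.0
    for i in labs:
        worst = 0.0
        for j in labs:
            if i == j:
                continue
            ratio = (scatter[i] + scatter[j]) / math.dist(cents[i], cents[j])
            worst = max(worst, ratio)
        total += worst
    return total / len(labs)


def ward_merge_order(X: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """Exhaustive Ward agglomeration: at each step merge the pair of clusters
    whose union minimises the increase in within-cluster sum of squares."""
    X = np.asarray(X, float)
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(X))]

    def ess(idx: frozenset) -> float:
        pts = X[list(idx)]
        cent = pts.mean(axis=0)
        return float(((pts - cent) ** 2).sum())

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                inc = ess(clusters[i] | clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                if best is None or inc < best[0]:
                    best = (inc, i, j)
        _, i, j = best
        merges.append((clusters[i], clusters[j]))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges
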