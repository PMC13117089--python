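"""Independent brute-force reference implementations used by the tests.

Everything here is written as explicit loops / exhaustive search so it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def median_filter_loop(img: np.ndarray, k: int) -> np.ndarray:
    """Per-pixel sort-and-middle median with edge replication."""
    pad = k // 2
    padded = np.pad(img, pad, mode="edge")
    out = np.empty_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            window = padded[r : r + k, c : c + k].ravel()
            out[r, c] = np.sort(window)[window.size // 2]
    return out


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def opening_loop(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a disk: erosion then dilation, explicit loops.

    Out-of-bounds neighbors are ignored (same effective border handling
    as reflecting an infinite-height border for min/max with finite
    support restricted to the image domain)."""
    h, w = img.shape
    offs = disk_offsets(radius)
    eroded = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            vals = [
                img[r + dr, c + dc]
                for dr, dc in offs
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            eroded[r, c] = min(vals)
    dilated = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            vals = [
                eroded[r + dr, c + dc]
                for dr, dc in offs
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            dilated[r, c] = max(vals)
    return dilated


def percentile_sorted(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile from first principles."""
    s = np.sort(np.asarray(values, dtype=float).ravel())
    idx = q / 100.0 * (s.size - 1)
    lo = int(np.floor(idx))
    hi = int(np.ceil(idx))
    frac = idx - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def regional_maxima_loop(img: np.ndarray) -> np.ndarray:
    """Exhaustive plateau search for regional maxima (8-connectivity)."""
    h, w = img.shape
    out = np.zeros((h, w), dtype=bool)
    visited = np.zeros((h, w), dtype=bool)
    for r0 in range(h):
        for c0 in range(w):
            if visited[r0, c0]:
                continue
            level = img[r0, c0]
            # flood the connected plateau at this level
            stack = [(r0, c0)]
            plateau = []
            seen = set()
            is_max = True
            while stack:
                r, c = stack.pop()
                if (r, c) in seen:
                    continue
                seen.add((r, c))
                plateau.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w):
                            continue
                        if img[rr, cc] == level:
                            if (rr, cc) not in seen:
                                stack.append((rr, cc))
                        elif img[rr, cc] > level:
                            is_max = False
            for r, c in plateau:
                visited[r, c] = True
                out[r, c] = is_max
    return out


def convex_hull_rasterized_area(coords: np.ndarray) -> float:
    """Count of pixel centers inside/on the convex hull of pixel centers."""
    from matplotlib.path import Path as MplPath
    from scipy.spatial import ConvexHull, QhullError

    pts = np.asarray(coords, dtype=float)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return float(len(pts))  # collinear: hull degenerates to the pixels
    poly = MplPath(pts[hull.vertices])
    r0, c0 = pts.min(axis=0).astype(int)
    r1, c1 = pts.max(axis=0).astype(int)
    grid = np.array(
        [(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)], dtype=float
    )
    inside = poly.contains_points(grid, radius=1e-9) | poly.contains_points(
        grid, radius=-1e-9
    )
    return float(inside.sum())


def ellipse_axes_from_moments(coords: np.ndarray) -> tuple[float, float, float]:
    """(major, minor, eccentricity) of the moment-equivalent ellipse.

    Second central moments computed by explicit summation over pixel
    centers (no sub-pixel correction), eigenvalues by the closed form.
    """
    pts = np.asarray(coords, dtype=float)
    mean = pts.mean(axis=0)
    d = pts - mean
    mrr = (d[:, 0] ** 2).mean()
    mcc = (d[:, 1] ** 2).mean()
    mrc = (d[:, 0] * d[:, 1]).mean()
    common = np.sqrt((mrr - mcc) ** 2 + 4 * mrc**2)
    l1 = (mrr + mcc + common) / 2.0
    l2 = (mrr + mcc - common) / 2.0
    major = 4.0 * np.sqrt(l1)
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    ecc = np.sqrt(1.0 - l2 / l1) if l1 > 0 else 0.0
    return major, minor, ecc


def point_to_line_dense(
    o: tuple[float, float],
    a: tuple[float, float],
    b: tuple[float, float],
    n: int = 2_000_001,
    span: float = 100.0,
) -> float:
    """Minimum distance from o to the (extended) line AB by dense sampling."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    direction = (b - a) / np.linalg.norm(b - a)
    t = np.linspace(-span, span, n)
    pts = a[None, :] + t[:, None] * direction[None, :]
    d2 = (pts[:, 0] - o[0]) ** 2 + (pts[:, 1] - o[1]) ** 2
    return float(np.sqrt(d2.min()))


def shadow_score_loop(
    pc: np.ndarray, pl: np.ndarray, rho: float
) -> float:
    """Loop-and-sort re-implementation of the shadow-region statistic."""
    n = len(pc)
    diff_sum = 0.0
    for i in range(n):
        diff_sum += pl[i] - pc[i]
    term1 = diff_sum / n
    diffs = [pc[i + 1] - pc[i] for i in range(n - 1)]
    if not diffs:
        return term1
    i_drop = min(range(len(diffs)), key=lambda i: (diffs[i], i))
    later = list(range(i_drop + 1, len(diffs)))
    if not later:
        return term1
    i_rise = min(later, key=lambda i: (-diffs[i], i))
    pce = sorted(pc[: i_drop + 1])
    pcl = sorted(pc[i_drop + 1 : i_rise + 1])
    if not pcl:
        return term1

    def med(xs: list[float]) -> float:
        m = len(xs)
        return xs[m // 2] if m % 2 else (xs[m // 2 - 1] + xs[m // 2]) / 2.0

    return term1 + rho * (med(pce) - med(pcl))


def icc2_anova(obs1: list[float], obs2: list[float]) -> float:
    """ICC(2,1) from two-way ANOVA mean squares, explicit formulas."""
    y = np.array([obs1, obs2], dtype=float)  # raters x subjects
    k, n = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=0)
    rater_means = y.mean(axis=1)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
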