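"""Naive reference implementations used as independent oracles.

Deliberately brute force — explicit Python loops over pixels, direct box
counting, direct polyline sums — and kept free of any production code path so
agreement with :mod:`vesselmetrics.metrics` is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def vd_naive(mask: np.ndarray, zone: np.ndarray) -> float:
    v = n = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if zone[r, c]:
                n += 1
                if mask[r, c]:
                    v += 1
    return float("nan") if n == 0 else v / n


def vdi_naive(mask: np.ndarray, skeleton: np.ndarray, zone: np.ndarray) -> float:
    v = s = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if zone[r, c]:
                if mask[r, c]:
                    v += 1
                if skeleton[r, c]:
                    s += 1
    return float("nan") if s == 0 else v / s


def vlf_naive(skeleton: np.ndarray, zone: np.ndarray) -> float:
    s = n = 0
    for r in range(skeleton.shape[0]):
        for c in range(skeleton.shape[1]):
            if zone[r, c]:
                n += 1
                if skeleton[r, c]:
                    s += 1
    return float("nan") if n == 0 else s / n


def fd_naive(skeleton: np.ndarray, zone: np.ndarray | None = None, min_box: int = 2) -> float:
    pts = []
    for r in range(skeleton.shape[0]):
        for c in range(skeleton.shape[1]):
            if skeleton[r, c] and (zone is None or zone[r, c]):
                pts.append((r, c))
    if not pts:
        return float("nan")
    r0 = min(p[0] for p in pts)
    c0 = min(p[1] for p in pts)
    max_box = min(skeleton.shape) // 4
    sizes, counts = [], []
    eps = min_box
    while eps <= max_box:
        boxes = set()
        for r, c in pts:
            boxes.add(((r - r0) // eps, (c - c0) // eps))
        if len(boxes) >= 2:
            sizes.append(eps)
            counts.append(len(boxes))
        eps *= 2
    if len(sizes) < 2:
        return float("nan")
    # ordinary least squares by hand
    lx = [math.log(s) for s in sizes]
    ly = [math.log(n) for n in counts]
    mx = sum(lx) / len(lx)
    my = sum(ly) / len(ly)
    slope = sum((a - mx) * (b - my) for a, b in zip(lx, ly)) / sum((a - mx) ** 2 for a in lx)
    return -slope


def lc_naive(points) -> float:
    total = 0.0
    for i in range(len(points) - 1):
        total += math.dist(tuple(points[i]), tuple(points[i + 1]))
    return total


def lx_naive(points) -> float:
    return math.dist(tuple(points[0]), tuple(points[-1]))


def mdac_naive(points, step: int) -> float:
    n = len(points)
    if n < 2 * step + 1:
        return float("nan")
    angles = []
    for i in range(step, n - step):
        ax = points[i][0] - points[i - step][0]
        ay = points[i][1] - points[i - step][1]
        bx = points[i + step][0] - points[i][0]
        by = points[i + step][1] - points[i][1]
        na = math.hypot(ax, ay)
        nb = math.hypot(bx, by)
        if na == 0 or nb == 0:
            continue
        cosv = max(-1.0, min(1.0, (ax * bx + ay * by) / (na * nb)))
        angles.append(math.acos(cosv))
    return sum(angles) / len(angles) if angles else float("nan")


def kruskal_naive(groups) -> float:
    """H statistic with tie correction via explicit midranks."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[k] = mid
        i = j
    rank_sum = [0.0] * len(groups)
    for (v, gi), rk in zip(pooled, ranks):
        rank_sum[gi] += rk
    h = 12.0 / (n * (n + 1)) * sum(
        rs**2 / len(g) for rs, g in zip(rank_sum, groups)
    ) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    correction = 1 - ties / (n**3 - n)
    return h / correction
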