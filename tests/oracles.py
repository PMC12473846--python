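"""Independent brute-force oracles.

Every function here is a deliberately naive nested-loop re-derivation of an
operator, written directly from its defining formula and kept free of any
code shared with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def _edge(img, r, c):
    h, w = img.shape
    return img[min(max(r, 0), h - 1), min(max(c, 0), w - 1)]


def bilateral_bf(img, diameter, sigma_s, sigma_r):
    h, w = img.shape
    rad = diameter // 2
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            num = den = 0.0
            center = float(img[r, c])
            for dr in range(-rad, rad + 1):
                for dc in range(-rad, rad + 1):
                    v = float(_edge(img, r + dr, c + dc))
                    ws = math.exp(-(dr * dr + dc * dc) / (2 * sigma_s**2))
                    wr = math.exp(-((v - center) ** 2) / (2 * sigma_r**2))
                    num += ws * wr * v
                    den += ws * wr
            out[r, c] = num / den
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)


def gaussian_bf(img, kernel):
    h, w = img.shape
    k = kernel.shape[0] // 2
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            s = 0.0
            for dr in range(-k, k + 1):
                for dc in range(-k, k + 1):
                    s += kernel[dr + k, dc + k] * float(_edge(img, r + dr, c + dc))
            out[r, c] = s
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)


def dilate_bf(img, ksize):
    h, w = img.shape
    rad = ksize // 2
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            m = 0
            for dr in range(-rad, rad + 1):
                for dc in range(-rad, rad + 1):
                    m = max(m, int(_edge(img, r + dr, c + dc)))
            out[r, c] = m
    return out


def threshold_bf(img, thr, i_max):
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            out[r, c] = i_max if img[r, c] > thr else 0
    return out


def absdiff_bf(a, b):
    h, w = a.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            out[r, c] = abs(int(a[r, c]) - int(b[r, c]))
    return out


def sobel_bf(img):
    gx_mask = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    gy_mask = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]
    h, w = img.shape
    mag = np.zeros((h, w))
    direction = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            gx = gy = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    v = float(_edge(img, r + dr, c + dc))
                    gx += gx_mask[dr + 1][dc + 1] * v
                    gy += gy_mask[dr + 1][dc + 1] * v
            mag[r, c] = math.hypot(gx, gy)
            theta = math.degrees(math.atan2(gy, gx)) % 180.0
            best, best_d = 0, 999.0
            for ori in (0, 45, 90, 135):
                d = abs(theta - ori)
                d = min(d, 180.0 - d)
                if round(d, 9) < round(best_d, 9):
                    best, best_d = ori, d
            direction[r, c] = best
    return mag, direction


def nms_bf(mag, direction):
    steps = {0: (0, 1), 45: (-1, 1), 90: (1, 0), 135: (1, 1)}
    h, w = mag.shape
    out = np.zeros_like(mag)
    for r in range(h):
        for c in range(w):
            dr, dc = steps[int(direction[r, c])]
            neighbors = []
            for s in (1, -1):
                rr, cc = r + s * dr, c + s * dc
                neighbors.append(mag[rr, cc] if 0 <= rr < h and 0 <= cc < w else 0.0)
            if mag[r, c] >= neighbors[0] and mag[r, c] >= neighbors[1]:
                out[r, c] = mag[r, c]
    return out


def hysteresis_bf(mag, low, high):
    """Flood fill from strong seeds through 8-connected weak/strong pixels."""
    h, w = mag.shape
    strong = mag > high
    cand = mag > low
    out = np.zeros((h, w), dtype=bool)
    stack = [(r, c) for r in range(h) for c in range(w) if strong[r, c]]
    out[strong] = True
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and cand[rr, cc] and not out[rr, cc]:
                    out[rr, cc] = True
                    stack.append((rr, cc))
    return np.where(out, 255, 0).astype(np.uint8)


def count_components_bf(binary):
    """8-connected component count by explicit flood fill."""
    h, w = binary.shape
    seen = np.zeros((h, w), dtype=bool)
    count = 0
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (
                                0 <= r2 < h and 0 <= c2 < w
                                and binary[r2, c2] and not seen[r2, c2]
                            ):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
    return count


def _on_segment(p, a, b):
    cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    if cross != 0:
        return False
    return (
        min(a[0], b[0]) <= p[0] <= max(a[0], b[0])
        and min(a[1], b[1]) <= p[1] <= max(a[1], b[1])
    )


def point_in_polygon_bf(point, vertices):
    """Crossing-number test; points on the boundary count as inside."""
    n = len(vertices)
    for i in range(n):
        if _on_segment(point, vertices[i], vertices[(i + 1) % n]):
            return True
    x, y = point
    inside = False
    for i in range(n):
        (x1, y1), (x2, y2) = vertices[i], vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


def match_count_bf(query_desc, ref_desc, ratio):
    """O(n^2) exhaustive good-match count with Lowe's ratio test."""
    good = 0
    for q in query_desc:
        dists = sorted(float(np.linalg.norm(q - r)) for r in ref_desc)
        if not dists:
            continue
        if len(dists) == 1 or dists[0] == 0.0 or dists[0] < ratio * dists[1]:
            good += 1
    return good
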