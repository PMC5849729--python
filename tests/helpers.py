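"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit loops, no shared code with the package.
"""

import math

import numpy as np


def flood_fill_components(mask, connectivity):
    """Connected components by explicit stack-based flood fill.

    Returns a list of ``frozenset`` of (row, col), ordered by the raster
    position of each component's first-encountered pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    cr, cc = stack.pop()
                    comp.add((cr, cc))
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return comps


def brute_force_otsu(values):
    """Smallest threshold maximizing between-class variance, by explicit scan.

    Foreground is strictly above the threshold.
    """
    values = [int(v) for v in np.asarray(values).ravel()]
    best_t, best_sigma = None, -1.0
    for t in range(256):
        bg = [v for v in values if v <= t]
        fg = [v for v in values if v > t]
        if not bg or not fg:
            continue
        w0, w1 = len(bg), len(fg)
        mu0 = sum(bg) / w0
        mu1 = sum(fg) / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_t = sigma, t
    return best_t


def average_ranks(values):
    """Average (midrank) ranks computed by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman's rho: average ranks, then the Pearson formula on ranks."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def enumerate_ellipse_pixels(shape, center_xy, major, minor, angle_deg):
    """Point-in-ellipse test at every pixel center; returns a set of (r, c)."""
    h, w = shape
    cx, cy = center_xy
    a, b = major / 2.0, minor / 2.0
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    out = set()
    for r in range(h):
        for col in range(w):
            dx, dy = col - cx, r - cy
            u = dx * c + dy * s
            v = -dx * s + dy * c
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                out.add((r, col))
    return out
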