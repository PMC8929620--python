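"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain nested loops over cells, deliberately
sharing no code with the vectorized implementations under test.
"""

from __future__ import annotations

import math

import numpy as np


def mid_ecdf_similarity(sample, x, epsilon) -> float:
    """Counting-loop mid-distribution ECDF typicality."""
    less = sum(1 for v in sample if v < x)
    equal = sum(1 for v in sample if v == x)
    f = (less + 0.5 * equal) / len(sample)
    p = 2.0 * min(f, 1.0 - f)
    return min(max(p, epsilon), 1.0)


def surface_reference(stack, train_sites, diameter_m, min_coverage, epsilon, alpha, d_floor):
    """Nested-loop potential surface: per-cell similarity -> joint -> weights -> total."""
    geom = stack.geometry
    cs = geom.cell_size
    radius = diameter_m / 2.0
    layer_names = list(stack.layers)
    valid = stack.valid_mask()

    # CSA samples by scanning every cell for every site
    csas = []
    for site in train_sites:
        samples = {n: [] for n in layer_names}
        n_circle = 0
        n_valid = 0
        # scan a generous window of lattice positions around the site
        for row in range(-200, geom.n_rows + 200):
            for col in range(-200, geom.n_cols + 200):
                x = geom.origin_x + (col + 0.5) * cs
                y = geom.origin_y - (row + 0.5) * cs
                if (x - site.x) ** 2 + (y - site.y) ** 2 > radius**2:
                    continue
                n_circle += 1
                if 0 <= row < geom.n_rows and 0 <= col < geom.n_cols and valid[row, col]:
                    n_valid += 1
                    for n in layer_names:
                        v = stack[n].values[row, col]
                        if not math.isnan(v):
                            samples[n].append(v)
        if n_circle == 0 or n_valid / n_circle < min_coverage:
            continue
        csas.append((site.x, site.y, {n: sorted(samples[n]) for n in layer_names}))

    out = np.full(geom.values.shape, np.nan)
    for row in range(geom.n_rows):
        for col in range(geom.n_cols):
            if not valid[row, col]:
                continue
            x = geom.origin_x + (col + 0.5) * cs
            y = geom.origin_y - (row + 0.5) * cs
            probs, weights = [], []
            for sx, sy, samples in csas:
                logp = 0.0
                for n in layer_names:
                    logp += math.log(
                        mid_ecdf_similarity(samples[n], stack[n].values[row, col], epsilon)
                    )
                probs.append(math.exp(logp))
                d = math.hypot(x - sx, y - sy)
                weights.append(max(d, d_floor) ** (-alpha))
            wsum = sum(weights)
            out[row, col] = sum(p * w / wsum for p, w in zip(probs, weights))
    return out


def nearest_true_distance(mask, cell_size) -> np.ndarray:
    """Min cell-centre distance to any true cell, by full scan."""
    nrows, ncols = mask.shape
    trues = [(r, c) for r in range(nrows) for c in range(ncols) if mask[r, c]]
    out = np.empty(mask.shape)
    for r in range(nrows):
        for c in range(ncols):
            out[r, c] = min(
                math.hypot(r - tr, c - tc) * cell_size for tr, tc in trues
            )
    return out


_D8 = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def d8_receivers(z) -> dict:
    """Steepest-descent receiver per cell (None for pits/flats), fixed tie order."""
    nrows, ncols = z.shape
    recv = {}
    for r in range(nrows):
        for c in range(ncols):
            if math.isnan(z[r, c]):
                continue
            best, best_slope = None, 0.0
            for dr, dc in _D8:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols):
                    continue
                if math.isnan(z[nr, nc]):
                    continue
                s = (z[r, c] - z[nr, nc]) / math.hypot(dr, dc)
                if s > best_slope:
                    best, best_slope = (nr, nc), s
            recv[(r, c)] = best
    return recv


def flow_accumulation_reference(z) -> np.ndarray:
    """Upstream count including self: walk every cell's flow path downslope."""
    recv = d8_receivers(z)
    acc = np.where(np.isnan(z), np.nan, 0.0)
    for start in recv:
        cell = start
        visited = set()
        while cell is not None and cell not in visited:
            visited.add(cell)
            acc[cell] += 1
            cell = recv[cell]
    return acc


def line_of_sight_visible(z, cell_size, obs_rc, tgt_rc, observer_height) -> bool:
    """Stepwise-sampled LOS with manual bilinear terrain interpolation."""

    def bilinear(rf, cf):
        r0, c0 = int(math.floor(rf)), int(math.floor(cf))
        r0 = min(max(r0, 0), z.shape[0] - 2) if z.shape[0] > 1 else 0
        c0 = min(max(c0, 0), z.shape[1] - 2) if z.shape[1] > 1 else 0
        fr, fc = rf - r0, cf - c0
        return (
            z[r0, c0] * (1 - fr) * (1 - fc)
            + z[r0 + 1, c0] * fr * (1 - fc)
            + z[r0, c0 + 1] * (1 - fr) * fc
            + z[r0 + 1, c0 + 1] * fr * fc
        )

    ro, co = obs_rc
    tr, tc = tgt_rc
    z_eye = z[ro, co] + observer_height
    z_tgt = z[tr, tc]
    dist = math.hypot(tr - ro, tc - co)
    nsteps = math.ceil(dist)
    for k in range(1, nsteps):
        t = k / nsteps
        terrain = bilinear(ro + t * (tr - ro), co + t * (tc - co))
        line = z_eye + t * (z_tgt - z_eye)
        if terrain > line + 1e-9:
            return False
    return True


def convexity_reference(z, window_radius, flat_tolerance=0.0) -> np.ndarray:
    """Windowed fraction of locally convex cells by explicit neighbour scans."""
    nrows, ncols = z.shape
    convex = np.zeros(z.shape, dtype=bool)
    for r in range(nrows):
        for c in range(ncols):
            if math.isnan(z[r, c]):
                continue
            nbrs = [
                z[r + dr, c + dc]
                for dr, dc in _D8
                if 0 <= r + dr < nrows and 0 <= c + dc < ncols
                and not math.isnan(z[r + dr, c + dc])
            ]
            if len(nbrs) == 8:  # complete neighbourhood required
                guard = 1e-9 * (1.0 + abs(z[r, c]))
                convex[r, c] = z[r, c] - sum(nbrs) / 8 > flat_tolerance + guard
    out = np.full(z.shape, np.nan)
    w = window_radius
    for r in range(nrows):
        for c in range(ncols):
            if math.isnan(z[r, c]):
                continue
            n_valid = n_conv = 0
            for dr in range(-w, w + 1):
                for dc in range(-w, w + 1):
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < nrows and 0 <= nc < ncols and not math.isnan(z[nr, nc]):
                        n_valid += 1
                        n_conv += convex[nr, nc]
            out[r, c] = n_conv / n_valid
    return out


def csa_cell_count(geom_origin_x, geom_origin_y, cell_size, nrows, ncols, sx, sy, radius):
    """Count cells whose centre lies within the circle, by scanning the grid."""
    n = 0
    for row in range(nrows):
        for col in range(ncols):
            x = geom_origin_x + (col + 0.5) * cell_size
            y = geom_origin_y - (row + 0.5) * cell_size
            if (x - sx) ** 2 + (y - sy) ** 2 <= radius**2:
                n += 1
    return n


def poisson_slope_grid_search(counts, lo=-3.0, hi=3.0, tol=1e-10):
    """1-D profile-score solution for the Poisson slope.

    For a trial slope b the intercept solves exp(a) = sum(y) / sum(exp(b x));
    the slope score g(b) = sum(x (y - mu)) is then bracketed on a fine grid
    and bisected to ``tol``.
    """
    y = np.asarray(counts, dtype=float)
    x = np.arange(1, y.size + 1, dtype=float)

    def score(b):
        a = math.log(y.sum() / np.exp(b * x).sum())
        mu = np.exp(a + b * x)
        return float(x @ (y - mu))

    grid = np.linspace(lo, hi, 20001)
    vals = [score(b) for b in grid]
    bracket = None
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return grid[i]
        if vals[i] * vals[i + 1] < 0:
            bracket = (grid[i], grid[i + 1])
            break
    if bracket is None:
        raise RuntimeError("no sign change for the slope score on the grid")
    a, b = bracket
    while b - a > tol:
        m = (a + b) / 2
        if score(a) * score(m) <= 0:
            b = m
        else:
            a = m
    return (a + b) / 2
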