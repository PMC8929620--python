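"""Terrain derivatives of a DEM: slope, aspect, convexity, drainage distance, cumulative viewshed.

These are the landscape variables the potential model samples around known
sites. All functions take and return :class:`~lamap.raster.GridRaster` on the
DEM's grid geometry.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import GridRaster

CANONICAL_LAYERS = ("elevation", "slope", "aspect", "dist_drainage", "viewshed", "convexity")

__all__ = [
    "DerivativeStack",
    "slope_aspect",
    "convexity",
    "flow_accumulation_d8",
    "extract_drainage",
    "distance_to_drainage",
    "cumulative_viewshed",
    "fill_depressions",
    "derive_all",
    "CANONICAL_LAYERS",
]


@dataclass
class DerivativeStack:
    """Ordered set of layers sharing one grid geometry."""

    layers: dict[str, GridRaster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        if rasters:
            ref = rasters[0]
            for r in rasters[1:]:
                same = (
                    r.values.shape == ref.values.shape
                    and abs(r.origin_x - ref.origin_x) < 1e-6
                    and abs(r.origin_y - ref.origin_y) < 1e-6
                    and abs(r.cell_size - ref.cell_size) < 1e-9
                )
                if not same:
                    raise ValueError("stack layers must share one grid geometry")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def geometry(self) -> GridRaster:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    def valid_mask(self) -> np.ndarray:
        """A cell is valid in the stack iff valid in every layer."""
        mask = np.ones(self.geometry.values.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.valid_mask
        return mask

    def as_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid, n_layers) matrix of stack-valid cells plus the boolean mask."""
        mask = self.valid_mask()
        mat = np.column_stack([r.values[mask] for r in self.layers.values()])
        return mat, mask


# ---------------------------------------------------------------------------
# Slope and aspect (Horn 3x3 finite differences)

def slope_aspect(dem: GridRaster) -> tuple[GridRaster, GridRaster]:
    """Slope (degrees, [0, 90)) and aspect (compass bearing of the downslope
    direction, 0 deg = north, clockwise; nodata where the gradient vanishes).

    Interior cells use the Horn 3x3 weighted finite-difference gradient;
    border rows/columns fall back to one-sided differences, which keeps the
    gradient exact on planar surfaces everywhere.
    """
    if dem.n_rows < 2 or dem.n_cols < 2:
        raise ValueError("DEM must be at least 2x2 for gradients")
    z = dem.values
    h = dem.cell_size
    zp = np.pad(z, 1, mode="edge")
    # eastward and northward derivatives (row index increases southward)
    gx = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8 * h)
    gy = (
        (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
        - (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
    ) / (8 * h)
    # one-sided differences on the border ring
    gx[:, 0] = (z[:, 1] - z[:, 0]) / h
    gx[:, -1] = (z[:, -1] - z[:, -2]) / h
    gy[0, :] = (z[0, :] - z[1, :]) / h
    gy[-1, :] = (z[-2, :] - z[-1, :]) / h

    grad = np.hypot(gx, gy)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(grad == 0, np.nan, aspect)
    invalid = ~dem.valid_mask
    slope[invalid] = np.nan
    aspect[invalid] = np.nan
    return dem.like(slope, "slope"), dem.like(aspect, "aspect")


# ---------------------------------------------------------------------------
# Convexity (windowed fraction of locally convex cells)

def convexity(dem: GridRaster, window_radius: int = 5, flat_tolerance: float = 0.0) -> GridRaster:
    """Fraction of cells in a (2r+1)^2 window that sit above their 8-neighbour mean.

    A cell is locally convex when it has a complete valid 8-neighbourhood and
    its elevation exceeds the neighbour mean by more than ``flat_tolerance``
    (metres) — the completeness requirement stops tilted surfaces from
    scoring as convex along the grid edge. The output is the fraction of
    valid cells in the window that are locally convex — a hilltop-likeness
    measure in [0, 1].
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    z = dem.values
    valid = dem.valid_mask
    zf = np.where(valid, z, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(zf, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    # border cells never have 8 in-grid neighbours under zero padding
    with np.errstate(invalid="ignore", divide="ignore"):
        nbr_mean = nbr_sum / nbr_cnt
    # magnitude-scaled guard so exact ties (planes) never count as convex
    guard = 1e-9 * (1.0 + np.abs(z))
    convex = valid & (nbr_cnt == 8) & (z - nbr_mean > flat_tolerance + guard)

    w = 2 * window_radius + 1
    win_convex = ndimage.uniform_filter(convex.astype(float), size=w, mode="constant", cval=0.0) * w * w
    win_valid = ndimage.uniform_filter(valid.astype(float), size=w, mode="constant", cval=0.0) * w * w
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = win_convex / win_valid
    frac = np.clip(frac, 0.0, 1.0)
    frac[~valid] = np.nan
    return dem.like(frac, "convexity")


# ---------------------------------------------------------------------------
# D8 flow routing and drainage distance

# fixed neighbour order: E, SE, S, SW, W, NW, N, NE (first wins on ties)
_D8_OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def flow_accumulation_d8(dem: GridRaster) -> GridRaster:
    """Upstream cell count (including self) under single-direction steepest descent.

    Each valid cell drains to the valid 8-neighbour with the greatest positive
    drop per unit distance (diagonals scaled by sqrt 2); slope ties are broken
    by the fixed neighbour order E, SE, S, SW, W, NW, N, NE. Pits and flats
    drain nowhere.
    """
    z = dem.values
    nrows, ncols = z.shape
    valid = dem.valid_mask
    best_slope = np.full(z.shape, 0.0)
    recv_r = np.full(z.shape, -1, dtype=np.int64)
    recv_c = np.full(z.shape, -1, dtype=np.int64)
    for dr, dc in _D8_OFFSETS:
        dist = np.hypot(dr, dc)
        zn = np.full(z.shape, np.nan)
        r0, r1 = max(dr, 0), nrows + min(dr, 0)
        c0, c1 = max(dc, 0), ncols + min(dc, 0)
        zn[r0 - dr : r1 - dr, c0 - dc : c1 - dc] = z[r0:r1, c0:c1]
        with np.errstate(invalid="ignore"):
            slope = (z - zn) / dist
            better = valid & (slope > best_slope)  # strict: earlier order wins ties
        best_slope = np.where(better, slope, best_slope)
        rr, cc = np.nonzero(better)
        recv_r[rr, cc] = rr + dr
        recv_c[rr, cc] = cc + dc

    acc = np.where(valid, 1.0, np.nan)
    order = np.argsort(z, axis=None, kind="stable")[::-1]  # descending elevation
    flat_recv = np.where(recv_r >= 0, recv_r * ncols + recv_c, -1).ravel()
    acc_flat = acc.ravel()
    valid_flat = valid.ravel()
    for idx in order:
        if not valid_flat[idx]:
            continue
        tgt = flat_recv[idx]
        if tgt >= 0:
            if np.isnan(acc_flat[tgt]):
                raise RuntimeError("flow routed into a nodata cell")
            acc_flat[tgt] += acc_flat[idx]
    return dem.like(acc_flat.reshape(z.shape), "flow_accumulation")


def extract_drainage(accumulation: GridRaster, threshold_fraction: float = 0.01) -> GridRaster:
    """Boolean drainage mask: accumulation >= threshold_fraction x valid cell count."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    acc = accumulation.values
    n_valid = accumulation.n_valid
    with np.errstate(invalid="ignore"):
        mask = acc >= threshold_fraction * n_valid
    if not mask.any():
        warnings.warn("drainage mask is empty at this threshold", stacklevel=2)
    out = np.where(accumulation.valid_mask, mask.astype(float), np.nan)
    return accumulation.like(out, "drainage_mask")


def distance_to_drainage(mask: GridRaster, cell_size: float | None = None) -> GridRaster:
    """Euclidean cell-centre distance (m) to the nearest drainage cell; drainage cells are 0."""
    cs = mask.cell_size if cell_size is None else cell_size
    drain = np.nan_to_num(mask.values, nan=0.0) > 0.5
    if not drain.any():
        raise ValueError("drainage mask contains no drainage cells")
    dist = ndimage.distance_transform_edt(~drain, sampling=cs)
    dist = np.where(mask.valid_mask, dist, np.nan)
    return mask.like(dist, "dist_drainage")


def fill_depressions(dem: GridRaster, epsilon: float = 0.0) -> GridRaster:
    """Priority-flood depression filling (optional preprocessing for D8 routing).

    With ``epsilon > 0`` filled cells are raised slightly above their spill
    level so former depressions keep a downslope gradient instead of becoming
    flats that drain nowhere.
    """
    z = dem.values.copy()
    nrows, ncols = z.shape
    valid = dem.valid_mask
    filled = np.where(valid, np.inf, np.nan)
    heap: list[tuple[float, int, int]] = []
    seen = np.zeros(z.shape, dtype=bool)
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            edge = r in (0, nrows - 1) or c in (0, ncols - 1)
            if not edge:
                edge = any(
                    0 <= r + dr < nrows and 0 <= c + dc < ncols and not valid[r + dr, c + dc]
                    for dr, dc in _D8_OFFSETS
                )
            if edge:
                filled[r, c] = z[r, c]
                seen[r, c] = True
                heapq.heappush(heap, (z[r, c], r, c))
    while heap:
        level, r, c = heapq.heappop(heap)
        for dr, dc in _D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and valid[nr, nc] and not seen[nr, nc]:
                seen[nr, nc] = True
                filled[nr, nc] = max(z[nr, nc], level + epsilon)
                heapq.heappush(heap, (filled[nr, nc], nr, nc))
    return dem.like(filled, dem.variable_name)


# ---------------------------------------------------------------------------
# Cumulative viewshed

def _observer_cells(dem: GridRaster, spacing_m: float) -> list[tuple[int, int]]:
    """Cells containing the grid-aligned observer points (origin-registered)."""
    min_x, min_y, max_x, max_y = dem.extent
    obs = []
    x = min_x
    while x < max_x:
        y = max_y
        while y > min_y:
            # snap the point into its containing cell (boundary points inward)
            col = min(int((x - min_x) // dem.cell_size), dem.n_cols - 1)
            row = min(int((max_y - y) // dem.cell_size), dem.n_rows - 1)
            if dem.valid_mask[row, col]:
                obs.append((row, col))
            y -= spacing_m
        x += spacing_m
    return obs


def cumulative_viewshed(
    dem: GridRaster,
    observer_spacing_m: float = 1000.0,
    observer_height_m: float = 1.6,
    max_radius_m: float = 5000.0,
) -> GridRaster:
    """Per-cell count of regular-grid observers with a clear line of sight to it.

    Observers sit on a square grid with ``observer_spacing_m`` spacing
    registered at the raster origin, at cell-centre elevation plus
    ``observer_height_m`` (eye height). A target cell is visible from an
    observer when no interpolated terrain sample along the sight line —
    sampled every ``cell_size`` with bilinear interpolation — rises above the
    straight line joining the observer's eye to the target's ground surface.
    Grazing contact counts as visible. Bare-earth only: no vegetation and no
    earth curvature.
    """
    if max_radius_m <= 0:
        raise ValueError("max_radius_m must be positive")
    if observer_spacing_m < dem.cell_size:
        raise ValueError("observer spacing must be at least one cell")
    z = dem.values
    valid = dem.valid_mask
    counts = np.where(valid, 0.0, np.nan)
    rows, cols = np.nonzero(valid)
    radius_cells = max_radius_m / dem.cell_size
    tol = 1e-9

    for ro, co in _observer_cells(dem, observer_spacing_m):
        z_eye = z[ro, co] + observer_height_m
        dr = rows - ro
        dc = cols - co
        dist = np.hypot(dr, dc)
        sel = dist <= radius_cells
        tr, tc, td = rows[sel], cols[sel], dist[sel]
        zt = z[tr, tc]
        nsteps = np.ceil(td).astype(int)  # samples at k/nsteps, k = 1..nsteps-1
        max_n = int(nsteps.max(initial=1))
        if max_n >= 2:
            k = np.arange(1, max_n)
            interior = k[None, :] < nsteps[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(interior, k[None, :] / nsteps[:, None], 0.0)
            rr = ro + t * (tr - ro)[:, None]
            cc = co + t * (tc - co)[:, None]
            terrain = ndimage.map_coordinates(
                np.nan_to_num(z, nan=-1e30), [rr.ravel(), cc.ravel()], order=1
            ).reshape(rr.shape)
            line = z_eye + t * (zt - z_eye)[:, None]
            blocked = np.any(interior & (terrain > line + tol), axis=1)
        else:
            blocked = np.zeros(tr.shape, dtype=bool)
        counts[tr[~blocked], tc[~blocked]] += 1.0
    return dem.like(counts, "viewshed")


def decompose_aspect(stack: DerivativeStack) -> DerivativeStack:
    """Replace the circular ``aspect`` layer with ``aspect_sin``/``aspect_cos``.

    Aspect is an angle (0 deg = 360 deg) but the similarity model treats
    variables as linear; this optional transform removes the discontinuity at
    north. Flat (nodata-aspect) cells stay nodata in both components.
    """
    if "aspect" not in stack.layers:
        raise KeyError("stack has no 'aspect' layer")
    out: dict[str, GridRaster] = {}
    for name, layer in stack.layers.items():
        if name != "aspect":
            out[name] = layer
            continue
        rad = np.radians(layer.values)
        out["aspect_sin"] = layer.like(np.sin(rad), "aspect_sin")
        out["aspect_cos"] = layer.like(np.cos(rad), "aspect_cos")
    return DerivativeStack(layers=out)


# ---------------------------------------------------------------------------
# Convenience: the full six-layer stack

def derive_all(
    dem: GridRaster,
    drainage_threshold_fraction: float = 0.01,
    convexity_radius: int = 5,
    viewshed_spacing_m: float = 1000.0,
    viewshed_height_m: float = 1.6,
    viewshed_max_radius_m: float = 5000.0,
    fill_pits: bool = False,
) -> DerivativeStack:
    """Derive the six canonical landscape layers from a DEM."""
    routing_dem = fill_depressions(dem) if fill_pits else dem
    slope, aspect = slope_aspect(dem)
    conv = convexity(dem, window_radius=convexity_radius)
    acc = flow_accumulation_d8(routing_dem)
    drain = extract_drainage(acc, drainage_threshold_fraction)
    dist = distance_to_drainage(drain)
    view = cumulative_viewshed(
        dem,
        observer_spacing_m=viewshed_spacing_m,
        observer_height_m=viewshed_height_m,
        max_radius_m=viewshed_max_radius_m,
    )
    return DerivativeStack(
        layers={
            "elevation": dem.like(dem.values.copy(), "elevation"),
            "slope": slope,
            "aspect": aspect,
            "dist_drainage": dist,
            "viewshed": view,
            "convexity": conv,
        }
    )
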