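"""The locally-adaptive potential model.

Each map cell is scored by how typical its landscape-variable values are of
the 1 km circular sampling areas (CSAs) around known sites:

1. per site and variable, an empirical value distribution is drawn from the
   CSA cells;
2. a target cell's per-variable similarity is a two-sided mid-distribution
   ECDF typicality, ``p = 2 * min(F(x), 1 - F(x))`` — 1 at the CSA median,
   decaying toward the tails, floored at a small epsilon;
3. per-variable similarities multiply (in log space) into a per-site joint
   probability;
4. per-site probabilities combine as a weighted average (law of total
   probability) with inverse-distance weights, giving a potential value in
   [0, 1];
5. the continuous surface is binned into k equal-count ordinal classes
   (quintiles by default), 1 = lowest potential ... k = highest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import GridRaster, SitePoint
from .terrain import DerivativeStack

__all__ = [
    "CSASample",
    "LamapSurface",
    "PotentialClasses",
    "LamapParams",
    "extract_csa",
    "empirical_similarity",
    "site_joint_probability",
    "distance_weights",
    "lamap_value",
    "compute_surface",
    "classify_quantiles",
]


class EdgeSiteError(ValueError):
    """CSA coverage below the minimum floor (site too close to the raster edge)."""


class NoTrainingDataError(ValueError):
    """Every training-site CSA was rejected."""


class DegenerateClassificationError(ValueError):
    """Surface has too few distinct values to split into classes."""


@dataclass
class CSASample:
    """Per-variable sorted value samples from one site's circular sampling area."""

    site_id: str
    x: float
    y: float
    samples: dict[str, np.ndarray]  # variable -> ascending values
    n_cells: int
    coverage: float


@dataclass
class LamapSurface:
    """Continuous potential surface in [0, 1] plus the parameters that produced it."""

    raster: GridRaster
    provenance: dict = field(default_factory=dict)


@dataclass
class PotentialClasses:
    """Ordinal 1..k class raster plus the k-1 cut values between classes."""

    raster: GridRaster
    class_edges: list[float]
    k: int = 5


@dataclass
class LamapParams:
    """Tunable parameters of the potential model."""

    diameter_m: float = 1000.0
    min_coverage: float = 0.5
    epsilon: float = 1e-6
    alpha: float = 1.0  # inverse-distance weighting exponent
    d_floor_m: float | None = None  # defaults to one cell size
    k_classes: int = 5

    def as_dict(self) -> dict:
        return {
            "diameter_m": self.diameter_m,
            "min_coverage": self.min_coverage,
            "epsilon": self.epsilon,
            "alpha": self.alpha,
            "d_floor_m": self.d_floor_m,
            "k_classes": self.k_classes,
        }


# ---------------------------------------------------------------------------
# CSA extraction

def extract_csa(
    stack: DerivativeStack,
    site: SitePoint,
    diameter_m: float = 1000.0,
    min_coverage: float = 0.5,
) -> CSASample:
    """Sample every stack layer over the cells whose centres lie within
    ``diameter_m / 2`` of the site point.

    ``coverage`` is the fraction of the full circle's cell positions (counting
    positions beyond the raster edge) that are stack-valid; sites whose
    coverage falls below ``min_coverage`` raise :class:`EdgeSiteError`.
    """
    geom = stack.geometry
    if not geom.contains(site.x, site.y):
        raise ValueError(f"site {site.site_id} at ({site.x}, {site.y}) outside raster extent")
    radius = diameter_m / 2.0
    cs = geom.cell_size

    # full-circle cell-centre count over the (unbounded) grid lattice
    col_f = (site.x - geom.origin_x) / cs - 0.5  # fractional col of site vs centres
    row_f = (geom.origin_y - site.y) / cs - 0.5
    rc = int(np.ceil(radius / cs)) + 1
    all_cols = np.arange(int(np.floor(col_f)) - rc, int(np.ceil(col_f)) + rc + 1)
    all_rows = np.arange(int(np.floor(row_f)) - rc, int(np.ceil(row_f)) + rc + 1)
    dx = (all_cols - col_f) * cs
    dy = (all_rows - row_f) * cs
    in_circle = (dx[None, :] ** 2 + dy[:, None] ** 2) <= radius**2
    n_circle = int(in_circle.sum())

    in_rows = (all_rows >= 0) & (all_rows < geom.n_rows)
    in_cols = (all_cols >= 0) & (all_cols < geom.n_cols)
    inside = in_circle & in_rows[:, None] & in_cols[None, :]
    rr, cc = np.nonzero(inside)
    rows_idx = all_rows[rr]
    cols_idx = all_cols[cc]

    stack_valid = stack.valid_mask()[rows_idx, cols_idx]
    rows_idx, cols_idx = rows_idx[stack_valid], cols_idx[stack_valid]
    n_cells = rows_idx.size
    coverage = n_cells / n_circle if n_circle else 0.0
    if coverage < min_coverage:
        raise EdgeSiteError(
            f"site {site.site_id}: CSA coverage {coverage:.2f} below floor {min_coverage}"
        )
    samples: dict[str, np.ndarray] = {}
    for name, layer in stack.layers.items():
        vals = layer.values[rows_idx, cols_idx]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise EdgeSiteError(f"site {site.site_id}: no valid {name!r} cells in CSA")
        samples[name] = np.sort(vals)
    return CSASample(site.site_id, site.x, site.y, samples, n_cells, coverage)


# ---------------------------------------------------------------------------
# Similarity and combination primitives

def empirical_similarity(
    sample: np.ndarray, x: float | np.ndarray, epsilon: float = 1e-6
) -> float | np.ndarray:
    """Two-sided mid-distribution ECDF typicality of ``x`` within ``sample``.

    ``F(x) = (#{v < x} + 0.5 #{v = x}) / n``; the similarity is
    ``2 min(F, 1 - F)`` clipped to ``[epsilon, 1]`` — 1 at the sample median,
    ``epsilon`` beyond the sample range. ``sample`` must be sorted ascending.
    """
    sample = np.asarray(sample)
    if sample.size == 0:
        raise ValueError("empty CSA sample")
    scalar = np.isscalar(x) or np.ndim(x) == 0
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    left = np.searchsorted(sample, xs, side="left")
    right = np.searchsorted(sample, xs, side="right")
    f = (left + 0.5 * (right - left)) / sample.size
    p = np.clip(2.0 * np.minimum(f, 1.0 - f), epsilon, 1.0)
    return float(p[0]) if scalar else p


def site_joint_probability(
    csa: CSASample, target_values: dict[str, float], epsilon: float = 1e-6
) -> float:
    """Product of per-variable similarities, accumulated in log space."""
    log_p = 0.0
    for name, sample in csa.samples.items():
        if name not in target_values:
            raise KeyError(f"target missing variable {name!r}")
        log_p += np.log(empirical_similarity(sample, target_values[name], epsilon))
    return float(np.exp(log_p))


def distance_weights(
    target_xy: tuple[float, float],
    sites: list[CSASample] | list[SitePoint],
    alpha: float = 1.0,
    d_floor: float = 1.0,
) -> np.ndarray:
    """Normalized inverse-distance weights, w_s proportional to max(d, d_floor)^-alpha."""
    if len(sites) == 0:
        raise ValueError("need at least one site")
    tx, ty = target_xy
    d = np.array([np.hypot(s.x - tx, s.y - ty) for s in sites])
    w = np.maximum(d, d_floor) ** (-alpha)
    return w / w.sum()


def lamap_value(site_probs: np.ndarray, weights: np.ndarray) -> float:
    """Law-of-total-probability combination: weighted average of per-site probabilities."""
    site_probs = np.asarray(site_probs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if site_probs.shape != weights.shape:
        raise ValueError("probability/weight length mismatch")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return float(site_probs @ weights)


# ---------------------------------------------------------------------------
# Full surface

def compute_surface(
    stack: DerivativeStack,
    train_sites: list[SitePoint],
    params: LamapParams | None = None,
) -> LamapSurface:
    """Apply the per-cell pipeline to every stack-valid cell.

    Edge sites whose CSA coverage falls below the floor are dropped (with all
    dropped, :class:`NoTrainingDataError` is raised); cells inside a training
    CSA are scored identically to any other cell.
    """
    params = params or LamapParams()
    geom = stack.geometry
    d_floor = params.d_floor_m if params.d_floor_m is not None else geom.cell_size

    csas: list[CSASample] = []
    for site in train_sites:
        try:
            csas.append(
                extract_csa(stack, site, params.diameter_m, params.min_coverage)
            )
        except EdgeSiteError:
            continue
    if not csas:
        raise NoTrainingDataError("all training-site CSAs were rejected")

    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    xs, ys = geom.cell_centers()
    cx, cy = xs[cols], ys[rows]

    # per-site joint probabilities, vectorized over cells
    n_cells = rows.size
    probs = np.empty((n_cells, len(csas)))
    for j, csa in enumerate(csas):
        log_p = np.zeros(n_cells)
        for name, layer in stack.layers.items():
            vals = layer.values[rows, cols]
            log_p += np.log(
                empirical_similarity(csa.samples[name], vals, params.epsilon)
            )
        probs[:, j] = np.exp(log_p)

    # inverse-distance weights across sites
    d = np.hypot(
        cx[:, None] - np.array([c.x for c in csas])[None, :],
        cy[:, None] - np.array([c.y for c in csas])[None, :],
    )
    w = np.maximum(d, d_floor) ** (-params.alpha)
    w /= w.sum(axis=1, keepdims=True)

    values = np.full(geom.values.shape, np.nan)
    values[rows, cols] = (probs * w).sum(axis=1)
    prov = params.as_dict() | {
        "n_train_sites": len(train_sites),
        "n_accepted_csas": len(csas),
        "variables": list(stack.layers),
    }
    return LamapSurface(raster=geom.like(values, "lamap"), provenance=prov)


def classify_quantiles(surface: LamapSurface | GridRaster, k: int = 5) -> PotentialClasses:
    """Equal-count ordinal classes of the potential surface.

    Valid cells are ranked ascending (ties broken by row-major cell order so
    runs are deterministic); the first ``n mod k`` classes receive
    ``ceil(n/k)`` cells, the rest ``floor(n/k)``. Class ``k`` holds the
    highest-potential cells.
    """
    raster = surface.raster if isinstance(surface, LamapSurface) else surface
    vals = raster.values
    mask = ~np.isnan(vals)
    flat = vals[mask]
    n = flat.size
    if n < k:
        raise DegenerateClassificationError(f"only {n} valid cells for {k} classes")
    if np.unique(flat).size < 2:
        raise DegenerateClassificationError("constant surface cannot be classified")

    order = np.argsort(flat, kind="stable")  # row-major tie-break
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    bounds = np.cumsum(sizes)
    classes = np.empty(n, dtype=float)
    start = 0
    edges: list[float] = []
    for c, stop in enumerate(bounds, start=1):
        classes[order[start:stop]] = c
        if c < k:
            edges.append(float(flat[order[stop - 1]]))
        start = stop

    out = np.full(vals.shape, np.nan)
    out[mask] = classes
    return PotentialClasses(raster=raster.like(out, "potential_class"), class_edges=edges, k=k)
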