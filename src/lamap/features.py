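"""Standardization and PCA of the landscape-variable stack.

The six raw layers have incommensurate units (metres, degrees, counts,
fractions), so they are z-scored per layer before a principal-component
rotation; the potential model then runs on the retained PC-score layers.
Standardization parameters and loadings are stored so that new values (e.g.
individual site CSA cells) can be projected without re-fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .raster import GridRaster
from .terrain import DerivativeStack

__all__ = ["FeatureStack", "standardize", "pca_transform"]


class DegenerateLayerError(ValueError):
    """A layer has zero variance (or too few valid cells) and cannot be standardized."""


@dataclass
class FeatureStack:
    """Layer stack plus the fitted transform parameters.

    After :func:`standardize`, ``layers`` hold z-scored values and ``means`` /
    ``sds`` the per-layer parameters (population-sd convention). After
    :func:`pca_transform`, ``layers`` hold PC scores, ``loadings`` the
    orthonormal component-weight matrix (columns = components over the
    original layer order in ``source_names``) and ``explained_variance`` the
    eigenvalues of the correlation matrix.
    """

    stack: DerivativeStack
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    source_names: list[str] = field(default_factory=list)
    loadings: np.ndarray | None = None
    explained_variance: np.ndarray | None = None
    n_retained: int = 0

    @property
    def layers(self) -> dict[str, GridRaster]:
        return self.stack.layers

    def transform_values(self, values: dict[str, float]) -> np.ndarray:
        """Project one raw-variable record through the stored transform.

        ``values`` maps source layer name -> raw value. Returns the z-scores
        if no PCA has been fitted, else the retained PC scores.
        """
        zs = np.array(
            [(values[n] - self.means[n]) / self.sds[n] for n in self.source_names]
        )
        if self.loadings is None:
            return zs
        return zs @ self.loadings[:, : self.n_retained]

    def save_params(self, path: str | Path) -> None:
        payload = {
            "source_names": self.source_names,
            "means": self.means,
            "sds": self.sds,
            "loadings": None if self.loadings is None else self.loadings.tolist(),
            "explained_variance": None
            if self.explained_variance is None
            else self.explained_variance.tolist(),
            "n_retained": self.n_retained,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def load_params(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())


def standardize(stack: DerivativeStack) -> FeatureStack:
    """Z-score every layer over the stack-valid cells (population sd).

    Cells invalid in any layer are masked everywhere, so all layers are
    standardized over the same cell set.
    """
    mask = stack.valid_mask()
    if mask.sum() < 2:
        raise DegenerateLayerError("fewer than 2 stack-valid cells")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    out_layers: dict[str, GridRaster] = {}
    for name, layer in stack.layers.items():
        vals = layer.values[mask]
        mu = float(vals.mean())
        sd = float(vals.std())  # population convention (ddof=0)
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateLayerError(f"layer {name!r} has zero variance")
        means[name] = mu
        sds[name] = sd
        z = np.where(mask, (layer.values - mu) / sd, np.nan)
        out_layers[name] = layer.like(z)
    return FeatureStack(
        stack=DerivativeStack(layers=out_layers),
        means=means,
        sds=sds,
        source_names=list(stack.layers),
    )


def pca_transform(features: FeatureStack, variance_retained: float = 0.95) -> FeatureStack:
    """Principal-component rotation of a standardized stack.

    Eigendecomposition of the valid-cell correlation matrix (equivalently,
    PCA of the z-scored data); retains the smallest number of components whose
    cumulative explained variance reaches ``variance_retained`` (pass 1.0 to
    keep all). Deterministic sign convention: each component's
    largest-magnitude loading is positive.
    """
    if not 0 < variance_retained <= 1:
        raise ValueError("variance_retained must be in (0, 1]")
    names = features.source_names or list(features.layers)
    if len(names) < 2:
        raise ValueError("PCA needs at least 2 layers")
    mat, mask = features.stack.as_matrix()
    if mat.shape[0] < mat.shape[1]:
        raise ValueError("fewer valid cells than layers")

    pca = PCA(n_components=len(names), svd_solver="full")
    pca.fit(mat)
    # population-convention eigenvalues of the correlation matrix
    eigvals = pca.explained_variance_ * (mat.shape[0] - 1) / mat.shape[0]
    loadings = pca.components_.T.copy()  # columns are components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    frac = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(frac, variance_retained - 1e-12) + 1)
    k = min(k, len(names))

    scores = mat @ loadings[:, :k]
    geom = features.stack.geometry
    out_layers: dict[str, GridRaster] = {}
    for j in range(k):
        vals = np.full(geom.values.shape, np.nan)
        vals[mask] = scores[:, j]
        out_layers[f"pc{j + 1}"] = geom.like(vals, f"pc{j + 1}")
    return FeatureStack(
        stack=DerivativeStack(layers=out_layers),
        means=features.means,
        sds=features.sds,
        source_names=names,
        loadings=loadings,
        explained_variance=eigvals,
        n_retained=k,
    )
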