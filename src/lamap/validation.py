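"""Model validation: held-out site counts per potential class and Poisson regression.

If the potential surface has predictive power, higher ordinal classes should
contain more held-out sites. The test regresses per-class validation-site
counts on the numeric class value 1..k with a log-link Poisson model — class
enters as a number, not a factor, so the slope has the interpretation "one
class up multiplies the expected site count by exp(beta)". Both a maximum
likelihood fit and a Bayesian fit (random-walk Metropolis with wide normal
priors) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .raster import SitePoint
from .surface import PotentialClasses

__all__ = [
    "ClassCounts",
    "PoissonFit",
    "count_sites_by_class",
    "poisson_glm_mle",
    "poisson_glm_bayes",
    "percent_increase_summary",
    "score_equation_residual",
]


@dataclass
class ClassCounts:
    """Validation-site counts per ordinal class 1..k."""

    counts: np.ndarray  # length k, non-negative integers
    n_excluded: int = 0  # sites on nodata cells

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.size

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, self.k + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({"class": self.classes, "count": self.counts}).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ClassCounts":
        df = pd.read_csv(path)
        if not {"class", "count"} <= set(df.columns):
            raise ValueError("counts CSV needs 'class' and 'count' columns")
        df = df.sort_values("class")
        if list(df["class"]) != list(range(1, len(df) + 1)):
            raise ValueError("classes must be consecutive integers from 1")
        return ClassCounts(df["count"].to_numpy())


@dataclass
class PoissonFit:
    """Log-link Poisson regression of counts on numeric class."""

    intercept: float
    slope: float
    covariance: np.ndarray
    converged: bool = True
    draws: np.ndarray | None = None  # posterior (intercept, slope) pairs
    n_iterations: int = 0
    burn_in: int = 0
    seed: int | None = None
    acceptance_rate: float | None = None

    def summary_dict(self) -> dict:
        out = {
            "intercept": self.intercept,
            "slope": self.slope,
            "slope_se": float(np.sqrt(self.covariance[1, 1])),
            "converged": self.converged,
        }
        if self.draws is not None:
            out["posterior_mean_slope"] = float(self.draws[:, 1].mean())
            out["posterior_sd_slope"] = float(self.draws[:, 1].std(ddof=1))
            lo, hi = np.quantile(self.draws[:, 1], [0.025, 0.975])
            out["slope_ci95"] = [float(lo), float(hi)]
            out["acceptance_rate"] = self.acceptance_rate
        return out


def count_sites_by_class(
    classes: PotentialClasses, validation_sites: list[SitePoint]
) -> ClassCounts:
    """Assign each site the class of the cell containing it and tally per class.

    Sites on nodata cells are excluded (and counted in ``n_excluded``); sites
    outside the raster extent are an error.
    """
    raster = classes.raster
    outside = [s.site_id for s in validation_sites if not raster.contains(s.x, s.y)]
    if outside:
        raise ValueError(f"sites outside raster extent: {outside}")
    counts = np.zeros(classes.k, dtype=int)
    excluded = 0
    for s in validation_sites:
        row, col = raster.locate(s.x, s.y)
        c = raster.values[row, col]
        if np.isnan(c):
            excluded += 1
            continue
        counts[int(c) - 1] += 1
    return ClassCounts(counts, n_excluded=excluded)


def _design(counts: ClassCounts) -> tuple[np.ndarray, np.ndarray]:
    x = counts.classes.astype(float)
    return np.column_stack([np.ones_like(x), x]), counts.counts.astype(float)


def score_equation_residual(counts: ClassCounts, intercept: float, slope: float) -> float:
    """Max absolute Poisson score-equation residual at (intercept, slope)."""
    X, y = _design(counts)
    mu = np.exp(X @ np.array([intercept, slope]))
    return float(np.abs(X.T @ (y - mu)).max())


def poisson_glm_mle(counts: ClassCounts) -> PoissonFit:
    """Maximum-likelihood fit via iteratively reweighted least squares.

    Zero counts are fine; all-zero counts are degenerate (the intercept
    diverges to -inf).
    """
    if counts.k < 2:
        raise ValueError("need at least two classes")
    if counts.total == 0:
        raise ValueError("all-zero counts: Poisson regression is degenerate")
    X, y = _design(counts)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(tol=1e-12, maxiter=200)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge: {res.mle_retvals}")
    params = np.asarray(res.params)
    if score_equation_residual(counts, params[0], params[1]) > 1e-8:
        raise RuntimeError("score equations not solved to tolerance")
    return PoissonFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        covariance=np.asarray(res.cov_params()),
        converged=True,
    )


def _log_posterior(theta: np.ndarray, X: np.ndarray, y: np.ndarray, prior_sd: float) -> float:
    eta = X @ theta
    # Poisson log-likelihood up to a constant, plus independent normal(0, prior_sd^2) priors
    ll = float(y @ eta - np.exp(eta).sum())
    lp = -0.5 * float(theta @ theta) / prior_sd**2
    return ll + lp


def poisson_glm_bayes(
    counts: ClassCounts,
    n_iterations: int = 20000,
    prior_sd: float = 10.0,
    seed: int | None = None,
) -> PoissonFit:
    """Bayesian fit: random-walk Metropolis with adaptive proposals during burn-in.

    Independent normal(0, prior_sd^2) priors on intercept and slope; the first
    10% of iterations are burn-in, during which the proposal scale adapts
    toward an acceptance rate near 0.3. Draws are returned post burn-in; the
    sampler errors out if the post-adaptation acceptance rate leaves
    (0.05, 0.95).
    """
    if n_iterations < 2000:
        raise ValueError("n_iterations too small for a stable posterior")
    X, y = _design(counts)
    rng = np.random.default_rng(seed)
    # start at the MLE when attainable, else zero
    try:
        mle = poisson_glm_mle(counts)
        theta = np.array([mle.intercept, mle.slope])
    except (ValueError, RuntimeError):
        theta = np.zeros(2)
    burn_in = n_iterations // 10
    scale = 0.5
    lp = _log_posterior(theta, X, y, prior_sd)
    draws = np.empty((n_iterations - burn_in, 2))
    accepted_post = 0
    for it in range(n_iterations):
        prop = theta + rng.normal(0.0, scale, size=2)
        lp_prop = _log_posterior(prop, X, y, prior_sd)
        accept = np.log(rng.uniform()) < lp_prop - lp
        if accept:
            theta, lp = prop, lp_prop
        if it < burn_in:
            # Robbins-Monro drift toward 30% acceptance
            scale *= np.exp((1.0 if accept else -0.43) * 0.3 / np.sqrt(it + 1))
        else:
            draws[it - burn_in] = theta
            accepted_post += bool(accept)
    acc_rate = accepted_post / (n_iterations - burn_in)
    if not 0.05 < acc_rate < 0.95:
        raise RuntimeError(f"sampler acceptance rate {acc_rate:.3f} outside (0.05, 0.95)")
    mean = draws.mean(axis=0)
    return PoissonFit(
        intercept=float(mean[0]),
        slope=float(mean[1]),
        covariance=np.cov(draws.T),
        converged=True,
        draws=draws,
        n_iterations=n_iterations,
        burn_in=burn_in,
        seed=seed,
        acceptance_rate=acc_rate,
    )


def percent_increase_summary(fit: PoissonFit, k: int = 5) -> dict:
    """Percent change in expected site count implied by the fitted slope.

    ``per_class``: one class up. ``bottom_to_top_5step``: exp(5 beta) - 1, the
    compounding convention that pairs a 50% per-class increase with a ~657%
    bottom-to-top increase. ``bottom_to_top_4step``: exp(4 beta) - 1, the
    literal class-1-to-class-k step count for k = 5. Both are reported.
    """
    b = fit.slope
    return {
        "slope": b,
        "per_class": 100.0 * (np.exp(b) - 1.0),
        "bottom_to_top_5step": 100.0 * (np.exp(5 * b) - 1.0),
        "bottom_to_top_4step": 100.0 * (np.exp((k - 1) * b) - 1.0),
    }
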