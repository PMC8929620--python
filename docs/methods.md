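# Methods

## Model

The potential value of a cell is a weighted average, over known (training)
sites, of how typical the cell's terrain is of each site's surroundings.
Three modelling commitments define the method:

1. **Local empirical distributions, not global fits.** Each training site
   contributes only the empirical value distributions of the landscape
   variables inside its circular sampling area (CSA, default 1 km diameter —
   roughly 3,500 cells at 15 m resolution). Nothing is assumed about the
   parametric form of "suitable terrain"; a site surrounded by atypical
   terrain simply contributes its own atypical distributions.
2. **Typicality as two-sided mid-ECDF.** The similarity of a target value
   `x` to a CSA sample is `p = 2·min(F(x), 1−F(x))` with the
   mid-distribution ECDF `F(x) = (#{u<x} + ½#{u=x})/n`, clipped to
   `[ε, 1]`. This is distribution-free, equals 1 at the sample median,
   decays monotonically toward the tails, and has an obvious counting
   oracle — the property the test suite leans on. The original
   implementation's estimator is published elsewhere and not restated in
   the sources available here, so this functional form is this package's
   own choice, selected for those properties; it is a surrogate, not a
   claim about the original code.
3. **Law-of-total-probability combination.** Per-variable similarities
   multiply into a per-site joint probability (accumulated in log space);
   per-site probabilities are averaged with inverse-distance weights
   `w_s ∝ max(d, d_floor)^(−α)` normalized to 1. The weighting exponent and
   floor are likewise unstated in the sources; α = 1 with a one-cell floor
   is the package default.

The per-variable product treats variables as independent given the site,
which is why the stack is decorrelated first: the six standardized layers
are rotated by correlation PCA and the model runs on the retained principal
component scores only (95% cumulative variance by default; configurable,
including keep-all). Correlation rather than covariance PCA because the
layers have incommensurate units. Eigenvector signs follow a deterministic
convention (largest-magnitude loading positive) so runs are bit-reproducible.

## Terrain derivatives

* **Slope/aspect** — Horn 3×3 weighted differences at interior cells,
  one-sided differences on the border ring (exact for planes everywhere).
  Aspect is the compass bearing of the downslope direction; gradient-free
  cells get nodata aspect and are excluded from CSA samples per-variable.
  Aspect's circularity (0° ≡ 360°) is handled *linearly*, a known caveat:
  north-facing cells near 0°/360° are artificially split. An optional
  `decompose_aspect` transform replaces the layer with its sine/cosine
  components; it is not the default and is not claimed to match the
  original analysis.
* **Drainage** — D8 steepest descent (drop per unit distance, diagonals
  √2), ties broken by the fixed neighbour order E, SE, S, SW, W, NW, N, NE;
  pits and flats drain nowhere. Drainage cells are those whose accumulation
  reaches 1% of the valid cell count (configurable; the extraction
  threshold is not stated in the sources). Distance to drainage is the
  exact Euclidean cell-centre distance (`scipy.ndimage.distance_transform_edt`).
  No pit-filling happens inside the flow operator itself; an optional
  priority-flood filler (with an optional epsilon gradient) is available
  and is used by the synthetic generator (below).
* **Cumulative viewshed** — observers on a square grid (default 1,000 m
  spacing, registered at the raster origin, snapped to containing cells) at
  1.6 m eye height; a target is visible when no bilinearly interpolated
  terrain sample along the sight line (sampled every cell width) rises
  above the eye-to-target line. Grazing contact counts as visible. Bare
  earth only: no vegetation, no earth curvature. The sight radius is capped
  (default 5 km; 2 km in the synthetic scenarios) to bound cost; an
  unlimited radius is a cluster-scale computation.
* **Convexity** — fraction of cells in a (2r+1)² window (default r = 5)
  that sit above their complete-8-neighbour mean by more than a flat
  tolerance (default 0, with a magnitude-scaled 1e−9 guard so exact ties on
  planes never count). This is an Iwahashi–Pike-style surrogate for the
  named GIS tool's "terrain surface convexity", which documents no formula.

## Classification and validation

Quintile classes are rank-based over all valid cells: stable ascending sort
(ties broken by row-major order), the first `n mod k` classes take
`⌈n/k⌉` cells, the rest `⌊n/k⌋` — class sizes are equal to within one cell
regardless of ties, and runs are deterministic. Training-CSA cells are
included in both the surface and the binning (they are scored identically
to all other cells).

Validation counts held-out sites per class and fits a log-link Poisson
regression of count on the numeric class value 1..k. Class enters as a
number, not a factor, so "one class up" has a single slope β. Two fitting
paths: IRLS maximum likelihood (statsmodels, score-equation residual
verified ≤ 1e−8) and random-walk Metropolis with independent normal(0, 10²)
priors, 20,000 iterations, 10% burn-in with Robbins–Monro proposal
adaptation toward 30% acceptance, fully seeded. No exposure offset is
needed: quintile classes have equal cell counts by construction.

Percent-increase summaries are reported in **both** step conventions:
`100·(exp(5β)−1)` (the compounding convention that pairs a 50% per-class
increase with ~657% "bottom to top") and the literal four-step
`100·(exp(4β)−1)` (~405% for the same fit). The five-step figure matches
the published pairing; the four-step one is the arithmetic reading of
"class 1 to class 5". Both appear, labelled, in every fit summary.

### A documented irreproducibility

For the published Random analysis (counts 6, 19, 21, 25, 21 per class) the
Poisson score equations give β = 0.199, a **22.0%** per-class increase —
not the published 12% (nor does any β consistent with those counts give
12%). The MLE here is asserted against an independent 1-D profile-score
grid search, and the discrepancy is reported as a property of the published
summary, not tuned away. The pre/post analysis (0, 4, 8, 13, 8) reproduces
exactly: β = 0.405, 49.9% ≈ 50% per class, 658% over five steps. Relatedly,
the published text says 60 post-10,000 cal BP test sites while the printed
column totals 33; the column total is treated as authoritative because it
is what the regression consumes.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any specific geography:

* **Terrain** — spectral synthesis: white Gaussian noise shaped by
  `f^(−η/2)` in frequency space (η ∈ [1, 4], default 3, a fairly smooth
  fractional-Brownian-like surface), rescaled to a 300 m relief. The raw
  surface is then conditioned by epsilon-gradient priority-flood filling
  (ε = 1 mm) so a connected drainage network exists — real valleys drain;
  unconditioned spectral noise is pocked with closed depressions that starve
  D8 accumulation.
* **Scale** — 128 × 128 cells at 60 m (a 7.7 km square). The cell size is
  deliberately coarser than the 15 m the full-scale analysis uses: what
  matters statistically is that the 1 km CSA is small relative to the
  landscape (as it is in a ~7,000 km² study region); at 15 m a desk-scale
  grid would be 1.9 km across and every CSA would cover half the map,
  erasing spatial contrast. CSA-geometry checks that depend on the 15 m
  resolution build their own 15 m grids.
* **Sites** — cell selection probability ∝ `exp(−β_pref · ‖z − a‖)` where
  `z` is the cell's per-layer z-score vector and `a` the archetype (default:
  elevation +1 sd, drainage distance −1.5 sd, convexity +1 sd — elevated
  ground close to water). β_pref = 0 is uniform placement. Sampling is
  without replacement with a two-cell minimum separation and within-cell
  jitter; validation draws exclude training cells, so train/test sets are
  disjoint by construction. Default split: 20 training / 40 validation
  sites.

What the generator does **not** emulate: loess deposition, vegetation,
taphonomy, survey bias, temporal change — passing recovery tests shows the
*pipeline* can detect a terrain preference of the assumed kind, not that
real site distributions have one.

## Problem sizes and numerics

The test suite and the analysis scripts run desk-scale configurations:
oracle-equivalence checks on grids ≤ 50×50 against nested-loop references
(agreement to 1e−12 for the surface, exact for counts and distances), and
parameter recovery over 20 seeds per preference strength at 128×128 with
the 2 km viewshed radius. Epsilon floor ε = 1e−6 per variable keeps joint
probabilities away from false zeros; products are accumulated as log sums.
`float64` throughout; Esri ASCII output uses `%.6g`.

## Limitations

* The similarity estimator, distance-decay form, drainage threshold and
  retained-component count are this package's own defaults where the
  sources are silent; all are exposed in configuration.
* Linear treatment of aspect biases similarity for north-facing terrain.
* D8 routing concentrates flow on single cell chains; braided or flat-basin
  drainage is not represented.
* The viewshed's stepwise-sampled line of sight is O(radius) per
  observer-target pair; it is chosen for oracle-checkability, not speed,
  and full-region radii at 15 m resolution are out of desk-scale reach.
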