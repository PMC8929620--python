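# lamap — locally-adaptive archaeological potential surfaces

`lamap` models **archaeological potential**: given a digital elevation model
and the coordinates of known archaeological sites, it scores every map cell
by how similar its terrain is to the landscape immediately around the known
sites. It is a *presence-only* method — no absence data and no background
contrast are required — aimed at survey planning and heritage management:
the output is a continuous probability-like surface in [0, 1] and a
five-class ordinal map (1 = lowest potential, 5 = highest) of where
undiscovered sites are most likely to be found.

## The model

Six landscape variables are derived from the DEM: elevation, slope, aspect,
distance to drainage, cumulative viewshed and convexity. Around each known
site *s*, a **circular sampling area** (CSA, 1 km diameter by default)
provides an empirical value distribution per variable. For a target cell
with value *x* in variable *v*, the similarity to site *s* is a two-sided
mid-distribution ECDF typicality

```
F(x) = (#{u < x} + ½ #{u = x}) / n,     p_v(x) = max(ε, 2 · min(F, 1 − F))
```

which is 1 at the CSA median and decays toward the tails. Per-variable
similarities multiply (in log space) into a per-site joint probability
`p_s = Π_v p_v`, and per-site probabilities combine over all sites by the
law of total probability with inverse-distance weights,

```
L(cell) = Σ_s w_s · p_s ,   w_s ∝ max(d(cell, s), d_floor)^(−α),  Σ w_s = 1 .
```

Before scoring, the six standardized layers are rotated to principal
components (95% variance retained by default), which decorrelates the
variables and keeps products of small probabilities away from floating-point
underflow. The surface is binned into equal-count quintile classes, and the
model is validated by counting *held-out* sites per class and fitting a
log-link Poisson regression of count on the numeric class value 1–5: a
positive slope β means one class step multiplies the expected site count by
`exp(β)`.

Because the real site coordinates that motivated this pipeline are redacted
in the public record, the package ships a first-class synthetic-data module:
spectral-synthesis terrain, the full derivative stack, and site placement
biased toward a configurable terrain archetype (default: elevated ground
close to drainage) with a recoverable preference strength.

## Worked example

```python
from lamap.synthetic import ScenarioConfig, SitePreference, make_scenario
from lamap.pipeline import evaluate_scenario

cfg = ScenarioConfig(preference=SitePreference(strength=3.0), seed=1)
scenario = make_scenario(cfg)          # 7.7 km synthetic landscape, 20 train / 40 validation sites
res = evaluate_scenario(scenario, regression="both", seed=1)
print(res["fits"]["counts"])
print(round(res["fits"]["mle"]["per_class"]))
```

prints

```
[0, 5, 4, 7, 24]
117
```

— the 40 held-out sites pile into the high-potential classes, and the fitted
Poisson slope (0.773) says each one-class step multiplies the expected site
count by ~2.17, i.e. a 117% per-class increase. On scenarios with preference
strength 0 the fitted slope is centred on zero (see
`analysis/06_parameter_recovery.py`).

The numbered scripts under `analysis/` walk the same pipeline step by step —
simulate, derive terrain, score, classify, validate — and
`analysis/05_tabled_count_regressions.py` refits the published per-class
validation counts from the middle Tanana Valley case study:

```
prepost: counts [0, 4, 8, 13, 8]
  MLE slope 0.4050 -> per-class 49.9%, 5-step 658%, 4-step 405%
```

Small tables land in `results/`; bulky rasters in `scratch/`. A `lamap`
console script exposes the same steps
(`lamap synth | terrain | surface | classify | validate | regress | run`).

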