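# Methods

`deepsdm` implements a presence-background species-distribution-modelling
(SDM) workflow for deep-sea benthic taxa, together with a virtual-species
test-bed that makes every stage verifiable against analytic ground truth.
This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic validation does and does not
demonstrate.

## Occurrence cleaning

Records carry a species name, WGS84 coordinates, a sampling depth
(metres, positive down) and a year. The cleaning rules, applied as
record-wise predicates followed by one species-level rule:

1. **Study window** — latitude in [56, 80]°N, longitude in [45°W, 45°E]
   (defaults; configurable via `StudyWindow`).
2. **Deep sea** — depth strictly greater than 200 m. "More than" is read
   as a strict inequality; a record at exactly 200 m is removed.
3. **Study period** — year in [2000, 2020], inclusive on both ends.
4. **Benthic validation** — the recorded depth is compared with the
   bathymetric depth of the grid cell containing the point
   (nearest-cell lookup, no interpolation). A record is kept iff
   `|depth − bathy| / bathy ≤ 0.05`. The bathymetric depth is the
   denominator because it is the reference surface. Records outside the
   bathymetry extent are removed and logged.
5. **Minimum sample size** — species with fewer than 200 surviving
   records are excluded (threshold inclusive: exactly 200 is kept).

Records missing depth or year are removed, since rules 2–4 cannot be
evaluated for them; this is conservative and every removal is written to
a per-record audit table. Record-level filters commute and are
idempotent, so their order does not affect the surviving set; the
species-level rule runs last so inclusion reflects usable records. No
spatial thinning or deduplication is applied.

## Environmental stacks and predictor screening

Covariate layers are regular lat/lon grids, north-up, with NaN as the
missing-data mask. Layers in a stack must be exactly aligned; the
package never resamples silently. Stacks are keyed by scenario: the
current baseline (2000–2020) or a future decade (2050–2060, 2090–2100)
crossed with an SSP (1-1.9, 2-4.5, 5-8.5) — seven keys in total.
Rasters are serialised as ESRI ASCII grids, a plain-text format
readable by standard GIS tools.

Multicollinearity is screened with the variance inflation factor,
`VIF_j = 1/(1 − R²_j)` with `R²_j` from regressing covariate j on the
others (equal to the j-th diagonal of the inverse correlation matrix).
Selection is greedy: while any VIF exceeds the threshold, drop the
largest (ties broken by dropping the alphabetically last name, which
makes the result invariant to column order) and recompute. The default
threshold is 5, a common conservative choice in SDM practice; exact
collinearity is reported as +inf rather than crashing.

## Sampling-bias correction (target-group background)

Marine occurrence data are collected where ships go, not where species
live. The correction estimates relative sampling effort from the pooled
presences of *all* modelled species (the target group) by kernel density
estimation with a quartic (biweight) kernel,

    K(d) = 3/(π h²) · (1 − (d/h)²)²  for d < h, else 0,

with bandwidth h = 100 km by default and great-circle distances on a
sphere of radius 6371.0088 km (projection-free, appropriate at basin
scale). Each point's kernel integrates to one over the plane. The raw
density is evaluated at cell centres of the environmental grid; using
the environmental grid rather than a finer one does not change which
covariate cell a background point lands in, and a finer `GridSpec` can
be supplied where wanted.

Never-sampled cells would get zero probability and become unreachable,
so zero cells are floored at (smallest positive cell value)/100 before
the surface is normalised to sum to one. Background points (50,000 by
default) are drawn i.i.d. with replacement from the cell multinomial and
jittered uniformly within their cell. One background set is shared by
every species' model.

**A consequence worth knowing:** because the background carries the same
spatial bias as the presences, apparent discrimination (AUC) is lower
than it would be against a uniform background — the model is asked to
distinguish a species from places that were *sampled*, not from the
whole region. Cross-validated AUCs around 0.8 on well-specified
synthetic species (below) reflect this, not model failure. The method
also assumes the pooled target-group distribution reflects effort rather
than a shared environmental response; when the whole community prefers
the same conditions, part of the focal species' signal is absorbed into
the background.

## MaxEnt

The model is the standard presence-background Gibbs formulation. Over
background cells b, `q_λ(b) = exp(λ·f(b))/Z_λ`, and the weights minimise
the penalised negative presence log-likelihood

    J(λ) = −(1/m) Σ_i λ·f(x_i) + log Σ_b exp(λ·f(x_b)) − log B
           + Σ_j β_j |λ_j|,

with per-feature penalties `β_j = multiplier × 0.5 × s_j/√m`, where
`s_j` is the feature's standard deviation over the presence rows and the
regularisation multiplier defaults to 2 (values 2–4× the conventional
default mitigate overfitting in habitat modelling). Features are
forward/reverse hinges at 30 evenly spaced quantile knots per covariate,
scaled to [0, 1] on the training range — hinge-only bases give
spline-like response curves.

Numerics: J is convex; the L1 term is made smooth by splitting λ into
positive and negative parts and the bound-constrained problem is solved
with L-BFGS-B (objective tolerance 1e-7, iteration cap 10,000, weights
box-bounded at ±200 — with features in [0, 1] larger weights are
numerically meaningless). `s_j` is floored at 1e-3 so a presence-constant
feature cannot receive a zero penalty. On problems small enough to
enumerate, the fitted weights match an exhaustive grid minimisation of
J to 1e-3 (this is a standing test). Weights below 1e-10 are snapped to
zero. The fit is deterministic given its inputs.

Suitability is reported through the complementary log-log transform
`1 − exp(−e^H r(x))`, where `r(x) = exp(λ·f(x) − log Z)` is the relative
occurrence rate and H the entropy of the fitted background distribution.
A uniform model scores exactly `1 − 1/e ≈ 0.632` everywhere; a logistic
variant and the raw rate are available by flag. Note the transform is a
monotone recalibration: the score 0.70 does not correspond to a true
occupancy probability of 0.70, and thresholded areas are operational
quantities, not occupancy areas.

Evaluation uses rank-based AUC (Mann–Whitney; ties count half) under
k-fold cross-validation (default k = 3) with presences and background
partitioned independently into random, seeded folds. Spatially blocked
folds are out of scope.

## Projection and habitat analytics

Models are projected cellwise onto scenario stacks. Covariates outside
the training range are clamped to the nearest bound by default (the
standard guard against hinge extrapolation; disabling it is logged).
Suitable area at threshold τ = 0.70 (inclusive, configurable) sums
spherical cell areas `R² Δλ (sin φ_top − sin φ_bottom)`, which tile the
sphere exactly. Across-species summaries report mean, min, max and
quartiles (linear interpolation between order statistics). A species is
a *consistent loser* when its area is strictly below the current-scenario
area in all six future scenarios, a *majority loser* at five of six;
equality never counts as loss. Richness maps count species at or above τ
per cell; delta maps subtract present from future richness.

## The virtual-species generator

Covariate fields are Gaussian-smoothed white noise (smoothness length in
cells, default 5–6), standardised, mixed through the Cholesky factor of
a target correlation matrix (so collinearity is controllable for VIF
testing), and re-standardised. Bathymetry is an independent smooth
positive field (default mean 1200 m, sd 500 m, floored at 250 m).
Sampling effort is a configurable positive field, by default Gaussian
hotspots on a constant baseline — survey effort clusters around ports
and repeat transects, but its true spatial form is unknown, so only
strict positivity is relied upon.

A virtual species has the product-Gaussian niche
`s(x) = exp(−Σ_j (x_j − μ_j)²/(2σ_j²))`. Presence cells are drawn with
probability ∝ s × effort and jittered within the cell; clean records get
a depth within ±4% of bathymetry (comfortably inside the 5% rule) and a
year uniform in the study period. Contaminated records violate exactly
one rule each: depth mismatched by ≥20% (never ambiguous against the 5%
boundary), coordinates south of the window, years strictly before 2000,
or depths at most 190 m. A truth sidecar records each record's status,
and on such data the cleaning filters recover the clean set exactly —
also a standing test.

Scenario shifts are affine per-covariate maps (`x·scale + offset`); the
true suitable-area change is computed by direct evaluation of the niche
on both stacks, giving every projection test an analytic target. The
generator emulates controllable correlation, smoothness, bias and
contamination, but not ocean physics, variable semantics, temporal
autocorrelation, or taxonomic error; passing tests demonstrate the
*machinery* is correct under known conditions, not that real amphipod
projections are accurate.

## Validation experiments

Two canned studies in `deepsdm.validation` double as acceptance checks:

* **Niche recovery** — 20 random virtual species on a 100×100 grid
  (≈0.2° cells spanning 58–76°N, 40°W–10°E), 4 covariates with 0.3
  cross-correlation, 400 presences each under hotspot bias, one shared
  5,000-point target-group background, hinge MaxEnt with multiplier 2,
  3-fold CV. Typical results: median Spearman correlation between true
  and predicted suitability ≈ 0.93, mean CV AUC ≈ 0.80 (capped by the
  bias-matched background, as discussed above).
* **Habitat-loss sign recovery** — 20 replicates; each builds a fresh
  50×50 world with one central focal species and 19 context species
  whose optima are spread wider (±2 sd) than the field support, so the
  pooled background reflects effort rather than a shared niche (the
  target-group assumption). The applied covariate shift is the smallest
  0.25-sd step that shrinks the focal species' *true* suitable area by
  more than 20% at thresholds 0.25, 0.5 and 0.7 simultaneously — a
  uniformly contracting niche. Requiring contraction at all shells
  matters: the cloglog 0.70 level set sits at a lower true-suitability
  shell, so a shift that shrinks only the true 0.70 shell while growing
  lower shells probes threshold calibration rather than trend detection.
  Detection (projected future area below current area in all six future
  scenarios) succeeds in ≥ 95% of replicates across the seeds tried.

Problem sizes throughout (grid dimensions, species counts, replicate
counts, the 1,500–5,000-point backgrounds in tests) are the package's
choices for routine validation; all are parameters and scale up freely.

## Reproducibility

Every source of randomness flows from one integer seed. The pipeline
derives per-stage, per-species sub-seeds as the first four bytes of
`BLAKE2b(f"{seed}|{stage}|{species}")` (mod 2³¹), so a species' results
do not change when other species are added or removed. Reruns with the
same configuration are byte-identical (timestamps aside); CSV floats are
written with a fixed `%.10g` format and rasters with fixed-format ASCII
for that reason.

## Known limitations

* No spatial cross-validation; random folds overestimate transferability
  under strong spatial autocorrelation.
* The 0.70 suitability threshold is an operational convention on a
  relative score, not an occupancy probability.
* The benthic rule assumes point depths; depth-interval records are not
  modelled.
* Taxonomic curation (e.g. excluding known pelagic species by trait) is
  expert work outside the package; only the depth-mismatch rule stands
  in for it.
* The generator's fields are stationary Gaussian surrogates; real ocean
  covariates have fronts, trends and shared physical drivers it does not
  mimic.
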