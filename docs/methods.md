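# Methods

## Geometry and gridding

All analysis happens in a local planar frame: an equirectangular
projection about the farm's reference point (x = R·cos φ₀·Δλ,
y = R·Δφ, R the mean Earth radius, 6 371 008.8 m). Over a site of a few
hundred meters the planar distance differs from the great-circle
distance by well under 0.05 % — far below GPS noise — so no geodetic
library is needed and the projection inverts exactly. Points more than
0.05° (~5.5 km) from the origin are rejected rather than silently
distorted.

The occupancy grid is anchored at the south-west corner of the farm's
planar bounding box, axes east/north, cell size 3 m (the conventional
neck-collar contact distance for horses, and the resolution at which a
resource zone spans a handful of cells). Cells are half-open intervals;
a point on a shared edge belongs to the higher-index cell, so assignment
is a total function. One extra row/column keeps the closed upper
boundary inside the grid.

Squares are labelled by **cell-center containment**: a square belongs to
the resource zone containing its center, else to PADDOCK or PASTURE by
containing polygon. The alternative (area-overlap majority) differs only
for the ring of cells straddling a zone border; with 3 m cells against
multi-meter zones the difference is marginal and the center rule is
deterministic and fast. Resource zones are tested in a fixed label order
so overlapping declarations cannot produce nondeterminism.

## Cleaning cascade

Order: (1) farm bounding-box clip (box = farm extent + 15 m margin);
(2) speed/step outlier removal; (3) clip to paddock ∪ pasture (or
paddock only for the "paddock only" variant). The order is a package
decision; the bounding box removes gross teleports cheaply, the
sequential step filter removes the rest, and the polygon clip defines
the dataset variant.

The step filter recomputes distances from coordinates (great-circle on
the mean-radius sphere) rather than trusting the device's distance
column, so filtering is consistent with the projection used for
gridding; the device column is kept for audit. Removal is **sequential
with anchor update**: each fix is tested against the last *retained*
fix, so a single spike cannot cascade into removals of the valid fixes
that follow it. Thresholds default to 50 km/h and 140 m per 10 s
(physiological bounds for horses); the distance threshold scales
proportionally with the time gap, so a 30 s gap allows 420 m. Horse-days
losing more than 20 % of their rows to parse errors or filter removals
can be flagged as demolished/ill-adjusted loggers
(`flag_demolished_days`).

## Responses

**Squares per hour** (model-1 response, one value per horse-day):
distinct squares occupied within each local clock hour, averaged over
hours holding at least 90 % of their expected fixes (324 of 360 at
0.1 Hz). The hour-coverage floor keeps sparse hours from biasing the
mean; a square revisited in two hours counts in both. The alternative
reading — total distinct squares per day divided by hours — is available
via `method="per_day_ratio"`. A day enters the analysis only with at
least 12 h of recording, i.e. ≥ 4320 fixes (inclusive boundary), applied
per dataset variant.

**Usage frequency** (model-2 response, one value per square-day):
100 × (fixes in square)/(all horses' fixes that day). Frequencies sum to
100 per day by construction. Only visited (square, day) rows are
materialised and modelled; the visited-square universe size is reported
separately. Per-location summaries average a label's frequency over all
of the label's squares (unvisited squares count zero), then over days;
locations with no squares are absent, not zero.

## Models

Model 1 is a linear mixed model with fixed breed class, sex, observation
day and age covariate, plus a random per-animal intercept; since each
animal belongs to exactly one breed, a plain per-animal intercept
realises the nesting. Final inference uses REML (statsmodels `MixedLM`);
model comparison during forward stepwise selection uses ML fits, the
standard resolution of the information-criterion-with-mixed-models
ambiguity. AICc = AIC + 2k(k+1)/(n−k−1) with k counting all estimated
parameters including the two variance components; it is undefined for
n ≤ k+1, in which case the candidate is refused with a message in the
selection trace. A term is added only when it minimises AICc among the
candidates **and lowers both AICc and BIC** — using the two criteria in
combination keeps the false-inclusion rate of null terms low (AICc alone
admits a null term with probability ≈ P(χ²₁ > 2) per candidate, which
compounds over candidates and rounds); AICc-only behaviour is available
via `criterion="aicc"`.

Least-square means weight every level of the other factors equally and
hold covariates at their observed mean. Pairwise LSM differences use a
containment-style denominator df (n − rank); raw p-values are multiplied
by the number of pairs, capped at 1, significance at p < 0.05.
Boundary estimates (σ²ₐ → 0) are handled by falling back across
optimizers and accepting a fit only with finite log-likelihood; at an
exact zero estimate the BLUPs are identically zero.

Model 2 is a two-way additive OLS fit (day + location) on visited rows.
Residual excess kurtosis is exposed because the pasture — huge in area,
tiny in per-square frequency, intermittent in access — inflates the
residual tails; removing it shrinks the kurtosis markedly, which is why
the paddock-only variant is the better-behaved presentation.

## Synthetic herd generator

The generator's defaults are the study conditions the pipeline is built
for: 52 horses split 31/6/15 into warmblood/pony/other, geldings and
mares, ages 2–29, 12 newcomers entering after day 1; 227 observation
days (159 summer, 68 winter); one fix per 10 s; pasture access twice a
day for ~90 min in summer (two pastures rotated over the summer halves).
The synthetic farm is a 120 × 90 m paddock (~1 ha) with two adjoining
120 × 44 m pastures and rectangular resource zones (LH_1 the 250 m²
"metal" hall, LH_2/LH_3 160 m² tarp halls, seven feed stalls, three
concentrate stalls, two racks, shelters and troughs); it is a synthetic
stand-in — the real farm's geometry is not published.

Movement is a semi-Markov behavioural machine: exponential dwells at a
resource (rest 45 min, feed 30 min, drink 3 min, stand 20 min, loiter
15 min on average), walking between targets at 1.1 m/s with lateral
jitter, and a correlated random walk (2.5 m per fix) across the pasture
during open windows. Age and a per-horse normal random effect
(σ = 6 squares/h) act **multiplicatively on the state-switch rate**
(dwell means divided by exp(η/25) with η = −0.6·(age − 12) +
animal-effect): their influence on the squares/h response is emergent
rather than painted onto the response, which keeps downstream
parameter-recovery tests honest. The gain of 25 squares/h per log
switch-rate unit makes the realised response slope land near the
configured −0.6 squares/h per year.

The observation process adds isotropic Gaussian GPS noise (σ = 2.5 m,
typical for consumer loggers under open sky), teleport spikes (offset
200–500 m with probability `spike_prob`, recorded as ground truth),
Bernoulli dropouts, and optional contiguous outage blocks (6–20 h)
emulating battery swaps and demolished collars, which produce the
below-12 h days the inclusion rule removes. Randomness is keyed as
(root seed, horse, day), so any subset of horses or days replays
byte-identically.

What the generator does **not** emulate: social interactions (dominance,
herding, synchronous feeding), diurnal activity rhythms beyond the
pasture windows, weather, multipath-correlated GPS error, or owner
interventions (walks outside the paddock). Passing tests therefore
demonstrate that the pipeline's computations are correct and that the
inference machinery recovers effects of the built-in kind — not that the
behavioural model reproduces real herd dynamics.

## Numerical and design choices

- Season windows are day-index ranges (default 1–159 / 160–227), not
  calendar parses; the heatmap colour scale saturates at a configurable
  cap (default 0.3 %) so resource hot spots do not flatten the paddock's
  dynamic range, and vector output is byte-stable for identical input.
- Logger CSV dialect is fixed (comma, ISO-8601, period decimal) and
  locale-independent; malformed rows are counted with line numbers,
  never silently dropped; a missing mandatory column is a hard error.
- Day boundaries follow local time, since the 12 h inclusion rule is
  about the husbandry day.
- Problem sizes in the test and acceptance runs (e.g. 20 horses ×
  60 days for parameter recovery, 5 horses × 3 days for spike recovery)
  are scaled-down studies chosen so between-horse quantities are
  estimable while the suites stay desk-scale.

## Known limitations

- The equirectangular projection and spherical distances are adequate
  only at farm scale; the 0.05° precondition enforces this.
- Cell-center labelling misattributes parts of cells straddling a zone
  border; with 3 m cells this affects only the border ring (flagged for
  sensitivity testing via custom layouts).
- The containment-style df for LSM tests is an approximation; exact
  Satterthwaite df is not implemented.
- Model 2 treats square-days as exchangeable given day and location;
  spatial autocorrelation between neighbouring squares is ignored, as is
  temporal autocorrelation in model 1.
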