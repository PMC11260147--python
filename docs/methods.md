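# Methods

## The synthetic world as a measurement instrument

The package's claims are validated on a generated ocean because the
generating process is then known exactly: every behavioral response the
model is asked to recover is written into the simulator in closed form. The
default world is an 18 × 36 lattice at 10° per pixel (648 pixels, 483 ocean
after a ~25% land mask grown as contiguous blobs; any ocean pocket not
4-connected to the main body is filled so the shortest-path metric is
defined everywhere). Pixel areas use the spherical band formula
R²·Δλ·(sin φ_top − sin φ_bot) with R = 6,371 km; on the full-sphere default
they sum to 4πR² to machine precision. Static layers emulate the structure
real features would have: EEZ bands with sovereign labels around coastal
anchors (the remainder `high_seas`), ports on the coast, seamount points,
depth increasing away from shore, two smooth AIS-reception fields, six
ocean basins, and three latitudinal mesopelagic zones.

Environmental covariates are emitted as pixel-year means and standard
deviations, emulating aggregation from finer-resolution sources: SST with a
latitudinal gradient plus an interannual anomaly loaded on a shared
ENSO-like annual index (plus a second, PDO-like index), chlorophyll, wind,
and a global fuel price. All interannual variation scales with a single
parameter so a zero value freezes the fields across years; by construction
the field-mean SST anomaly correlates > 0.8 with the first index.

## Effort generator and its behavioral response

Effort is hurdle-structured: occurrence ~ Bernoulli(logistic(attractiveness))
and positive intensity lognormal (σ = 0.5 on the log scale) around an
attractiveness- and environment-driven mean, times pixel area. The default
intercepts give roughly one-third structural zeros and positive pixel-year
hours in the hundreds-to-thousands range. A 2%/year multiplicative drift
stands in for secular growth.

MPAs act through one expected-hours multiplier m per pixel-year:

* inside: m = 1 − delta_inside · compliance · c_eff, where c_eff is the
  union coverage with each record scaled by its in-force fraction of the
  year (implementation day through Dec 31, leap-aware);
* outside: m = 1 + delta_outside · exp(−d / decay_km), d the land-avoiding
  distance to the nearest implemented record (strongest record wins, each
  scaled by its in-force fraction);
* anticipation multiplies effort of to-be-covered pixels the year before
  implementation; a fleet (one per EEZ plus one high-seas fleet) exits
  entirely with probability p_fleet_exit once coverage of its grounds
  crosses a threshold (defaults keep both channels off: 0).

m multiplies the conditional intensity; occurrence responds only in the
limit m = 0, where hours are forced to zero. This is a deliberate design
choice: expected hours then scale by exactly m, so the recovery oracle
`ground_truth_effect` — 100·(m − 1) per pixel, no sampling — is exact, and
the response is expressible by a point-predicting hurdle (a response split
across the occurrence odds would be invisible to a thresholded classifier
except as all-or-nothing flips). Defaults: delta_inside = 0.8 with full
compliance (an 80% suppression), delta_outside = −0.3 with a 1,200 km
e-folding — a decrease outside MPAs, strongest near the boundary, consistent
with effort declining rather than concentrating at the line.

The historical schedule places ~16 blob MPAs (cores fully covered, one
partial-fraction edge pixel each) totalling ~12% of the ocean, implemented
in staggered cohorts across every interior year at a uniformly drawn day of
the year. Three aspects are identification design, not realism tuning: (i)
cohorts in every training year give each cross-validation fold fresh
implementations; (ii) uniform implementation days create training rows
whose lagged effort is only partially suppressed while their coverage
features read "fully inside", which is exactly the feature region scenario
prediction visits (new closures on currently fished pixels); (iii) the
coverage share is far above the real world's ~2.5% because a 483-pixel
ocean at 2.5% would hold ~12 treated pixels, too few to learn from. What
passing recovery tests on this world shows is that the pipeline can extract
a behavioral response that is identified in the training data; it does not
show that 6 years of real AIS data identify the real response equally well.
The generator also omits vessel-level behavior, gear types, real coastlines
and bathymetry, and spatial error correlation.

## Features

43 features in 8 groups are computed per ocean pixel-year (MPA
implementation 11, environmental 12, geographic 7, governance 6, economic 3,
technological 2, residual 2 — lagged log effort and year). Conventions that
the sources leave open:

* Neighborhood coverage uses Moore rings (ring 1 and ring 2), area-weighted.
* All distances (MPA, EEZ boundary, port) are shortest paths on the
  8-connected ocean graph with great-circle edge weights; travel through
  land is impossible by construction. Longitude wraps when the grid spans
  360°.
* Overlapping MPAs combine as a union, never a sum: polygon records are
  unioned geometrically; fraction-only records combine as 1 − Π(1 − f)
  (independent-overlap convention), bounded by 1.
* `years_since` uses the oldest covering record; outside pixels inherit it
  from the record owning the nearest covered pixel. Before any MPA exists,
  distance takes a constant sentinel (twice the maximum pairwise ocean
  distance) and `years_since` = −1.
* The lagged log-density feature floors zero-effort rows at (minimum
  positive log in the fitting data − 1); stage 2 never trains on zero rows,
  so the floor only enters as a predictor. Natural logs throughout.
* EEZ sovereigns holding < 1% of training pixels collapse to `other`;
  non-EEZ pixels are `high_seas` with fraction 0.
* Categorical levels, the lag floor and the sentinels are frozen in a
  hashed schema at training time and reused verbatim at prediction time.

## Model protocol

Datasets are built per horizon t by pairing features at year y with effort
at y + t; the last outcome year is the temporal test set, and rolling
one-year folds (analysis = the preceding pair-year, assessment = the next;
a cumulative variant is available) tune the two tree hyperparameters over a
seeded 10-point maximin Latin-hypercube grid — mtry over [1, encoded
width], minimum node size over [2, 40]. Stage 1 maximizes mean across-fold
ROC AUC; stage 2 maximizes mean across-fold `rsq_trad` computed on smeared,
backtransformed level predictions with the smearing coefficient refit
inside each fold from its analysis split. The classification threshold
scans an exhaustive candidate set — midpoints of sorted unique predicted
probabilities plus one candidate below the minimum and one above the
maximum, so every achievable confusion matrix is reachable — and takes the
smallest τ maximizing mean across-fold F1. Ties in the grid break toward
smaller mtry, then larger node size, then grid order. The learner contract
is pluggable; a logistic + linear pair (no grid, threshold still tuned)
serves as the robustness comparator, alongside lag-only variants of both
learners.

Leave-one-ocean-out splits hold out one basin's final-year rows and train
on earlier years of the other basins only. A leakage audit asserts that no
(pixel, outcome-year) pair crosses a train/assessment boundary; the four
future-coverage flags intentionally use implementation dates from the
network (announced closures), never effort data.

## Scenario engine

Hypothetical networks close fully protected pixels at the start of the base
year (the last simulated year): ranked rules share one seeded ranking per
world, so targets are nested; ties in the most-fished ranking break by
pixel id. Scenario features are recomputed under union(baseline,
hypothetical) with years-since 0, fraction-of-year 1, and no future flags;
BAU uses the baseline network alone, so an empty or duplicate scenario
reproduces BAU bit-exactly. Differences are reported pixelwise and
aggregated globally, by region (inside / partial / outside), and by
distance bins (defaults: inside, then 0–1, 1–2, 2–4, > 4 pixel-widths);
aggregate percent change is the change of the sums, and pixels with zero
BAU prediction are excluded from pixel-level percent change (counted, never
imputed) but kept in all sums.

The recovery and ordering checks use the one-year horizon: its scenario
rows (new closure, unsuppressed lag) have the closest training analogues,
and it is the analogue of a one-year-after vs one-year-before comparison.
Longer horizons respond in the same direction but more weakly — the same
attenuation the lag feature induces in any autoregressive counterfactual —
which is a documented limitation, not a target of the tests.

## Shapley attribution

Per stage (probability scale for stage 1, log-intensity for stage 2),
Shapley values are estimated by permutation sampling with background
marginalization: along each random feature ordering, features switch from a
background row's value to the foreground row's, and the prediction
increments are credited and averaged over the full background and over
orderings. Because each ordering telescopes, base + Σφ equals the
prediction exactly for any sampling budget; the budget only controls the
variance of the per-feature split. Group attributions sum member features
per observation (additivity), reported as mean |group value| over the
foreground; the default eight groups keep previous effort and year as
singletons. Group magnitudes are scale-dependent and must not be compared
across stages.

## Numerical choices and degenerate inputs

Seeded determinism end to end: every stage derives a substream from one
master seed (hash-based, < 2³¹). Unreachable ocean pixels get +inf distance
with a warning. Single-class folds are skipped in tuning with a warning
(error if all are). τ falls back to 0.5 with a warning if no threshold
yields a true positive. `rsq_trad` and `nrmse` (sample SD, n − 1) refuse
constant outcomes. Metric scopes that are empty or single-class are omitted
with a note rather than imputed.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run on a single CPU in minutes: 648 pixels × 6 years, 500-tree forests,
10-point grids, three seeds for the stochastic recovery checks, and reduced
Shapley budgets in the demo pipeline (the estimator's accuracy guarantees
are exact at any budget; sampling noise only widens per-feature splits).
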