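# Methods

## Seasonality and abundance

A calendar date `d` is mapped to a signed day offset from a per-species
marker date `m`, wrapped into `(−365/2, 365/2]` so dates at opposite ends
of the calendar year are seasonally close. Three conventions turn the
offset into a score:

* `angular` (default): `cos(2π · offset/365)` ∈ [−1, 1]. This is the
  working transform: it is periodic, bounded, and can take the negative
  values that below-threshold rules need.
* `literal`: `cos(offset/365)`. With wrapped offsets this is always
  ≥ cos(0.5) ≈ 0.878, so no rule thresholded below zero can ever fire; it
  is retained for audits of the arc-length reading, not for modelling.
* `linear`: `offset/182.5` ∈ (−1, 1], the signed solar day itself. The
  synthetic generator evaluates its truth curves on this axis, because a
  species' presence window is most naturally expressed in solar days.

The year length is fixed at 365; leap days fold into the cycle. Abundance
weights each proximity band's count by `1/proximity`, so a bird in the
band adjacent to the runways (proximity 1) counts fully and one four bands
out counts a quarter. Harassed birds count alongside observed birds: a
harassment operation is evidence of presence, often of birds the daily
count missed. Proximity values are positive reals; bands are formed by
exact value equality.

## Kernel-mix expected abundance

The seasonal mean abundance is `Σᵢ gᵢ(s) + Σᵢ sᵢ(s)` with Gaussian
components (peaks: migratory build-up and departure) and
sigmoid-difference bumps (plateaus: a population stable over part of the
year). Component counts (m, n) are user choices per species; the default
m = 1, n = 0 fits a single seasonal peak. Fitting is trust-region least
squares with non-negativity bounds on heights and widths, multi-started
(default 32 restarts) from random initialisations spanning the data's
range and scale; the best SSE wins, and the diagnostics retain every
restart's SSE so the best-of-restarts contract is testable. Bump
evaluation uses the overflow-safe logistic throughout.

## Threshold rules

Strike days are the minority class by two orders of magnitude, so the
logistic fit is preceded by nearest-neighbour interpolation oversampling
of the minority class (synthetic points on segments between a minority
point and one of its k = 5 nearest minority neighbours; a singleton
minority falls back to duplication with a warning). The rule is
single-attribute by design: the attribute with the largest absolute
standardised coefficient, thresholded where the predicted probability
crosses 0.5 with the other attributes at their means. The boundary value
itself classifies *low* — the low branch owns the closed interval — which
is the only internally consistent reading of an inclusive low rule.
Accuracy and F-score are stratified 5-fold cross-validation means, with
oversampling applied inside training folds only so no synthetic point
leaks into a test fold. Rules may carry a seasonality split (the
hunting-mode pattern of a resident raptor): days are dispatched to one of
two branch rules at a split value, the boundary going to the low branch.

## Bayesian network

Networks are small by construction (about a dozen nodes, at most three
states), so the engine materialises the full joint by broadcasting CPTs
and conditions on evidence slices — exact inference at negligible cost,
with contradictory evidence raising an error rather than NaN. Complete
data is learned by counting with additive smoothing (α = 1 by default;
rare strike states would otherwise produce zero rows). Missing entries
trigger EM: posteriors over each case's missing nodes are accumulated into
expected family counts, and the observed-data log-likelihood trace is kept
on the result so its monotonicity is asserted in tests. Cross-validation
is stratified on the likelihood node with K = 2 by default; cases are
first put into a canonical content-sorted order so fold membership — and
hence accuracy — is invariant to the order cases arrive in (identical
discrete rows are interchangeable). Prediction is argmax posterior with
ties broken toward the lower state; ROC uses P(highest state) as the
score, and AUC (trapezoid) equals pairwise concordance with half-credit
for ties. Influence strength of an edge is the maximum total-variation
distance between the child's conditional distributions as the parent
varies, maximised over co-parent configurations.

The per-species default structures shipped in `strikerisk/configs/` encode
plausible relations for the three default species (season driving weather
and seasonal/hunting behaviour, counts driving the likelihood); edge lists
are configuration, not a claim about any particular airfield, and users
supply their own YAML for real deployments. The likelihood label reads
"location proximity to runway" as the zone's location-risk weight and
"proximity weight" as `1/proximity`, summed over zones; a single-zone
reading is available via `LikelihoodLabelSpec(mode="single")` for data
where one zone dominates a day's record. Quantile discretisation takes
cutpoints from training data only; ties at a cutpoint go to the lower
state.

## Day typing

Features are z-scored (unbiased sd; zero-variance columns dropped with a
warning) and strike flags are excluded from the feature matrix by
construction. Distances are Euclidean throughout — standardisation makes
that scale-free. The Hopkins statistic is reported in the convention where
values near zero indicate clusterable structure and uniform data gives
about one half: `W/(U+W)` with W the nearest-neighbour distances within a
data sample and U those from uniform points in the data's bounding box.
K recommendations come from the elbow (maximum second difference of WSS,
including K = 1), maximum average silhouette, and the gap statistic
(20 uniform reference sets, smallest K with gap(K) ≥ gap(K+1) − s(K+1)).
K-means is k-means++/Lloyd, best of 10 restarts by WSS. The Dunn index is
minimum between-cluster pair distance over maximum within-cluster
diameter, with a +∞ sentinel for separated zero-diameter clusters. PCA
contributions are squared loadings normalised to 100% per component.

Strike association uses the percentile bootstrap, B = 10,000 by default —
enough that the 3-decimal interval endpoints of a 9-in-761 rare-event
regime are stable across seeds. Overlap between a cluster's CI and the
overall CI is closed-interval intersection; probabilities are reported
with half-up rounding to 3 decimals.

## Synthetic campaigns

The generator emulates the study conditions downstream stages assume: 761
consecutive days, eleven zones (proximities 1–5, location-risk weight
`1/proximity`), three species. Daily totals are negative-binomial — not
Poisson, because flocking species are strongly overdispersed — with mean
from the species' truth kernel mix and a per-species dispersion (size)
parameter; totals are allocated to zones multinomially by preference
weights concentrated near the runways for the migrant and raptor. Harassed
counts are a binomial split of the total, so observed + harassed recovers
the day's true presence. Strike days are Bernoulli with log-odds linear in
the day's realized proximity-weighted abundance; intercepts are calibrated
by deterministic Monte-Carlo root-finding so the expected strike-day count
over the campaign hits the targets such campaigns record (9 for the
migrant, 20 for the raptor, 3 for the flocking species). Weather is a
southern-hemisphere sinusoid with noise (temperature), a seasonally
varying wet-day/gamma mixture (rain), and Poisson aircraft movements.

All draws flow from one seed through substreams named by species and
purpose, so adding a species never shifts another's realisation, and
identical config + seed reproduces byte-identical CSVs. The generator does
not emulate multi-day autocorrelation in counts, observer effort
variation, or within-day timing — so passing tests demonstrate correct
method behaviour under the stated statistical structure, not performance
on any real airfield's data. A planted-regime variant draws each day from
one of two parameter sets and returns the true labels for external
cluster validation.

## Pipeline

The three techniques run in parallel on the same species-day table; the
combined flag is their disjunction (any elevated/high signal flags the
day), the conservative choice when a missed strike costs far more than a
false alert. The clustering technique signals a day when its cluster's CI
is disjoint from the overall CI *above* it. A failed stage is recorded in
the report and exits non-zero, but never suppresses the other stages'
signals. Report files round probabilities to 3 decimals and validity
indices to 2, with fixed column order, so re-runs are byte-identical.

## Problem sizes in the test suite

Simulation-backed tests use campaigns of 120–1,500 days, 200-replicate
calibration checks, n = 5,000 cases for CPT recovery, and brute-force
oracle sweeps at n ≤ 30 — sizes at which the checked quantities' Monte
Carlo error is well inside the asserted tolerances while the whole suite
stays quick on a single core.

## Known limitations

* Threshold extraction is single-attribute by design; interacting
  predictors surface only through the attribute-importance ranking.
* The BN engine targets small discrete networks; it has no structure
  learning and would need factored inference beyond ~15 nodes.
* K-means day types are convex by construction; non-convex day structure
  is out of scope.
* Bootstrap CIs for very small strike counts (k ≤ 2) have coarse,
  granular endpoints; the overlap verdict is correspondingly conservative.
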