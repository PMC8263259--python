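# Methods

This note documents the models, conventions and design choices behind
`birthlink`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Readiness score

A facility's readiness for birth/newborn care is summarized over six domains
(basic EmOC; newborn signal functions and immediate care; general
requirements; equipment; medicines and commodities; guidelines, training and
supervision), each holding 4–15 dichotomous indicators. The domain subscore
is `100 × yes / total`; the overall score is the **unweighted mean of the six
domain subscores**. This is the equal-weighting construction: a 4-indicator
domain and a 15-indicator domain contribute equally when their yes-proportions
are equal. A pooled variant (percentage of all indicators pooled across
domains) is available behind `pooled=True` for sensitivity analysis; the two
differ whenever domain sizes and domain-specific readiness are correlated.
Missing indicator values in real data are treated as "not available" by
default (conservative reading of readiness); `missing_as_no=False`
renormalizes the domain denominator instead.

Terciles (of readiness scores and of population density) are cut at weighted
cumulative thirds using the lower weighted quantile: the boundary is the
smallest value whose cumulative weight fraction reaches 1/3 (resp. 2/3), and
values exactly on a boundary go to the **lower** tercile. Hence a degenerate
all-equal input is labelled entirely "low". Zero or negative total weight is
an error.

## Geographic linkage

* **Haversine distance** uses a spherical earth with radius 6,371 km.
  Coordinates are validated to |lat| ≤ 90, |lon| ≤ 180.
* **Euclidean buffers** are 5 km for urban clusters and 10 km for rural ones
  (inclusive boundary), asymmetric because published cluster centroids are
  displaced up to 2 km (urban) / 5 km (rural, 1% up to 10 km). Links ignore
  administrative boundaries.
* **Least-cost travel time** runs Dijkstra on the friction raster viewed as
  an 8-connected grid graph; the cost of a step between adjacent cells is the
  mean of the two cells' minutes-per-metre values times the step length
  (cell size, ×√2 for diagonals). This is the standard accumulated-cost-
  surface convention; the grid connectivity is a package choice, since
  cost-distance tools differ here. Endpoints snap to their containing cell;
  two points in the same cell are 0 minutes apart. Endpoints off-grid or on
  a barrier cell (infinite friction) yield `inf` — a distinct *unreachable*
  value rather than an exception — as do pairs separated by barriers;
  unreachable pairs are never linked. The time cutoff (default 120 minutes)
  is inclusive. Discretization error on a uniform surface falls below 10%
  when the cell size is halved (asserted empirically in the suite).
* **Walking chain**: a primary router is tried per pair; on failure the
  fallback router is consulted only when the pair is strictly under 50 km
  apart by Haversine; otherwise (and on fallback failure) the pair is
  unreachable. A synthetic router (Haversine × detour factor at 5 km/h, with
  a configurable failure set) stands in for network routers in tests and
  synthetic runs.

All linkage uses the **displaced** coordinates, as an analyst of released
survey data must; the generator retains true coordinates solely for
displacement-misclassification experiments.

## Two-level survey weights

Multilevel fits need weights at both levels, but surveys release a single
normalized individual weight. We de-normalize (scale by population/sample)
and split each de-normalized weight `D_ij` by allocating a share α of its
variation to the cluster level:

```
level2_j  = (mean of D_ij in cluster j)^α        (α = 0.5 default)
level1_ij = D_ij / level2_j
```

so `level2_j × level1_ij = D_ij` exactly for every individual. This
power-split on the cluster mean is an **approximation**: the defining
contract is the α-allocation plus the exact product identity, not any
particular design-based reconstruction. With α = 0 all weight sits at level
1. In synthetic mode the de-normalization factor defaults to 1 (weights are
already on an absolute scale with mean 1).

## Outcome and regression model

Appropriate newborn care is the binary indicator of receiving ≥5 of the six
provider-initiated interventions. It is modelled with a Poisson distribution
and log link ("modified Poisson") so coefficients exponentiate to risk
ratios, with a cluster-level random intercept and cluster-robust sandwich
standard errors. The robust variance is essential: the Poisson variance
function is deliberately wrong for a binary outcome.

Estimation is weighted penalized quasi-likelihood (PQL): IRLS on the
linearized model, with the per-cluster random intercepts profiled out through
a Schur complement so each iteration costs O(n p²) regardless of the number
of clusters. The variance component is updated by the conditional-moment rule
σ² ← mean_j(u_j² + 1/S_j), floored at 1e-10 and capped at 25. Convergence
requires both a 1e-9 relative change in β and 1e-6 in σ². Weights enter as
the per-observation product `level1 × level2` (fixed-effect equations) and
the level-2 weight scales the per-cluster penalty; both weight levels are
normalized to mean 1 internally, which makes the point estimates invariant to
rescaling either level by a constant — the documented convention behind the
weight-invariance property test. The sandwich uses the profiled working
information as bread and per-cluster score outer products (at the fitted
conditional means) as meat; with σ² → 0 this reduces exactly to the familiar
cluster-robust modified-Poisson estimator. For log-link models with an
independent random intercept, conditional and marginal covariate effects
coincide, so the recovered fixed effects are directly comparable to the
marginal risk ratios the generator encodes.

If the PQL loop fails (non-convergence, singular system), the model is refit
as a weighted exchangeable-correlation Poisson GEE (statsmodels) and the
result flagged `gee_exchangeable_fallback`; for cluster-level exposures both
routes target the same marginal risk ratios. A logit variant is deliberately
not the primary route: risk ratios, not odds ratios, are the reported
estimand.

Separation is detected before fitting: a term with no variation, or a level
with zero positive outcomes (whose log-RR diverges), raises a
`SeparationError` naming the term. Rows with missing values in any model
column are dropped listwise and the count recorded in the fit's warnings.
Reference levels default to: no facility (count exposure), lowest tercile
(tercile exposure, with "no facility" as a distinct non-reference level),
facility birth, lowest density, poorest quintile, age <20, less than
secondary education; all are re-codable, and re-coding changes the
parameterization but not the fitted means (property-tested).

## Synthetic-data generator

The generator emulates the *structure* of a linked household survey /
facility census study, with every quantity a pure function of
(config, seed):

* **Facilities** (default 540, all providing birth services): uniform
  locations in the study rectangle; a latent per-facility readiness drawn
  from Beta(12, 6), per-domain indicator probabilities from a Beta centred on
  it (concentration 35), indicators Bernoulli. These defaults put overall
  scores roughly in the 25–99 range with mean near 67, matching the spread
  reported for facility censuses of this kind.
* **Clusters** (default 850, 12.5% urban): uniform true locations;
  displacement at a uniform bearing with distance U(0, 2 km) urban and, for
  rural, U(0, 5 km) with probability 0.99 else U(5, 10 km]. The published
  displacement rule describes the 1% tail as "displaced up to ten km"; we
  draw that tail beyond the 5 km cap so the fraction of rural draws exceeding
  5 km is 1% by construction — the calibration the displacement tests check.
  The admin-boundary restriction is approximated by clipping to the study
  rectangle (no admin polygons exist in the synthetic world); documented
  limitation. Design weights are log-normal (σ = 0.4), normalized to mean 1.
  Population density is log-normal, an order of magnitude higher in urban
  clusters.
* **Friction surface**: a Gaussian-smoothed log-normal field in minutes per
  metre (default mean 0.0018 ≈ 33 km/h best-case speed, 1 km cells), with the
  top 2% of an independent smooth field marked impassable to mimic water.
  A constant surface and barrier-free surfaces are configurable.
* **Births** (default ~6,000): 30/33 households per urban/rural cluster,
  thinned binomially to the target count. Covariates are drawn independently
  at published survey margins (12.5% urban, 20% under-20, 19.6% secondary+
  education, 26% first births, 6.9% home births, wealth quintile shares
  25.9/23.3/19.6/16.8/14.4). The binary appropriate-care outcome is drawn
  from the marginal log-link model `p = baseline × Π RR^x` with baseline 0.60
  and default effects: home birth 0.32, middle/high service-environment
  tercile 1.17/1.24, secondary education 1.08, all others 1 (all
  configurable). Probabilities above 0.995 are truncated with a warning and
  the truncated fraction recorded in the truth sidecar. The six intervention
  booleans are then filled consistently with the outcome (5 or 6 true when
  appropriate, with P(6 | appropriate) = 0.45; otherwise a count 0–4 from a
  configurable distribution with mass concentrated at 3–4, echoing the
  observed right-shifted co-coverage shape), the specific interventions
  chosen uniformly.

Because the outcome is generated *from the exposure the models see* (the
tercile of the maximum linked score under the 5–10 km buffer linkage of the
displaced coordinates), the adjusted model is correctly specified and
replicated fits recover the configured risk ratios without attenuation. What
the generator deliberately does **not** emulate: covariate–covariate and
covariate–exposure correlations present in real populations (e.g. home birth
concentrating among poorer, less-educated households), facilities co-located
with towns, real road networks or terrain, admin-2 displacement constraints,
cluster-level unobserved heterogeneity (the true random-intercept variance is
zero), and item missingness. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the stated data-generating
process, not robustness to confounding or misclassification in real data.

## Experiment sizes

The replicated experiments use 200 synthetic studies at full scale (~6,000
births in 850 clusters each): effect recovery summarizes per-replicate
adjusted-model estimates by their geometric mean (the natural average for
ratio parameters), and the null-calibration experiment regenerates the same
worlds with every effect at RR = 1 and reports per-term coverage of 1 by the
robust 95% intervals. Unit tests use scaled-down worlds (50–400 clusters) —
sizes chosen to keep Monte-Carlo error well inside the asserted tolerances.

## Degenerate inputs and tie-breaks

* Empty indicator domains, non-dichotomous indicator values, out-of-range
  coordinates, non-positive weights, zero total weight, degenerate bounding
  boxes and invalid effect ratios raise `ValidationError`.
* Buffer radii and the travel-time cutoff are inclusive (≤); measure-zero
  effect on continuous data but deterministic and documented.
* Tercile boundary ties go low (above).
* A missing readiness score for a linked facility is an error rather than a
  silent skip; clusters with no links carry an undefined maximum score and
  enter tercile-exposure models as the "no facility" level.

## Known limitations

* The α-split weight construction is a pragmatic stand-in for design-based
  two-level weights; only the allocation contract and product identity are
  guaranteed.
* PQL is approximate for binary-like outcomes with large variance components;
  in this package's regime (small σ², cluster-level exposures) the sandwich
  protects inference, and the GEE fallback covers pathological fits.
* The ESRI ASCII friction grid is stored in a local projected metric system
  with a JSON georeference sidecar; consumers expecting a geographic-CRS
  ASCII grid should reproject.
* The synthetic walking routers are Haversine-based; they exercise the chain
  semantics (primary → <50 km fallback → unreachable) but not real network
  routing.
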