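# Methods

## Scope and design

`obstaccess` analyses the closure of hospital obstetrics departments
between two reporting years and its consequences for driving-time
accessibility. The real data source for such studies — structured hospital
quality reports at site level — is not redistributable, so the package is
built around two synthetic data layers with different purposes:

* **`synthetic_region`** generates a *random* study region (road network,
  areas, registries, closure outcomes) from configurable marginals. It is
  the engine for replicate experiments: parameter recovery, selection
  frequencies, calibration.
* **`synthetic_benchmark`** constructs a single *deterministic* registry
  pair whose marginal counts equal the published cohort tables of the
  German 2014/2019 obstetric-hospital population. It exists so the
  operationalization funnel (identification, linkage, exclusions,
  descriptive arithmetic) can be exercised against known printed totals.
  Only margins are pinned; joint distributions within them are filled in
  blockwise and are not data.

## Operationalization

A site counts as obstetric in a reporting year if it is an acute facility
(day-care and rehabilitation excluded), has an obstetrics/gynecology
department code, and documents at least one live birth. Live births are the
sum of the OPS 9-262 subsection counts (9-262, 9-262.0, 9-262.1, 9-262.x,
9-262.y); the parent code and subcodes are treated as disjoint, and codes
outside the list contribute nothing. Malformed code strings are skipped
with a warning rather than failing the site.

Linkage across years uses the stable site id. A baseline obstetric site is
*closed by follow-up* iff it is absent from the follow-up obstetric set; it
is a *whole-hospital closure* iff it vanished from the full follow-up
registry (or carries an explicit whole-closure flag). Before regression,
university hospitals and whole-hospital closures are removed: the former
because no university obstetrics department closes in this population, the
latter because site-level failure has its own causes.

Category boundaries follow the published "≤" rules: density low ≤ 100,
high > 1000 inhabitants/km²; fertility low ≤ 1.3, medium (1.3, 1.6], high
> 1.6 children/woman. The published three-tier density rule leaves
(500, 1000] unassigned; the medium band is extended to 1000 so the
categories partition the domain while the printed high cutoff is kept.
Fertility enters the regression as a continuous covariate; the categories
are used descriptively only.

### Nearest-competitor travel time

The competition covariate is each site's minimum car travel time to the
nearest other obstetric site. It is computed exactly in one pass: a
multi-source Dijkstra from all site nodes yields the graph-Voronoi cell and
nearest-site distance of every node; for every edge (u, v) crossing a cell
boundary, d(site_u, u) + w(u, v) + d(site_v, v) bounds the inter-site
distance, and the minimum over boundary edges adjacent to a cell is exactly
that site's nearest-other-site distance. A unit test checks this against
per-pair Dijkstra on random graphs. Sites sharing a node are 0 minutes
apart; a site unreachable from all others gets +inf with a warning.

## Closure model

Closure is modelled by multivariate logistic regression (response: closed
by follow-up) with terms ownership (ref. private), pediatrics on site
(ref. no), teaching status (ref. non-teaching), population density
(ref. low), fertility rate, annual live births, and nearest-competitor
time. Numerical contract: Newton iteration, at most 100 steps, and the
score's max-norm at the solution must be below 1e-8 — otherwise the fit
fails loudly (this catches quasi-separation, where the MLE does not
exist, rather than reporting meaningless estimates). Rank deficiency and
perfect separation raise errors naming the offending columns. Wald
standard errors come from the observed information; 95% CIs are
exp(coef ± 1.96·SE). Near-separated fits may report infinite CI bounds;
that is the honest Wald summary.

Benjamini–Hochberg adjustment is applied within one model across all
non-intercept coefficient p-values. Note the step-up transform is *not*
idempotent (BH([1, 0.25]) = [1, 0.5] but BH([1, 0.5]) = [1, 1]); the
package asserts order invariance, rank monotonicity, adjusted ≥ raw and
the cap at 1 instead.

Model fit is summarized by AIC = 2k − 2·LL and BIC = k·ln n − 2·LL with k
counting all parameters, and McFadden adjusted R² = 1 − (LL − k′)/LL_null
with k′ excluding the intercept. Multicollinearity is screened by the
generalized variance inflation factor (determinant ratio over the
predictor correlation matrix, Fox–Monette), with the scaled rule
GVIF^(1/(2·df)) > √10 flagging a term. Linearity of the logit is checked
Box–Tidwell style (Wald test of the x·log x term, covariates shifted to a
minimum of 1 when non-positive, with the shift reported).

Backward stepwise selection removes, at each step, the whole term whose
removal lowers AIC the most, while any removal lowers AIC; categorical
terms leave as complete indicator blocks, and AIC ties are broken by
dropping the term listed later in the specification (determinism). By
construction the final model's AIC never exceeds the full model's.

LOWESS closure-probability curves over live births use locally weighted
linear smoothing with span 2/3 by default (configurable; no robustness
iterations, so curves are deterministic and can be evaluated on a fixed
grid), per pediatrics stratum, skipping strata under 20 observations.

## Accessibility

Random points are sampled uniformly over the bounding box (or a supplied
polygon), snapped to the nearest network node (snap distance recorded, zero
access time — users can add an access penalty from the logged distance).
One multi-source Dijkstra sweep from all active facilities yields every
node's minimum driving time; the contract tested is equality with the
per-facility minimum and with brute-force path enumeration on small
graphs. Bands: t < 30 under; 30 ≤ t ≤ 40 middle ("between 30 and 40
minutes"); t > 40 over, including unreachable points (the islands analog).
Both boundaries are configurable. The default sample is 100 000 points;
experiments and tests use ≤ 20 000, which already gives band-share
standard errors below 0.4 percentage points.

Scenarios (all sites; pediatrics required; ≥ 600 live births, inclusive)
are facility-set filters evaluated on one common point sample. Since a
filtered set is a subset, no point's minimum time can decrease and the
over-40 share cannot shrink; this theorem-level monotonicity is asserted
on every scenario run.

## Synthetic region: what it emulates, what it does not

The generator reproduces the study population's *statistical structure*:
~700 obstetric sites; ownership ≈ 39.9/43.2/16.9% nonprofit/public/
private; pediatrics ≈ 39.5%; density strata ≈ 5/42/53%; log-normal live
births solved from median 683 and IQR (450, 1126); area-level fertility ≈
N(1.48, 0.12) truncated to (0.8, 2.2), giving roughly 5/75/20% category
shares; and a road network (uniform nodes, geometric-radius plus 3-nearest-
neighbor edges, bridged to connectivity; edge time = Euclidean km × 1.3
detour factor at 60 km/h over a 650×870 km box) whose nearest-competitor
times have a median near 18 minutes. Density strata are assigned to area
cells by largest-remainder quota rather than iid draws: the study region's
composition is a fixed marginal, and quota allocation keeps the rare
low-density stratum from collapsing in individual replicates.

Closures are simulated independently across sites from the logistic model
with the published final-model odds ratios (0.995 per birth, 0.357 for
pediatrics, 0.24/0.251 for medium/high density, 0.157 per fertility unit,
0.95 per minute; ownership and teaching null). No intercept is published;
it is calibrated per cohort by Brent root-finding so the mean closure
probability equals the published 10.26% event share.

Not emulated: the real geography (no islands, no postal-code polygons, no
actual road hierarchy), spatial correlation of closures (competing
neighbors presumably interact; closures here are independent given
covariates), secular drift in covariates between years, and reporting
noise in the registries. Passing recovery tests therefore show that the
*estimation pipeline* is correct and well calibrated under the stated
conditions — not that the published effect estimates are externally valid.

## Numerical and edge-case conventions

* All generators are pure functions of (config, seed); replicate seeds are
  spawned from one master seed via a seed sequence.
* Boundary comparisons use "≤" exactly as printed (closed left categories).
* Empty registries, empty strata, empty scenario results and single-site
  regions degrade to warnings plus well-defined values (empty result, +inf
  travel time), never silent wrong numbers.
* Chi-squared tables with a zero expected count are flagged unreliable;
  constant tables return statistic 0, p 1 by convention.
* CSV is UTF-8/comma/point-decimal; GeoJSON is RFC 7946-shaped JSON with a
  note declaring planar km coordinates.

## Problem sizes

The replicate experiment uses 200 cohorts of n = 702 on a fixed
1500-node network (sites, attributes, travel times and outcomes redrawn
each replicate); the accessibility drivers sample 10 000–20 000 points;
exactness checks enumerate all simple paths on graphs of ≤ 8 nodes.
These sizes give Monte-Carlo bands well inside the asserted tolerances
while keeping a full run in tens of seconds.

## Known limitations

* Wald inference only; profile-likelihood CIs are out of scope, and near
  separation the Wald summary is conservative to the point of infinite
  bounds.
* The travel-time engine is a planar surrogate; plugging a real router
  means implementing the same minutes-between-coordinates contract.
* The benchmark registries pin only published margins; any statistic that
  depends on unpublished joint distributions (e.g. closure-by-ownership
  cross-tabs) is a modelling artifact there, not a reproduced number.
* The 30 ≤ t ≤ 40 middle band includes both boundaries; the published maps
  do not state the convention, so both boundaries are configurable.
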