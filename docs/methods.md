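# Methods

`ira` implements a three-step integrated resilience assessment of an annual
multivariate system (a year × taxon matrix of strictly positive abundance
proxies) driven by a single stressor series (e.g. annual mean sea-surface
temperature). This note records the models, the numerical choices, and what
the bundled simulator does and does not emulate.

## Step 1 — complexity reduction

The system matrix is natural-log transformed (`log_transform`; an additive
offset is exposed for zero handling and defaults to 0, so zeros are an error
the user must resolve explicitly) and decomposed by a PCA **of the covariance
matrix** — centred but not variance-scaled, so abundant, variable taxa carry
more weight, as is conventional in integrated ecosystem assessments. The
leading score series (PC1) is the holistic system indicator. Components are
oriented so the largest-magnitude loading is positive; any orientation is
statistically equivalent, this one is just deterministic across linear-algebra
backends.

Supporting diagnostics:

* **Traffic light** — each logged taxon series is categorised into quintiles
  using average ranks with fixed boundaries at ranks n/5, 2n/5, …
  (category = ⌈5·rank/n⌉), which is deterministic under ties; a constant
  series sits entirely in the middle category. Taxa are ordered by their PC1
  loading.
* **STARS** — a sequential t-test for step changes in the indicator mean,
  implemented as a retrospective variant: the variance scale is the average
  variance of consecutive L-year windows; a candidate opens when a value
  departs from the current regime's baseline mean (estimated from the
  regime's first L years, the same convention as for the initial regime) by
  more than `t_crit(p, 2L_eff−2)·sqrt(2σ²_L/L_eff)`; the regime shift index
  accumulates Huber-weighted anomalies (weight `min(1, h/|z|)`) over the next
  L years and confirms iff it stays positive throughout the full window —
  hence no shift can be confirmed within the last L−1 years. The red-noise
  correction deflates L to `L_eff = L(1−α)/(1+α)`, with α estimated by lag-1
  OLS on the full series (default) or by an MPK-style subsample estimator
  (windows of length min(L, n/3), first-order bias correction). Defaults
  L=10, p=0.05, h=1.
* **Autocorrelation-corrected correlation** — Pearson r between indicator and
  lagged stressor with a Pyper–Peterman/Chelton effective sample size,
  `1/n_eff = 1/n + (2/n)·Σ_{j≤J} ρ_x(j)ρ_y(j)` (J=5 by default, clamped to
  [3, n]); the two-sided p-value uses Student's t with `n_eff − 2` df. With
  J=0 this is exactly the classical Pearson test. The exact historical
  formula variant is not uniquely documented in the regime-shift literature;
  this widely used product form is adopted and J is configurable.

## Step 2 — continuous vs discontinuous response models

The response is the indicator (negated, by default automatically, so that
chronologically older states sit higher on the y-axis — the customary fold
orientation); the covariate is the stressor at lags 0–2.

* **Smoother.** A penalized **natural** cubic regression spline of effective
  dimension k (default 4): k+2 cubic B-splines with the two
  zero-second-derivative boundary constraints projected out, interior knots
  at quantiles of the distinct covariate values, and the exact integrated
  squared-second-derivative penalty (3-point Gauss–Legendre per knot
  interval, exact for the piecewise-quadratic integrand). The natural basis
  is the standard choice in the threshold-GAM literature and — because the
  spline leaves the data range linearly — keeps out-of-range prediction
  slopes tame, which matters in the cross-validation below. λ is selected on
  a 25-point log grid (10⁻⁶…10⁶) by GCV with an effective-df cost multiplier
  γ=1.4, the standard small-sample guard against GCV undersmoothing; the
  *reported* `gcv_internal` keeps the canonical `n·rss/(n−edf)²` form.
  Near-ties in the selection criterion (10⁻⁴ relative, e.g. on the flat
  fully-penalized shelf) break to the smallest λ. Predictions outside the
  training range use linear extrapolation with the boundary slope (constant
  extension is available by configuration). The λ→∞ limit is the OLS line
  (the penalty null space).
* **TGAM.** Candidate threshold years are the observed years whose 1-based
  rank r satisfies `0.1·n + 1 ≤ r ≤ 0.9·n` and which leave at least 5 points
  per branch; for each candidate, separate smoothers are fitted to the years
  before/after, and the threshold minimises the whole-model GCV
  `n·(rss₁+rss₂)/(n−edf₁−edf₂)²`, ties to the earliest year. Gaussian errors
  throughout (the response is a PC score), so residual deviance = RSS.
* **gCV.** Model classes are compared by the genuine cross-validatory squared
  prediction error: a leave-one-out loop in which *everything* — λ for every
  smoother and, for the TGAM, the threshold search itself — is re-estimated
  on each fold, and the held-out year is predicted by the branch its year
  falls into under the fold's own threshold. This is verified against a
  naively coded refit-from-scratch double loop.
* **Threshold chains.** A TGAM encodes one threshold. Both branches of the
  selected fit are screened for a second step (STARS with a short cut-off on
  the branch residuals *and* on the raw branch level, since a steep smoother
  can absorb a step into the x-effect); if the screen fires, the GAM/TGAM
  comparison is repeated on the sub-period and the sub-TGAM is kept iff its
  gCV wins. A sub-threshold found on the lower branch means the full-period
  threshold fell inside a middle regime, so the years after the earlier
  threshold are re-modelled. Near-tied thresholds are resolved by a
  chi-square parsimony test on the residual-deviance difference with
  df = max(|Δedf|, 1): non-significant differences (p > 0.05) favour the
  smaller total edf (tie → earlier year).

## Step 3 — resilience assessment and the stability landscape

The stressor is mean-standardised (PC scores are mean-centred by
construction), putting both axes on comparable scales; an optional `sd`
scaling of both axes is available for sensitivity analysis. Each regime's
fitted branch is its **attractor**; regime spans tile the analysis period
using the threshold chain (a sub-period refit supersedes the coarser
full-period branch starting at the same year). The **shift direction** of a
regime's exit is the sign of the largest stressor excursion from the regime's
median stressor near the boundary — robust to spike-and-relax transitions
where the stressor crosses the tipping point transiently.

Per year: `vComp = −|y − attractor(x)| ≤ 0`,
`hComp = direction·(x_F − x) ≥ 0` (the signed in-basin distance to the
regime's tipping point; regimes with both an entry- and an exit-side point
use the minimum of the two signed distances), `Res = hComp + vComp`, and
`rRes = Res / max Res` over the system.

Tipping points lie on the (possibly linearly extrapolated) attractor at exact
multiples of the rounding quantum q (default 0.05 stressor units,
configurable):

* **exit side** — anchored one quantum beyond the first year after the
  regime's last resident (non-transitional) state, then pushed outward in
  q-steps until every in-regime Res is non-negative;
* **entry side** — the extremal q-multiple nearest the year cluster such that
  `|x_y − x_F| ≥ |vComp_y|` for every regime year (equivalently, the largest
  q-multiple below `min(x_y − |vComp_y|)` for a regime entered from below).

**Transitional years.** With an explicit user list, those years carry
`Res = rRes = 0` and the exit points are pushed as above. By default the
package reclassifies iteratively: while the *trailing* in-regime year has
negative Res under the current placement, it is peeled off as transitional
(the transition occupies the boundary years, and the exit anchor then steps
back to the stressor excursion that drove the shift); any residual interior
negativity is absorbed by the outward push. Peeling only at the boundary
keeps the iteration stable — reclassifying arbitrary negative years can
cascade through a cluster when an early placement is poor.

The **landscape** interpolates all (x, y, rRes) nodes — yearly states,
tipping points at zero, and optional auxiliary zero points for anchoring an
otherwise unconstrained basin border — piecewise-linearly on the Delaunay
triangulation, sampled on a 100×100 grid over the node bounding box; cells
outside the convex hull are undefined (NaN), not zero. **Basin borders** are
marching-squares contours of the surface. The exact zero set of a
non-negative surface has measure zero and cannot be crossed by a finite
grid, so borders are extracted at a small resolvable level, by default 2% of
the maximum rRes; an all-zero surface yields no contour.

## The synthetic fold-bifurcation generator

The generator is the test bed: it emulates the *structure* of the kind of
data the method targets, with known ground truth.

* **Stressor**: base level + step jumps + stationary AR(1) noise (marginal
  sd as given, lag-1 autocorrelation α). The scenarios use jumps of ~0.5–0.9
  units that spike, cross a tipping value, and partially relax — so regime
  year-clusters overlap on the stressor axis, which is precisely the
  configuration in which hysteresis is observable and a single smooth curve
  cannot fit the data.
* **Fold ladder**: regimes switch forward when the lagged stressor crosses
  the next forward tip and back below the corresponding (lower) backward tip;
  the latent state is the current regime's affine branch curve at the lagged
  stressor plus Gaussian state noise. An optional expression delay
  (`switch_delay`) lets the community lag the driver by a year; the bundled
  scenarios use immediate expression.
* **Taxa**: `value[t,i] = exp(μ_i + w_i·latent_t + ε)`, with loading
  magnitudes in [0.3, 1.0], half of each sign (warm- vs cold-affiliated),
  log-normal observation noise (sd 0.25 in the scenarios) sized so the
  leading component explains roughly half of the log-scale variance, and
  baseline abundances spanning ~50–5000.
* **Scenarios** (29 years, 1985–2013 analogue; stressor from 1982 for the
  lags): `east_like` — one shift, 1-year lag, branch offsets ±0.3 (latent
  units), within-regime slope 1.0 per stressor unit so the lag is
  identifiable from year-to-year fluctuations; `west_like` — two shifts,
  2-year lag, three branches at +0.7/0.0/−0.7, a 6-year middle regime, and a
  small early-years base step that deepens the first basin; `smooth_null` —
  a linear response to a gradually ramping stressor, the GAM-favouring
  control. Branch separations are many times the state noise (sd 0.04).

What the generator does **not** emulate: taxon-specific dynamics and
interactions, observation gaps, effort-driven trends in the abundance
proxies, multiple interacting stressors, and non-stationary noise. Passing
tests therefore demonstrate that the pipeline recovers fold-bifurcation
structure *of this idealised kind*; they do not certify behaviour on real
landings data, where confounding pressures (e.g. exploitation) can mimic or
mask regime structure.

## Validation experiments and problem sizes

`ira.benchmarks` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures: PCA against a brute-force covariance
eigendecomposition (50 random matrices); gCV against a refit-everything
double loop (one fixed 20-point dataset); threshold/lag recovery over 50
east-like seeds and model-class selection over 50 smooth-null seeds; STARS
noiseless-step detection and false-positive ordering under AR(1) α=0.5 noise
(200 replicates); corrected-correlation equivalence and rejection ordering
under AR(1) α=0.8 (500 replicates); resilience-geometry invariants and a
hand-computed tipping fixture; and three-regime hysteresis/shallow-middle
recovery over 25 west-like seeds. These sizes keep the full validation run
in the minutes range on a single core while leaving Monte-Carlo rates with
standard errors of a few percentage points.

## Known limitations

* The threshold search is over *years* (time thresholds); covariate-value
  thresholds are out of scope.
* One covariate, Gaussian errors, single-indicator response only.
* gCV with threshold re-estimation is noisy on short sub-periods (~10–15
  years); single leave-one-out folds in which the fold's threshold re-routes
  a transition-adjacent year can dominate the mean. The natural-spline basis
  and the γ-inflated selection keep this in check but do not remove it.
* STARS shift years can be attributed to an elevated year adjacent to the
  true change; exact-year attribution degrades gracefully with the
  signal-to-noise ratio.
* The middle regime of a three-regime system takes the *minimum* of its two
  tipping-point distances for hComp; the behaviour of two-sided basins under
  alternative rules has not been explored.
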