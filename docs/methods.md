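# Methods

## The model

`navcoc` estimates how well a migrating animal knows where it is. The animal
is assumed to aim for the great-circle (GC) route between its migration start
and end points; everything the model sees is the animal's *signed
cross-track deviation* from that route, one value per day. For animal `j`
with observed deviations `y_{j,t}` (km):

    y_{j,t} = x_{j,t} + eps_{j,t},          eps_{j,t} ~ N(0, sigma_eps^2)
    x_{j,t} = gamma_j x_{j,t-1} + sigma_j e_t,   e_t ~ t_nu

The latent `x_{j,t}` is the animal's best guess of its position relative to
the route; `gamma_j` (|gamma| < 1) is the day-to-day persistence of being on
one side of the route, and `sigma_j` the scale of the daily course-keeping
shock. The *circle of confusion* — the radius around the animal's position
within which it cannot resolve its own location from indirect cues — is the
stationary scale of this AR(1):

    CoC_j = sigma_j / sqrt(1 - gamma_j^2)   (km)

1.96 x CoC is the radius of the 95% positional interval. Large CoC means
poor navigation: either large daily wander (`sigma`) or slow correction back
toward the route (`gamma` near 1).

**Scale, not standard deviation.** `sigma_j` is the *scale* of the t-shock.
With heavy tails the fitted degrees of freedom `nu` routinely land near or
below 2, where the t variance is infinite or undefined, so defining CoC on
the t scale keeps it meaningful in exactly the regime the robust error model
is there for. `PosteriorSamples.coc_corrected()` provides the
variance-corrected alternative `sqrt(nu/(nu-2)) * CoC` for draws with
`nu > 2`.

**Hierarchy.** Animals are exchangeable: `gamma_j = 2 v_j - 1` with
`v_j ~ Beta(a, b)`, and `sigma_j ~ N(theta, tau^2)` truncated to positive
(`theta = 0` recovers the classic half-normal). Uniform hyper-priors sit on
`a, b, theta, tau`; `nu` is uniform on (1.5, 50); `sigma_eps` has an
informative normal prior, mean 2 km and SD 0.02 km, reflecting how little
measurement error survives robust daily regularization of Argos fixes. Under
`grouping="by_sex"` each sex has its own `(a, b, theta, tau)`; `nu` and
`sigma_eps` describe the shock and measurement processes and stay shared.
The posterior predictive ("new animal") CoC draws a fresh
`(gamma*, sigma*)` from each retained draw's hyper-parameters — the induced
distribution of navigation ability for an unobserved individual.

## Priors that matter, and why

* `a in U(1, 500)`, `b in U(1, 20)`. Two constraints shaped these bounds.
  First, representing `gamma` concentrated near 0.97-0.99 (the regime the
  model exists to measure) requires `a + b` in the hundreds — a textbook
  `U(1, 20)` cap on both would confine the prior mean of `gamma` below
  ~0.9 and bias every animal's CoC downward. Second, `b >= 1` keeps the
  beta density bounded at `v = 1`: the likelihood of a near-unit-root AR(1)
  is almost flat as `gamma -> 1`, and with `b < 1` the joint posterior can
  slide into the integrable singularity at `gamma = 1`, dragging all
  individual `gamma_j` upward together.
* Initial state: `x_{j,1} ~ N(0, sigma_j^2 (nu/(nu-2)) / (1 - gamma_j^2))`
  — the stationary Gaussian approximation, the package default. Tying the
  initial state to `(gamma_j, sigma_j)` penalizes `gamma -> 1` exactly as
  stationarity demands and measurably improves parameter recovery relative
  to a diffuse data-anchored alternative (`x_1 ~ N(y_1, (10 sigma_eps)^2)`,
  available as `init_state=("data", 10.0)`); a fixed `N(m, sd^2)` option
  supports fully self-consistent simulation-based calibration.
* `theta in U(0, 50) km`, `tau in U(0.01, 50) km`: spans per-day shock
  scales from near-deterministic course keeping to ~100 km/day wander.
* Missing days contribute no observation term; the state evolves across the
  gap (handled exactly by the Kalman recursions).

## Sampler

No probabilistic-programming backend is used. The sampler is Gibbs:

1. Latent paths by forward-filtering backward-sampling (FFBS), exact because
   conditional on per-day mixing weights the model is linear-Gaussian. The t
   shock is the scale mixture `e_t | w_t ~ N(0, 1/w_t)`,
   `w_t ~ Gamma(nu/2, nu/2)`.
2. `w_{j,t}` by its conjugate Gamma update.
3. Every scalar parameter by univariate slice sampling (stepping-out +
   shrinkage) on its full conditional, with widths scaled to each prior
   range. Slice sampling needs no tuning and cannot reject.

Default protocol: 2 chains x 40,000 iterations, 20,000 burn-in, thinning 5 —
8,000 retained draws. A single master seed fans out deterministically to
per-chain streams (`numpy.random.SeedSequence.spawn`). Split-chain R-hat
(arviz) above 1.1 triggers a warning naming the offending parameters, never
a failure.

Correctness is established by independent routes rather than by
construction:

* **Grid oracle.** With Gaussian process errors the latent states integrate
  out exactly (Kalman prediction-error decomposition, itself cross-checked
  against a dense multivariate-normal evaluation and statsmodels' SARIMAX).
  The MCMC histogram over `(gamma, sigma)` is compared to the exact grid
  posterior by total-variation distance. The comparison uses a 40 x 40 grid
  over a region holding essentially all posterior mass and ~40,000 retained
  draws: the expected TV of even a perfect sampler's histogram grows like
  sqrt(occupied cells / draws), so very fine grids measure Monte-Carlo noise
  rather than sampler error.
* **Simulation-based calibration.** Parameters drawn from the prior, data
  simulated forward (t shocks included), the sampler run, and the rank of
  the truth among thinned posterior draws recorded; ranks must be uniform.
* A fixed-`gamma` one-dimensional marginal is checked against dense-grid
  numerical integration by Kolmogorov-Smirnov distance.

## Pipeline upstream of the model

* **Regularization.** Each 24 h window (anchored at the first fix) is
  collapsed to one location: the Minimum Covariance Determinant location
  (mean of the `h = floor((n+3)/2)`-subset with minimal covariance
  determinant; exhaustive for `n <= 12`, FAST-MCD via scikit-learn beyond)
  for windows with at least 4 fixes, the coordinate-wise median for 1-3,
  missing otherwise. MCD runs on raw (lon, lat) degrees — windows are local
  enough that anisotropy is negligible at daily scale. Argos location-class
  codes are read and carried but not used.
* **Geometry.** Spherical Earth, R = 6371.0 km, fixed in one place
  (`navcoc.geometry.EARTH_RADIUS_KM`). Deviations are signed, positive to
  the left of the start-to-end direction of travel (the side-persistence the
  AR(1) models would be destroyed by unsigned distances). The deviation is
  the distance to the route's full great circle; a `clamp` flag measures to
  the nearer endpoint when the foot point falls outside the arc.
* **Segmentation.** Migration start: global maximum of robustly smoothed
  daily travel rates (running median, default 7-day window, plus one
  Hanning pass; endpoints copied), excluding the first week (post-tagging
  behaviour). Migration end: first reversal of the smoothed day-to-day
  longitude-change sign that persists at least 5 days after the start —
  localized foraging/breeding behaviour churns direction. Both windows are
  configurable and per-animal manual bounds are first-class, since end
  points in real data are partly a judgment call. Current-boundary splits
  take a west-to-east polyline (user input) with a band half-width; `after`
  begins at the first location south of the boundary never followed by a
  return north of boundary + band.
* **Edge trim.** `trim_edges` drops floor(0.025 T) deviations from each end
  — the tied-down-random-walk sensitivity check; the hierarchical CoC
  should move only slightly.

## Model comparison

Competing fits are scored by minimum posterior predictive loss under squared
error: per observed deviation, replicates are simulated from the fitted
model for each retained draw — by default the state is re-advanced one step
from the drawn `x_{t-1}` with a fresh t shock, then observation noise is
added (a flag conditions on the drawn `x_t` instead); day-one replicates
condition on the drawn initial state. With predictive means `mu_l` and
variances `v_l`:

    G = sum (mu_l - y_l)^2,  P = sum v_l,  D_k = P + k/(k+1) G,  D_inf = P + G

The sums run over every observed deviation of every animal — the loss is
defined per observation; aggregating first to per-animal summaries is a
documented alternative reading. Smaller `D_k` wins; `select_model` refuses
results computed on different observation sets and reports whether the
ranking is stable across `k in {1, 3, 9, inf}`. The drift-compensation test
deliberately compares `D_inf` across *different* observation sets (full
track vs after the current crossing, each with its own route) — those raw
values are reported side by side rather than passed through `select_model`.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the features the pipeline's stages key on:
~3-month (default T = 90 day) southward migrations along a great circle
(Nova Scotia to the eastern Caribbean by default), 7 animals per sex,
Poisson(6) fixes per day with Gaussian jitter (SD 1.5 km) and a stated
fraction of gross outliers (~500 km), pre/post-migration dwell phases as
small-step random walks (direction churn), a departure travel-rate burst
(factor 1.8 decaying over ~4 days — the peak the start detector uses), and
an optional mid-track eastward drift event after which the animal re-aims
at its destination along a fresh great circle. Truth (per-animal
parameters, CoC, latent paths, daily positions, phase boundaries) is
returned alongside.

Per-animal parameters are drawn from hyper-distribution truth
(`a = 581, b = 8.9, theta = 25 km, tau = 6 km`, i.e. gamma centred at 0.97
with SD ~0.01) and rejected until `gamma_j` lies in [0.95, 0.99] and CoC in
[60, 150] km — the study conditions the defaults encode; explicit per-animal
values may be supplied instead. The daily outlier count is the rounded
nominal fraction of that day's fixes rather than per-fix Bernoulli, so
contamination stays at its stated rate instead of occasionally exceeding
the MCD breakdown point by luck.

Deliberate simplifications: no within-day movement (each day's fixes sample
that day's position, and the first fix anchors the window grid to the day
grid); no oceanographically realistic current fields; no Argos duty-cycling
or class-dependent error structure (the pipeline discards class information
anyway); dwell churn is isotropic. Passing tests therefore demonstrate the
pipeline's statistical behaviour under its own assumptions plus these
controlled violations (outliers, heavy tails, dwell phases, drift) — not
performance on the full messiness of real Argos tracks.

## Problem sizes used in validation

Validation experiments are scaled to desk hardware as the package's own
test design: grid-vs-MCMC at T = 60 with ~40k retained draws; parameter
recovery on 14 animals at T = 90 under a 2 x 4,000 (burn 2,000, thin 2)
protocol, pooled over a few replicate populations; calibration at 200
single-animal replicates of T = 20; model-selection power at 7 + 7 animals,
T = 60, single-chain scaled-down fits. The full 2 x 40,000 protocol is the
library default for real analyses.

## Known limitations

* The predictive-loss comparison has limited power against group-level
  *scale* contrasts: because replicates condition on the fitted individual
  states and parameters, the individual level absorbs most of a between-group
  scale difference and the Common/Separate D gap is a second-order shrinkage
  effect. In simulation, a 3-fold group-scale contrast is detected in only
  ~60-70% of replicates at 7 + 7 animals, while identical groups correctly
  favour the pooled model in ~90-95%. Marginal (new-animal) replicates do not
  fix this — they zero out the fit term entirely and reduce the criterion to
  a pure variance penalty — so the conditional design is retained.
* Near-unit-root geometry is intrinsically hard: with T ~ 90 days the
  likelihood constrains `gamma` to ~±0.02 at best, which maps to ~±25%
  relative uncertainty in CoC at `gamma ~ 0.98`. Posterior medians of
  individual CoC are correspondingly noisy even when the sampler is exact;
  the hierarchical mean CoC is much better determined.
* The route is a fixed great circle; persistent forcing (currents) inflates
  CoC. The boundary-split machinery mitigates, not solves, this.
* One deviation series per animal; staged migrations (re-planning at
  waypoints) would need a within-individual level the model does not have.
* The end-of-migration change-point detector encodes one operationalization
  of a partly manual procedure; manual bounds override it.
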