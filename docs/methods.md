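# Methods

## Model

`growthfit` models a growth curve as the standard three-parameter
logistic equation,

    N(t) = K / (1 + A e^(-r t)),    A = (K - N0) / N0,

the solution of dN/dt = r N (1 - N/K) with N(0) = N0.  `K` is the
carrying capacity (upper asymptote, in reading units), `r` the intrinsic
per-capita growth rate (inverse time units), and `N0` the population
size at time zero.  The model assumes a single sigmoidal growth phase:
no lag-phase term, no diauxic shift, no death phase.  Wells exhibiting
those features will still be fitted, but `sigma` (the residual standard
error) will be inflated and the parameter estimates should be treated
with caution — inspecting fits with large `sigma` is the recommended
triage.

Derived metrics:

* **Doubling time** `t_dt = ln 2 / r` — the generation time the
  population would have far from carrying capacity, where growth is
  unrestricted.  It is a strictly decreasing function of `r`, so across
  any batch of fits the Spearman correlation between `r` and `t_dt` is
  exactly −1.
* **Inflection time** `t_mid = ln A / r` — where the curve reaches
  `K/2`.  Undefined (reported as NaN) for declining fits with `N0 > K`.
* **Logistic AUC** — the definite integral of the fitted curve, using
  the closed-form antiderivative `(K/r) ln(e^(rt) + A)`.  The log term
  is evaluated as `logaddexp(rt, ln A)` for `A > 0` and as
  `rt + log1p(A e^(-rt))` for `A < 0`, so `e^(rt)` never overflows —
  relevant whenever rates are expressed per minute over a day-long run.
  The closed form is verified against adaptive quadrature (relative
  1e-8 over randomized parameter draws) in the test suite.
* **Empirical AUC** — the composite trapezoid sum over the observed
  (background-corrected) readings.  When the requested window edge
  falls between two sample times, the final trapezoid is truncated by
  linear interpolation; points beyond the edge are excluded.

## Background correction

Raw readings carry the media's absorbance.  Two mutually exclusive
modes:

* `min_value` (default): subtract the per-well minimum reading.  Needs
  no blank well, and makes the fitted parameters exactly invariant to
  any constant offset in the raw data.  Note that on a noise-free curve
  this subtracts `N0 + background`, not just the background, so the
  corrected signal is the true logistic shifted down by `N0`; the
  resulting bias is negligible whenever `N0 << K` (the usual inoculum
  regime, where dilution puts `N0/K` around 10^-2–10^-4) but it is the
  reason exactness tests fit uncorrected data.
* `blank_series`: subtract a designated media-only well point by point.
  Negative corrected values are retained rather than clipped — clipping
  would bias the many information-poor early-time points — and flagged
  via `has_negative`.

## Fitting

Residuals `y_i − N(t_i)` are minimized with scipy's bounded
trust-region reflective least-squares solver.  The classical reference
algorithm for this problem is unbounded Levenberg–Marquardt; the
bounded variant finds the same optimum on well-behaved data while
keeping pathological wells inside a sane box:

* `r ∈ (0, r_max]`, `r_max` = 20 per time unit by default — caps
  step-function-like fits on spiky artefacts.  Configurable.
* `N0 ∈ [ε, max(y)]` with `ε = 1e-6·max(y)` — accommodates the zeros
  produced by min-value correction and slightly negative blank-corrected
  points.
* `K ∈ (0, 1e6·max(y)]`.  The cap is deliberately loose: a slow curve
  (`r ≈ 0.1/h`, tiny inoculum) may reach only a fraction of a percent of
  `K` within 24 h, and any tight cap tied to the observed maximum would
  then exclude the true value.  1e6 never binds in practice but keeps
  the solver out of overflow territory.  Configurable via
  `k_max_factor`.

Starting point: `K₀ = max(y)`, `N0₀ = max(y₁, ε)`, and `r₀` from the
slope of a least-squares line through `ln(y + ε)` versus `t` over the
early-exponential points (between 10 % and 50 % of the maximum), falling
back to 1 per time unit when fewer than 3 such points exist or the slope
is non-positive.

Solver controls are frozen at `ftol = xtol = 1e-10`, `gtol = 1e-12`, at
most 1000 residual evaluations.  Standard errors come from the
Jacobian-based covariance `σ²(JᵀJ)⁻¹` (via SVD); when the Jacobian is
rank-deficient they are reported as absent, not zero.
`σ = sqrt(RSS/dof)` with `dof = n − 3`.

Non-convergence is data, not an exception: constant, all-zero, or
monotone-decreasing wells and optimizer failures return a result with
`converged = False` and a diagnostic note, so one bad well never kills a
plate run.  Fits that land at `N0 > K` (declining curves, typically
noisy flat wells) are permitted and flagged in the note.

## Synthetic data

The generator emulates a plate-reader acquisition: readings on a
regular grid — by default every 10 minutes for 24 hours, i.e. 145
points with time in hours — equal to the logistic trajectory plus a
constant background offset plus additive i.i.d. Gaussian noise
(`noise_sd = 0.005` is typical OD600 instrument noise).  Per-well seeds
on a plate are spawned from one master seed via
`numpy.random.SeedSequence`, in well order, so a plate is reproducible
from a single integer while wells get independent noise streams.

What it deliberately does not simulate: lag and death phases, diauxie,
heteroscedastic or multiplicative noise, evaporation and edge effects,
well-to-well biological variation.  Passing tests therefore demonstrate
correctness of the estimator under the stated model, not robustness to
every artefact of real plates; the residual `sigma` is the user's
handle on model misfit in real data.

## Numerical choices

* Trajectory evaluation switches between two algebraic forms of the
  logistic depending on the sign of `rt`, so neither exponential can
  overflow.
* Summary CSVs print floats at 17 significant digits; reading them back
  with a correctly-rounding parser reproduces every value bit-for-bit.
  (Plate parsing converts through numpy's string parser for the same
  reason — pandas' default fast parser can be one ulp off.)
* Exactness of the Spearman ρ = −1 property is asserted with the
  integer rank-difference formula `1 − 6Σd²/(n(n²−1))`, which is exact
  for tie-free data, with `scipy.stats.spearmanr` as an independent
  cross-check.
* Problem sizes in the test and acceptance runs — 30-draw recovery
  sweeps, 1000-draw quadrature sweeps, 100-replicate noise studies,
  one 96-well end-to-end plate — were chosen to exercise each property
  across its parameter range while keeping the default suite fast to
  iterate on.

## Known limitations

* Single-phase logistic only; no Gompertz/Baranyi/Richards alternatives
  and no lag-time parameter.
* `K` and `r` are poorly identified when a curve is far from plateau at
  the end of the run; the fit is then effectively exponential and the
  reported standard errors (which grow accordingly) must be consulted.
* Min-value correction shifts the whole curve down by `N0` on
  noise-free data (see above), biasing the inoculum estimate; for
  precise `N0` estimates with a known blank, prefer `blank_series`.
* No vendor-specific plate-reader export parsers; inputs must be plain
  wide CSV/TSV.
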