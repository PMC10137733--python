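# Methods

This note records the model this package implements, the conventions it
fixes where the underlying theory leaves freedom, and the numerical choices
that matter for interpreting its output.

## Model

A cell's slow internal state X (scalar) and fast microenvironment Y
(scalar) are coupled through a sensing channel P(Y|X).  One decision step
of duration τ replaces the prior P(X) by the posterior P(X|y) for an
observed y.  Everything else follows from three ingredients:

1. **The channel.**  Y|X=x is Gaussian with mean F(x) and standard
   deviation σ_{Y|X}(x) = b + g(x − X̄), where b = F(X̄) − Ȳ and
   g = |F′(X̄)| come from linearizing the (possibly unknown) sensing
   function F around the mean internal state.  b and g depend only on
   environment moments, never on x.
2. **The Gibbs steady state.**  The long-time internal distribution is
   P(x) ∝ exp(−β ∫ˣ S(Y|X=u) du − β′x) with S the conditional entropy of
   the channel, β a sensitivity and β′ a tilt that absorbs the
   x-independent evidence term ∫ P(y|x) ln P(y) dy.
3. **The mesoscopic picture.**  (X, Y) is an Itô diffusion; under timescale
   separation the joint Fokker–Planck equation splits into a fast equation
   for P(Y|X), a slow 1-D equation whose stationary solution is
   P(x) ∝ exp(∫ˣ K₂/σ₂₂), and the coupling constraint
   2∂_y(σ₁₂P) + σ₂₂∂_yP = 0.  Setting K₂(x) = −βσ₂₂S(Y|X=x) − β′σ₂₂ makes
   pictures 2 and 3 agree exactly.

## Conventions fixed by consistency

Several printed forms of this theory admit more than one reading; the
package fixes each by requiring internal consistency, and the tests lock
the choices in.

* **Fisher information sign.**  F = E[−d²ln p/dx²], so a Gaussian of
  standard deviation σ gives +1/σ², and ½Δ²F is the small-shift KL cost.
* **Standard deviation, not variance, is linear in x.**  Only
  σ_{Y|X}(x) = b + g(x − X̄) is simultaneously consistent with the Gaussian
  entropy ½ln(2πe σ²), the log-integrand ln(b + g(x − X̄)) of the
  linear-sensing steady state, and the averaged law σ²_{Y|X} = b² + g²σ_x².
  The literal quadratic-variance reading is available as
  `variance_mode="variance_literal"` for exploration only.
* **Entropy convention.**  `eq29_literal` (default) folds the additive
  constant ½ln(2πe) of the Gaussian entropy into β′, so the linear-sensing
  entropy profile is ln σ(x); `full_gaussian` keeps the constant in the
  integrand (equivalent to shifting β′ by β·½ln(2πe)).
* **Sensor-ON closed form.**  Direct integration of the exponent gives
  (b + g(x − X̄))^{−β(x − X̄ + b/g)} e^{(β−β′)x}; the sign is fixed by
  pointwise agreement with the cumulative-quadrature density (relative sup
  gap < 1e−6 on fine grids), which is always the primary computation.
* **Modality vs sign of β.**  With this exponent, d²lnP/dx² at the interior
  stationary point is −βg/σ(x), so β > 0 yields the interior maximum
  (interior-unimodal) and β < 0 the boundary-bimodal regime.  Narrative
  accounts of this switch sometimes attach the opposite labels; the package
  follows the derivative test, and only the *existence* of the sign switch
  is substance.
* **Langevin ↔ Fokker–Planck dictionary.**  FP diffusion coefficients are
  σ_pq = (ΣΣᵀ)_pq/2; an OU slow variable dX = −kX dt + Σ dW therefore has
  stationary variance σ₂₂/k.  The Euler–Maruyama variance test across
  k ∈ {0.5, 1, 2} pins this convention.
* **Drift from entropy.**  Differentiating the Gibbs exponent gives the
  constant tilt term −β′σ₂₂ (not a term growing with x); the implementation
  uses K₂(x) = −βσ₂₂S(x) − β′σ₂₂, the unique choice for which the slow
  stationary solution reproduces the Gibbs steady state.
* **The update-normalization ratio β̃.**  Its printed double-integral
  definition is not a probability-mass ratio for normalized conditionals;
  it is implemented purely as a windowed-quadrature diagnostic (posterior
  mass captured by a declared X′-window over prior-and-channel mass
  captured by a declared (X,Y)-window).  All identity tests use β̃ = 1,
  the value it takes on full supports.

## Learning modes

`observed` draws one y per step from the environment-truth density (by
default the model-implied evidence of the current prior, emulating a cell
that senses a world consistent with its beliefs; an external truth density
can be supplied to simulate mismatch).  `averaged` is the deterministic
surrogate P′(x) ∝ P(x)·exp(E_{P(Y)}[ln P(y|x)]): for the conjugate-Gaussian
chain it reproduces the exact posterior-precision recursion, leaves the
prior mean untouched, and makes the variance decay strictly monotone — the
property the entropy-decay results need.  Note the naive candidate
E_Y[posterior] is the prior itself and carries no information.

Randomness: the step-t observation stream is `default_rng([seed, t])`, so
trajectories are reproducible and extendable without replaying history.

## LEUP comparison

The maximum-entropy (least-microenvironmental-uncertainty) distribution
P(x) ∝ exp(−βS(Y|X=x) − β′x) uses the entropy itself where the Bayesian
steady state uses its cumulative integral.  `compare_leup_bayes` compares
the two after folding the domain-mean entropy level into the Bayes tilt —
exactly the cancellation the evidence term provides at the learning fixed
point — so constant profiles coincide to machine precision.  For
nonconstant profiles on a domain of width w both normalized densities scale
like 1/w; the raw sup-norm difference therefore saturates at
|β||S(x̂) − S′(x̂)|/2 while the scale-relative sup-norm and the L1 distance
vanish linearly in w.  The localization (mean-value-theorem) statement is
asserted on the scale-relative distance.

## Numerical choices

* Uniform grids, trapezoidal quadrature throughout; default 2001 points.
  Cumulative exponents use the cumulative trapezoid (O(h²)); tests that
  need 1e−6-level agreement with closed forms use finer grids because the
  entropy curvature 1/σ(x)² is large near the positivity edge.
* 0·ln 0 := 0; densities clipped at 1e−300 before logs (clip events are
  logged at debug level).  Densities count as normalized when the integral
  is within 1e−6 of one; `normalize` brings them within 1e−8.
* Sensing domains are truncated (with a logged warning) to
  {x : b + g(x − X̄) ≥ 1e−6}; the sensor-OFF half-line is truncated where
  the exponential tail mass drops below 1e−10.
* KL-shift computations translate the density by an exact number of grid
  cells when the shift is a node multiple (no interpolation error) and
  interpolate ln p otherwise; shifts pushing more than 1e−10 mass off-grid
  are rejected.
* Euler–Maruyama: Itô stepping, per-step Cholesky of twice the FP diffusion
  matrix, fast rates scaled by 1/ε (exercised at ε ∈ {0.1, 0.01}); blow-up
  aborts with the step index.  Slow confined simulations use reflecting
  boundaries (the linear-sensing drift diverges at the positivity edge),
  20% burn-in, and thinning to at most 4·10⁵ retained samples.
* Stationary-variance estimates take second moments around the ensemble
  grand mean, with the standard error across independent paths; per-path
  centering would be biased low by ~2τ/T for window T and relaxation time
  τ.  Simulation sizes (300–1000 paths × 6–16·10³ steps) put the
  empirical-CDF error a comfortable factor below the 0.01–0.02 KS
  tolerances used in the tests.
* Modality classification counts strict interior maxima with plateau
  merging at relative tolerance 1e−12; a boundary is a mode only if its
  density exceeds the adjacent interior value; interior stationary points
  of linear-sensing solutions are refined analytically via
  x* = X̄ + (e^{−β′/β} − b)/g.

## What the synthetic conditions do and do not show

The canonical scenario (b = 2, X̄ = 2, β′ = 0, g ∈ {0, 1}) and the Gaussian
channel with sd linear in x are the study conditions; the generators
emulate exactly these.  Passing tests demonstrate the internal consistency
of the theory — identities, regime switches, the mesoscopic bridge — under
Gaussian noise, a linearized channel, scalar X and Y, and Markovian
dynamics.  They say nothing about non-Gaussian microenvironments,
multivariate internal states beyond the additive product form
(`product_form_pmi`), history-dependent (non-Markov) environments, or
multicellular coupling, all of which are out of scope.

## Known limitations

* The Gaussian channel means evidence and posteriors are computed on finite
  y-grids; a coverage guard rejects grids capturing < 99.9% of the evidence
  mass rather than silently truncating.
* `beta_tilde` is a diagnostic, not a calibrated physical quantity.
* The fast-conditional and slow-simulation densities are histogram
  estimates; their KS comparisons are limited by the autocorrelation time
  of the underlying diffusion, not by the raw sample count.
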