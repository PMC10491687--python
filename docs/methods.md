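# Methods

## Model and assumptions

The package simulates a compartmental model of malnutrition transmission
with four state variables: nutrient-susceptible females `S_f`, malnourished
boys `M_b`, malnourished girls `M_g` and underweight individuals `U`.
States are continuous person-counts (the ODE limit of a large population);
all rates are per day.  Transfer out of the susceptible pool is mass-action
(`λ_b S_f M_b`, `λ_g S_f M_g`); progression to and return from the
underweight class are linear; girls additionally recover to the susceptible
pool at rate `δ_g`; recruitment `B` plus vertical spread `ε` enter the
susceptible class and a common death rate `ϑ` drains every compartment,
with an extra restoration exit `ϑ_b` for malnourished boys.  Summing the
equations gives the total-population drift `(B+ε) − ϑN − ϑ_b M_b`, an
identity the test suite enforces to rounding accuracy.

Two tabulated treatment-rate parameters, `ϑ1` and `ϑ2`, appear in the
model's parameter listing but in none of its equations.  They are stored on
`ModelParameters` (validated to `[0,1]`) and never used; tests pin the fact
that they cannot influence the vector field.

The feasible region is the nonnegative orthant with total population at
most `(B+ε)/ϑ`; the malnutrition-free state is
`E0 = ((B+ε)/ϑ, 0, 0, 0)`.  No closed form exists for an endemic state, so
`endemic_equilibrium` locates one numerically: a coarse explicit-midpoint
relaxation (step 0.5 d over 2000 d, started just off `E0`) supplies the
long-run state, which a Jacobian-based root solve (scipy `hybr` with the
analytic Jacobian) polishes.  A state is reported only if
`‖drift‖∞ < 1e−10` with all components strictly positive; otherwise the
result is "not found", never a spurious root.

## Thresholds

The deterministic basic reproduction number is evaluated from its closed
form (see README).  The next-generation construction is *also* exposed:
`next_generation_matrices` builds the 4×4 new-infection matrix `F` and
transition matrix `V` at `E0` and `ngm_spectral_radius` returns
`ρ(F V⁻¹)`.  The closed form depends only on the girls' transfer rate
`λ_g` while `F` carries both transfer rates, so the two quantities are
reported side by side and deliberately *not* asserted equal: the package
treats the closed form as canonical for thresholds and keeps the matrix
construction as an independent diagnostic rather than silently reconciling
the two.

The stochastic threshold `R0^s` and the Lyapunov constants
`ψ_i = (B+ε)/(i-th denominator factor)`, `ψ5 = 4(B+ε)[(R0^s)^{1/4} − 1]`
require each denominator factor positive; violating noise raises a
`NoiseRegimeError` rather than returning a value outside the formula's
regime.  Persistence classification follows the sufficient condition only
(`R0^s > 1` ⇒ "persist"); no extinction threshold is claimed below 1.

## Special functions

`mittag_leffler` evaluates `E_Λ(z) = Σ z^k/Γ(Λk+1)` with a partitioned
strategy.  For `z ≥ −1` the series is summed in double precision with
term-ratio stopping at 1e−14 (no harmful cancellation there).  For
`z < −1` the alternating series cancels on the scale of its largest term,
`~exp(|z|^{1/Λ})` — up to ~10^935 inside the supported range — and the
rounding of the gamma argument `Λk+1` alone already exceeds a 1e−10 budget
once terms pass ~1e3, so the function is instead evaluated through its
complete-monotonicity integral

    E_Λ(−x) = (sin Λπ/π) ∫_0^∞ e^{−u} u^{Λ−1} x / (u^{2Λ} + 2x u^Λ cos Λπ + x²) du,

whose denominator is bounded below by `x² sin²Λπ`; adaptive quadrature
reaches ~1e−13 relative accuracy across the grid used in the tests.
Arguments with `|z| > 15` raise instead of degrading silently (the model
never needs them), and a quadrature whose achieved-error estimate exceeds
1e−11 relative raises with that estimate.  The frozen test references were
produced by an arbitrary-precision series oracle with working precision
sized to the cancellation scale (up to ~990 digits); a live closed-form
check at `Λ = 1/2` (`exp(z²) erfc(−z)`) and the `E_1 = exp` identity guard
the implementation independently.

Normalizations: the exponential-decay kernel uses `M̄(Λ) = 2/(2−Λ)`
throughout (note `M̄(1) = 2`; the scheme below uses this printed constant
consistently rather than renormalising to 1), and the Mittag-Leffler kernel
uses `ABC(Λ) = 1 − Λ + Λ/Γ(Λ)` with exact endpoint values 1.

## Integrators

**Grid.**  All regimes share one uniform step `Δζ`; switch times must sit
on the grid within 1e−9 relative or scheduling fails loudly.  Degenerate
regimes (zero length) contribute a single boundary point.

**Classical branch** is the explicit three-step Adams–Bashforth scheme,
weights `(23/12, −16/12, 5/12)·Δζ` on the three most recent field values.
Multistep startup: the first two grid values are produced by classical
fourth-order Runge–Kutta at Δζ/10 sub-steps, preserving third order
without inventing history.

**Power-law branch** uses the three-point fractional multistep scheme: the
state at grid index `m` is reconstructed from an anchor state plus
`Δζ^Λ`-scaled history sums of zeroth, first and second differences of the
field, weighted by

    ℑ1(u) = (u+1)^Λ − u^Λ
    ℑ2(u) = (u+1)^Λ (u+2Λ+3) − u^Λ (u+3Λ+3)
    ℑ3(u) = (u+1)^Λ (2u² + (3Λ+10)u + 2Λ²+9Λ+12) − u^Λ (2u² + (5Λ+10)u + 6Λ²+18Λ+12)

with gap `u = m−1−ς` and prefactors `Δζ^Λ/Γ(Λ+1)`, `Δζ^Λ/Γ(Λ+2)`,
`ΛΔζ^Λ/(2Γ(Λ+3))`.  The newest field value entering a step is the lagged,
already-computed one, keeping the scheme explicit; the full history is
retained (O(n²) work — acceptable at desk scale, no short-memory
truncation).  The weights are implemented in the real-valued sign pattern
above; a published variant with the opposite sign convention in ℑ1/ℑ3 is
reachable through an explicit `as_printed` switch, which raises when it
produces a fractional power of a negative base and is excluded from the
default path because its Λ = 1 limit does not collapse to the classical
scheme.  Two startup choices matter: the first two steps are RK4-bootstrapped
(as in the classical branch), and the reconstruction is anchored at the
bootstrap terminal state, which carries the first two steps' panel of the
memory integral classically.  This makes the Λ = 1 limit agree with
three-step Adams–Bashforth *exactly* and costs an O(Δζ) startup error that
dominates the measured error of the branch (0.19% maximum relative error
against `E_Λ(−t^Λ)` at Λ = 0.7, Δζ = 1e−3 on [0, 2], halving with Δζ).

**Exponential-decay branch**: state = anchor + `(1−Λ)/M̄(Λ)`·(lagged field)
+ `Λ/M̄(Λ)`·(cumulative Adams–Bashforth quadrature of the field, including
the two bootstrap increments).  At Λ = 1 the local term vanishes and the
accumulation is scaled by `1/M̄(1) = 1/2` — the coefficient structure's own
limit, verified exactly on state-independent fields.  The branch is
cross-checked by self-convergence against a first-order rectangle
discretization of the same integral form on a 100× finer grid, away from
the `t = 0⁺` boundary layer that the local term induces.

**Mittag-Leffler kernel branch**: state = anchor + `c_loc`·(lagged field) +
`Λ/ABC(Λ)`·(the power-law history sums).  The local coefficient defaults to
the integral-operator value `c_loc = (1−Λ)/ABC(Λ)`, under which the Λ = 1
limit coincides with the power-law branch (and hence the classical scheme)
to machine precision; the published alternative `Λ/ABC(Λ)` is available as
`local_coefficient="as_printed"` but retains a spurious O(1) local offset
at Λ = 1, which is why it is not the default.  The two differ per step by
exactly `(2Λ−1)/ABC(Λ)`·field, a relation the tests pin.

**Stochastic branch** extends the classical scheme with noise terms pairing
Brownian increments at lags (0, 1, 2) behind the step with the diffusion
amplitude at the states of the same lags, using the same
`(23/12, −16/12, 5/12)` weights, as a forward recursion from the regime
start; the two bootstrap steps carry a single Euler–Maruyama noise term.
With zero noise (or zero increments) the branch is arithmetically identical
to the classical one.  An Euler–Maruyama integrator (strong order 1/2,
verified on geometric Brownian motion with shared refined paths) serves as
the independent reference; both accept a `diffusion_fn` override so
additive-noise test processes (Ornstein–Uhlenbeck) reuse the same code.

**Positivity** is audited, never enforced: no scheme clips, and
`positivity_check` reports per-compartment minima and the first violation.
The baseline deterministic prefix is verified nonnegative; the stochastic
regime can and occasionally does undershoot zero at large noise, which the
audit surfaces.

## Synthetic data

The study design is a single tabulated configuration, so the generator has
two jobs.  `brownian_increments` draws the four independent `Normal(0, Δζ)`
increment sequences from a numpy `SeedSequence`-seeded generator; ensembles
spawn one child stream per path from the root seed, making members
independent yet bit-reproducible.  `perturbed_scenarios` surrounds the
design point with median-preserving log-normal jitter: each rate is
multiplied by `exp(sZ)` with `s = sqrt(log(1+rsd²))`, so factors are
positive by construction, the median factor is exactly 1, and the relative
standard deviation equals the requested `rsd` (default experiments use
0.1).  The two placeholder treatment rates are left untouched, as are the
noise intensities and initial state — those are study settings, not
sampled quantities.

What the generator does *not* emulate: real anthropometric survey data
(sampling noise, reporting bias, age structure), seasonality, or any
fitted-parameter uncertainty — no fitting is performed anywhere.  Passing
tests therefore demonstrate the *methods* (schemes, thresholds,
diagnostics) against mathematically known ground truth, not agreement of
the model with field data.

## Ensemble and ergodicity diagnostics

`run_ensemble` shares the deterministic prefix across paths and propagates
the stochastic regime in a batched mirror of the per-path scheme whose
elementwise arithmetic is structured identically, so every ensemble member
is bit-identical to a stand-alone run on the same substream (a property the
tests assert).  Moments are accumulated by a streaming Welford pass over
paths (sample variance, ddof = 1, zero for a single path) and
cross-checked against a two-pass computation; quantiles (2.5/50/97.5%) use
linear interpolation of order statistics; histograms use equal-width bins
over the observed range with a moment-fitted normal, matching the
`N(mean, variance)` overlays used for stationary-distribution frequency
plots.  Counts conserve the path total by construction.

`ergodic_average_check` compares the time average of a statistic along one
long stochastic-regime path (batch-means standard error, 20 batches)
against its ensemble average at a late terminal time (Monte-Carlo standard
error).  It is a diagnostic, asserted only for the Ornstein–Uhlenbeck
oracle where the stationary law (`mean 0, variance σ²/2a`) is known; for
the malnutrition model the report is informative — at the baseline rates
the stationary law concentrates near the malnutrition-free state, and short
ensembles visibly have not relaxed, which the diagnostic makes explicit.

`convergence_order` fits the log–log slope of an error ladder (≥3 halved
steps), reports "exact" when all errors sit at rounding level (schemes are
exact on constant fields), and refuses to quote an order for non-monotone
ladders.

## Problem sizes and tolerances

The verification suite uses: Δζ ∈ {0.04, 0.02, 0.01} on [0, 2] for the
classical order (accepted band [2.7, 3.3]); Δζ ∈ {4e−3, 2e−3, 1e−3} at
Λ = 0.7 for the fractional branch (≤2% relative, monotone under halving);
512→64-step ladders with 2000 shared paths for the strong order of
Euler–Maruyama (band [0.35, 0.65]); 1000 paths at σ = 0.01, Δζ = 0.01,
T = 10 for small-noise mean consistency (within 3 Monte-Carlo standard
errors of the noiseless flow); 2000 paths / T = 20 and one path / T = 500
for the Ornstein–Uhlenbeck stationary-variance (10%) and ergodic-average
(3 SE) checks.  These sizes were chosen so each check resolves its target
comfortably on a single CPU; all random checks run under fixed seeds.

## Known limitations

- The schemes are explicit and not positivity-preserving; stiff parameter
  regions or large noise may require smaller steps than the defaults.
- Fractional branches keep full history: O(n²) time, O(n) memory per
  component; horizons beyond ~10⁵ steps become expensive.
- The exponential-decay branch inherits the `t = 0⁺` jump of its integral
  form's local term; comparisons near the regime switch should exclude the
  first few steps.
- The persistence classification is a one-sided certificate; `R0^s ≤ 1`
  states only that the certificate fails, not that malnutrition dies out.
- `ngm_spectral_radius` and the closed-form `R0` are distinct published
  objects and are reported separately by design; downstream code should not
  assume their equality.
- No Lévy/Poisson jump noise, no implicit or adaptive stepping, no
  parameter fitting to field data.
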