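# Methods

## Model

A network of `N` species follows `dx_i/dt = ψ_i(k, x) + a_i h(t)` with
non-negative rates `k`, locally Lipschitz right-hand sides `ψ_i` on the
non-negative orthant (a contract enforced by the model builders, not
re-checked generically), and a single unobserved input `h(t)` with no
assumed functional form. Observations are taken at times `t_0 … t_n`
under one of two noise models: additive Gaussian
(`x_obs = x + ε, ε ~ N(0, σ²)`) or multiplicative log-normal
(`x_obs = x·exp(ε)`; the log-observation is Gaussian around `log x` and
the density carries a `−log x_obs` Jacobian term). The log-normal model
requires strictly positive trajectories and data.

Feedback from the network into `h`, multiple simultaneous latent
inputs, and non-affine observation functions are out of scope: with a
non-linear readout the extraction identity below no longer isolates `h`
linearly.

## Two-step estimation

**Step 1 — smoothing.** Each observed component is fitted with a cubic
B-spline expansion minimising `‖y − Φβ‖² + λ β'D'Dβ`, where `D` is the
order-2 difference operator on coefficients — the standard P-spline
finite-difference surrogate for the curvature integral. The basis uses
uniform, unclamped knots extending three intervals beyond each end of
the time domain, giving exactly `K` basis functions; uniform spacing is
what makes the difference penalty's null space map exactly onto straight
lines, so the `λ → ∞` limit is the least-squares line (verified to
~1e−7 in the tests). Defaults: `K = min(n+1, 20)` (the cross-validated
penalty controls the effective flexibility, so `K` only needs
headroom), and a 25-point logarithmic `λ` grid `1e−4 … 1e4`. `λ_i` is
chosen per component by exact leave-one-out refitting (not a hat-matrix
shortcut — at 30 points per series the `(n+1) × 25` small solves are
cheap and the score is exact), with ties broken toward the smoother
fit. For log-normal noise the spline is fitted on the log scale —
keeping the additive-error smoothing criterion coherent with the noise
model — and mapped back via `x = exp(g)`, `dx/dt = exp(g)·dg/dt`. Which
scale the cross-validation should use is a genuine design choice; we
cross-validate on the same (log) scale the spline is fitted on.

**Step 2 — likelihood.** By the extraction identity
`h = (dx_i/dt − ψ_i)/a_i`, each supported component yields a residual
estimate `h⁰_i = dx̂_i/dt − ψ_i(k, x̂)` of `a_i h`; these are pooled
pointwise, `ĥ_a = (1/N_a) Σ h⁰_i/a_i`. The forced system is re-solved
with `ĥ_a` and the observation likelihood evaluated; `σ²` has the
closed-form maximiser "mean squared (log-)residual over all observed
entries" and is profiled out at every objective evaluation. Free rates
(log-transformed to preserve positivity) and initial values flagged
unknown are estimated in the same objective. The residual table is
recomputed at every candidate rate vector; the splines themselves are
fitted once per dataset and cached.

*Identifiability.* `a_i h = (ξ a_i)(h/ξ)` for any `ξ ≠ 0`, so weights
are normalised to `Σ|a_i| = 1`; a support of size one means `a = ±1`
(both signs evaluated, the better kept). The joint sign of `(a, h)`
remains free; estimates are returned oriented so that the latent course
has non-negative mean. This convention matters when reading weights as
activation/inhibition and is what the repair edit interpreter assumes.

*Optimisation.* The constrained weight vector is parameterised as
`a = u/Σ|u_i|` over unconstrained `u` (degenerate `u ≈ 0` rejected by a
large finite penalty, which also replaces `−∞` likelihoods so the
simplex stays well-defined). Nelder–Mead with `xatol 1e−4`,
`fatol 1e−8`, and a budget of `300·dim` evaluations; two starts — one
informed, one randomly perturbed (seeded). The informed start sets
`|u_i|` to the RMS of `h⁰_i` with signs from the correlation against
the strongest component's residual, and initialises free rates by
non-negative least squares of the smoothed derivatives on the flow
terms (gradient matching). With these starts, additional random
restarts were not worth their cost; the restart count is a parameter.

## Partial observation

With `M < N` observed channels (affine in single model coordinates —
the model must already be expressed in observed coordinates; a helper
performs the affine substitution automatically for linear networks), a
preliminary pass solves the system with `h ≡ 0` to stand in for the
unobserved coordinates, whose initial values are always treated as
unknown parameters. The procedure then alternates: residual extraction
and ML update on the observed channels (support restricted to observed
components; the likelihood is a product over observed channels only),
then re-solution of the unobserved coordinates under the current
`(a, ĥ)`. Convergence: `|ΔlogL| < 1e−6` and `max|Δĥ| < 1e−4`, capped
at 100 iterations. The alternation is not guaranteed to be monotone;
when it stalls or oscillates (five iterations without likelihood
improvement) the best-likelihood iterate is returned with the
convergence flag cleared. Initial values of observed coordinates are
taken from the model when known and initialised from the smoothed value
at `t_0` when flagged unknown.

## Model selection and repair

Candidate supports are scored by `AIC = −2 logL + 2 N_a` or
`BIC = −2 logL + penalty·N_a`, where `N_a` is the number of nonzero
weights — the only part of the parameter count that varies between the
nested candidates. Two readings of the BIC penalty are implemented:
`log((n+1)·N)` (default; the log of the total observation count, `N`
counting observed components) and the heavier `N·log(n+1)`
(`bic_sample="per_time"`). Search strategies: best subset (exhaustive,
`2^N` fits), forward (grow from empty; a component once added stays),
backward (prune from full). Acceptance requires a strict criterion
decrease with an `1e−6` float guard; step ties go to the lower
component index. A failing candidate fit scores `+∞` and the search
continues.

Repair loop: fit the current structure (free rates, null model), run
support selection; if a latent component improves the criterion,
interpret its weight pattern as an edit — by default a single flow from
the most negatively weighted component to the most positively weighted
one — apply it (new free rate, initialised at 0.1), and repeat. Stops
on a null selection, an uninterpretable pattern (no positive/negative
pair), or the edit budget. The criterion is compared within a
structure; rate counts across structures are not penalised, since `N_a`
is the only varying dimension the criterion tracks.

## Synthetic benchmark conditions

The generator reproduces the reference study conditions: random
mass-transport networks (`dx_i/dt = Σ_u (k_iu x_u − k_ui x_i) + a_i h`)
with `k_iu ~ U[0,1]`, `a_i ~ U[−1,1]` then L1-normalised, 30 equally
spaced time points, log-normal noise at `σ ∈ {0.01, 0.1, 0.3}`, and
100%/67%/33% of components observed (`⌈fN⌉` lowest indices). Values
the reference protocol leaves open are fixed once as package defaults:
time span `[0, 10]`; initial values `U[0.5, 1.5]`; the shared latent
input is a deterministic Gaussian bump (unit height, peak at 40% of the
span, width 15% of the span) standing in for the unpublished
single-peaked course. A draw whose noise-free trajectories touch zero
cannot carry log-normal noise and is redrawn deterministically from the
same seed stream. Estimated latent courses are compared to the truth by
`s = (1/(n+1)) Σ |ĥ(t_j) − h(t_j)|` (the mean-≥-0 orientation
convention aligns signs with the positive bump).

The cascade experiment defaults: forward rates (0.15, 0.29, 0.20),
feedback 0.2, initial state (2.0, 0.5, 0.5, 0.5), span `[0, 30]`,
log-normal `σ = 0.1`, all four components observed (feedback rate,
noise level, initial state and span are package choices; the reference
experiment does not state them).

What the generator does **not** emulate: non-linear kinetics,
correlated or heteroscedastic noise beyond the two models above,
missing individual observations, and irregular sampling. Passing tests
therefore demonstrate recovery under clean, regularly sampled,
independently noised linear dynamics — not performance on real
immunoblot data.

## Numerical choices

- Default integrator: adaptive RK45, `rtol 1e−8`, `atol 1e−10`. A
  piecewise-linear latent signal has derivative kinks at its grid
  points, so integration proceeds segment-by-segment between knots
  (otherwise the controller's error estimate is invalid and
  reproducibility of likelihood identities degrades to ~1e−4). A
  fixed-step classical RK4 is available and is what the order-
  convergence test exercises.
- Linear(-affine) systems use an exact propagator in the likelihood
  loop: with `h` piecewise linear, each interval is an LTI problem and
  one Van Loan block matrix exponential gives the step matrix and both
  forcing integrals; the trajectory is exact up to `expm` rounding
  (matches the adaptive solver to ~1e−9, at a fraction of the cost).
- Latent-signal interpolation off-grid: piecewise linear by default
  (bounded, shape-preserving; and exactly what the propagator assumes);
  cubic selectable. Grid points always return the stored values
  exactly.
- State non-negativity is not enforced during integration; under a
  strong negative latent forcing trajectories may transiently go
  negative, in which case a log-normal likelihood is `−∞` (scored as a
  rejected candidate, not an exception).
- Degenerate inputs: an all-zero weight vector cannot be aggregated
  (error); an empty support is the null model; `σ̂²` is floored at
  1e−300 before taking logs.

## Problem sizes

The test suite and the acceptance script run the studies at sizes
chosen for single-CPU execution: 100 replicates for the cascade
recovery rate, 50 replicates per simulation-study cell, 200 replicates
for the variance-estimator MSE, 15–25 seeds for the selection
behaviour checks. The study grid machinery accepts the full
27-cell × 100-replicate configuration unchanged.

## Known limitations

- The aggregation divides each residual by its weight, so components
  with small true `|a_i|` contribute noise amplified by `1/|a_i|`;
  selection then rightly drops them, which bounds how small a weight
  can be detected (at `σ = 0.01` and 30 points, roughly `|a_i| ≲ 0.1`
  after normalisation).
- Greedy forward search can stall at the null model on strongly coupled
  mass-conserving networks with mixed-sign weights: forcing a single
  component with the pooled signal overshoots the net mass input and
  can fit worse than the null, so no first step is accepted even when a
  two-component support would win decisively. Best-subset and backward
  search do not share this failure mode.
- Under the default (lighter) BIC penalty, a well-specified model can
  still admit a marginal latent component that fits smoothing residual
  noise; the `per_time` penalty reading suppresses this and makes the
  repair loop stop cleanly after the correct edit.
- In-sample likelihoods reward a latent course that absorbs measurement
  noise; `σ̂²` is correspondingly a slightly optimistic noise estimate
  under large supports.
- The diagonal CRLB `2σ⁴/(N(n+1))` for `σ̂²` assumes independent
  residuals with a correctly specified mean. The pipeline's residuals
  share the estimated latent course, whose smoothing error is
  correlated across components and time, and carry a small
  spline-approximation bias floor; the calibration test measures a
  Monte-Carlo MSE a few-fold above that bound rather than within twice
  of it.
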