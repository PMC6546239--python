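# Methods

## The problem

Nonlinear regression models in systems biology frequently have parameters
with a unique optimum but an unbounded confidence interval: along certain
directions in parameter space the predictions saturate, the weighted sum of
squares χ² stays below the likelihood-ratio threshold forever, and the
parameter is *practically non-identifiable*. Any method built on a Taylor
expansion of χ² around the optimum — notably Fisher-information standard
errors — cannot represent this boundedness: a quadratic form always crosses
every threshold. `rncfit` implements a geometric construction that retains
the local quadratic information *and* the global boundedness, using only
first- and second-order residual sensitivities evaluated once at the
optimum.

## Model and objective

Observations follow `y_D,m = y(t_m, θ_true) + ε_m` with independent
Gaussian noise `ε_m ~ N(0, σ_m²)` and known σ. The maximum-likelihood
estimate minimizes

    χ²(θ) = Σ_m [(y_D,m − y(t_m, θ)) / σ_m]².

The normalized residual map `r(θ)` embeds the N-dimensional parameter space
in M-dimensional data space; its image is the model manifold. The pullback
of the Euclidean data-space metric,

    g_{μν} = Σ_m (∂r_m/∂θ_μ)(∂r_m/∂θ_ν)     (= JᵀJ, the Fisher information),

and the Christoffel symbols of the second kind,

    Γ^μ_{αβ} = g^{μν} Σ_m (∂r_m/∂θ_ν)(∂²r_m/∂θ_α∂θ_β),

are evaluated at the optimum θ̂ and **frozen**. The geodesic equation
`θ̈^μ = −Γ̂^μ_{αβ} θ̇^α θ̇^β` with these constant coefficients is solved as a
two-point boundary value problem θ(0) = θ̂, θ(1) = θ*; the initial velocity
`v = θ̇(0)` is the Riemann normal coordinate (RNC) of θ*. The surrogate
objective is the quadratic form in RNC,

    χ̃²(θ) = χ²(θ̂) + v(θ)ᵀ ĝ v(θ).

Because the frozen geodesic equation is quadratic in the velocity, its
solutions can blow up at finite τ: infinite parameter values correspond to
finite v, the RNC domain is bounded, and χ̃² is bounded along exactly those
directions — the mechanism behind open confidence intervals. Vanishing
Christoffel symbols (linear models) recover straight geodesics,
`v = θ − θ̂`, and χ̃² degenerates to the Fisher-information quadratic form.

### Accuracy and its limits

χ̃² is exact when the manifold is extrinsically flat (the one-parameter
exponential with a single datum, and every linear model). In general it
matches χ² through the terms generated by the intrinsic connection but
neglects extrinsic curvature. Concretely, with nonzero residuals at the
optimum the two objectives already differ at second order by the term
`Σ_m r̂_m ∂²r_m/∂θ∂θ` (the full-Hessian vs Gauss-Newton gap); on data with
vanishing optimum residuals the agreement is third-order. This deviation is
deliberate — accounting for it would require the very global information
the construction avoids — and it is why surrogate profiles track original
profiles well only in a neighborhood whose size shrinks with the noise
level (see the fixture choices below). The Christoffel symbols, and hence
the quality of the approximation, depend on the parameter chart; the chart
(`natural` by default, `log` via `LogScaleModel`) is recorded in every
geometry snapshot.

## Sensitivities

* Closed-form models carry sympy expressions; first and second derivatives
  of predictions are generated symbolically and evaluated vectorized.
* ODE models integrate the forward sensitivity equations
  `Ṡ = (∂f/∂x)S + ∂f/∂θ` jointly with the state (LSODA, rtol 1e-8,
  atol 1e-10 — stiff-capable because the enzyme model separates
  timescales). Second-order sensitivities come from central finite
  differences of first-order sensitivities with per-parameter step
  `1e-4·max(|θ_k|, 1)`, symmetrized over the last two indices; generating
  the O(N³) second-order sensitivity ODE system symbolically is out of
  scope by design. A parameter within one step of a bound raises an error
  rather than silently differencing across the bound.

## Numerical geometry

* **Geodesic IVP.** DOP853 with rtol 1e-10 / atol 1e-12. A geodesic is
  declared *diverged* — a first-class outcome, not an error — when
  ‖θ‖∞ > 1e6 or ‖θ̇‖∞ > 1e12 before τ = 1; the escape time τ* is located by
  the integrator's event finder. The velocity bound exists because near a
  blow-up θ escapes only logarithmically in τ while the velocity grows
  polynomially; it also bounds the numerically evaluable surrogate domain.
* **BVP (RNC map).** Damped Newton shooting seeded with the flat-manifold
  velocity v₀ = θ* − θ̂ (exact when Γ = 0), with the endpoint sensitivity
  ∂θ(1)/∂v integrated from the variational equations. All residual
  evaluations use the same augmented system: integration bias near a
  blow-up is amplified proportionally to the terminal velocity, so mixing
  differently-stepped systems puts an artificial floor under the Newton
  residual. Fallbacks: continuation over intermediate targets, then a
  (node-capped) collocation solve. Boundary residual tolerance
  1e-8·max(1, ‖θ*‖); non-convergence raises an error carrying the best
  residual and the hint that θ* may lie beyond the manifold boundary.
* **Surrogate derivatives.** ∂v/∂θ by central finite differences of the
  BVP map (step 1e-5·max(|θ_k|, 1), warm-started); gradient 2(∂v/∂θ)ᵀĝv and
  Gauss-Newton Hessian 2(∂v/∂θ)ᵀĝ(∂v/∂θ).
* **Surrogate profile points.** Since χ̃² is exactly quadratic in v, the
  profile value at θ_i = c is `min_v vᵀĝv  s.t.  θ(1; v)_i = c`, solved in
  v-space by a Levenberg-damped Gauss-Newton KKT iteration (one forward
  shoot with endpoint sensitivities per step, no inner BVP). Iterations
  stop when the constraint is met and the feasible value stops improving
  (relative 1e-6); the damping bounds the step component along
  metric-flat directions, where the constraint is most nonlinear. Box
  bounds on nuisance parameters are not enforced on this path (they are
  inactive in all shipped analyses). An unreachable slice — no geodesic
  endpoint attains θ_i = c — terminates the profile with a *boundary*
  marker, distinct from a threshold crossing.
* **Boundary scan.** Bisection on the speed c of a unit-ĝ-norm direction
  for the smallest c whose geodesic blows up before τ = 1; by the exact
  rescaling θ_{cv}(τ) = θ_v(cτ) this is monotone in c, and the radius is
  reported in arc-length units.

## Inference

* **Fitting.** L-BFGS-B with analytic gradient 2Jᵀr, multistart from a
  seeded Latin-hypercube jitter of width max(|θ0|, 1) around the supplied
  start, clipped to bounds.
* **Thresholds.** Pointwise per-parameter profiles use the χ²₁ quantile at
  the requested confidence level (0.9889 at 68%, 3.8415 at 95%).
* **Profiles.** Outward walk in both directions with adaptive steps
  targeting Δχ² ≈ 0.1·T₉₅ per step, clipped to [1e-4, 1]·max(|θ_i|, 1) (so
  the parameter at most doubles per step; a flat direction spanning six
  orders of magnitude costs ~20 points). Nuisance parameters are
  re-optimized warm-started from a linear extrapolation of the previous
  two nuisance vectors — without the predictor step the optimizer loses
  the compensation canyon when the profiled parameter doubles. A direction
  ends by threshold crossing (with bisection refinement of each crossing),
  parameter bound, surrogate boundary, flatness (range ×10⁶ without
  crossing → open interval), or a step cap (→ explicit *undetermined*
  marker, never a silent finite endpoint).
* **Comparison.** Original and surrogate profiles are aligned on the
  original grid inside its 95% region; the report carries max/mean
  absolute χ² discrepancy and per-level agreement of the
  identifiable/non-identifiable classification.

## Synthetic data

The generator draws `y = prediction + N(0, σ²)` from a single PCG64 stream
seeded by the design seed, so every fixture is a pure function of its seed
(byte-identical CSV on regeneration). A zero design σ yields noise-free
values recorded with unit weights. What the fixtures emulate — and what
they do not — determines what passing tests mean for real data: noise is
Gaussian, homoscedastic per point, with known σ; there are no outliers, no
model misspecification, and no unknown-variance estimation.

* `model1_paper` — the single exactly-solvable datum (t=1, y=1, σ=1),
  noise-free.
* `model2_default` — three observations of `A0·e^{−k1 t}` at t = 1, 2, 3,
  θ_true = (1, 1), σ = 0.02, seed 20. The noise level is chosen so the 95%
  region reaches into the A0–k1 compensation canyon (the non-quadratic
  regime worth studying) while remaining where the frozen-Christoffel
  surrogate tracks the original profile to a few tenths of a χ² unit; at
  5% noise the approximation error at the region edge exceeds the half-unit
  scale for most noise draws.
* `model3_default` — enzyme kinetics (states S, E, C, P; parameters k1, k2,
  k3, S0; E0 = 0.4 per condition) with timescale separation
  k1 = k2 = 10 ≫ k3 = 0.1, observing S and P at ten times from 0.12 to 100
  with σ = 0.02, seed 34. The single early sample catches the tail of the
  binding transient: it pins a unique interior optimum (without it the fit
  drifts to k1, k2 → ∞ where the metric is singular) yet is weak enough
  that k1 and k2 stay below the 68% threshold toward large values — the
  regime with a well-determined ratio k2/k1 and open upper intervals that
  this fixture exists to realize. The seed is part of the frozen design;
  realizations of this marginal regime vary, and the shipped one exhibits
  it.
* `model3_dose_response` — the same enzyme system across 51 initial enzyme
  concentrations (logarithmic from 0.01 to ~3.2), product read out at two
  times per condition.

## Problem sizes and defaults

Shipped analyses use M = 1 (model 1), M = 3 (model 2), M = 20 (model 3)
observations, 2–3 multistart fits, two profile levels (68%, 95%), and
50 replicates for the coverage study; these sizes keep a full end-to-end
run of all examples in the few-minute range on a single core while leaving
every qualitative regime intact. Tolerances: fit gtol 1e-10 (outer),
profile inner optimizer ftol 1e-11/gtol 1e-7, geodesic rtol 1e-10, BVP
boundary residual 1e-8 relative — the settings that bound the round-trip
error `‖rnc_map(shoot(v)) − v‖` below 1e-6 on the oracle model.

## Known limitations

* The surrogate's evaluable domain is capped by the velocity bound; very
  distant targets in bounded directions report a boundary rather than a
  value. This is the numerical image of the manifold boundary itself.
* Constant-Christoffel geometry can also fabricate boundaries: `y = θⁿ`
  (odd n) is unbounded yet has Γ = (n−1)/θ, the same form as the genuinely
  bounded reciprocal parameterization. The method is best used where
  restricted model behavior is expected a priori.
* Structural non-identifiability (exactly redundant parameterizations)
  produces a singular metric; the error names the null-space direction,
  and the redundancy must be removed before the geometric analysis.
* The BVP limits practical use to models with few parameters; cost grows
  with both N and the stiffness of geodesics near boundaries.
* Profiles on the surrogate path ignore nuisance box bounds (see above);
  analyses whose nuisance optimum sits on a bound should use the original
  objective's profile for that parameter.
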