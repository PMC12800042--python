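# Methods

## Model and assumptions

The package integrates a five-component Caputo fractional system describing
colon-cancer treatment: tumor cells T, macrophages M, dendritic cells G,
CD4⁺ T helper cells C and a probiotic drug concentration P.  The modeling
assumptions are:

- logistic tumor growth (rate g₁, carrying capacity s₁) with saturating
  (Michaelis–Menten) kill terms by macrophages (β₁, half-saturation s₂) and
  CD4⁺ cells (ω, s₄), plus linear chemotherapy kill u₃T;
- tumor-driven recruitment of macrophages and dendritic cells through
  saturating terms; constant innate production r₁, r₂; linear natural and
  chemo-induced death (βᵢ, dᵢ);
- CD4⁺ recruitment by the probiotic through δPC/(b+P) and by immunotherapy
  through u₂C; the probiotic itself is dosed at constant rate u₁ and decays
  linearly (ϑ), so its equation is linear and decoupled — its exact solution
  u₁/ϑ + (P₀ − u₁/ϑ)E_α(−ϑt^α) is used as a solver oracle throughout;
- all drug inputs u₁, u₂, u₃ are constant doses, so the system is autonomous
  (every published simulation uses constant controls);
- the fractional order α ∈ (0, 1] is shared by all equations; the constant
  prefactor σ^(1−α) keeps time dimensions consistent.  σ has no assigned
  value in the source analysis; the package defaults to σ = 1, at which the
  scaled and unscaled systems coincide, and exposes σ for sensitivity
  exploration only.

The extended variant adds saturating cross-recruitment: g₅C/(s₂+C) to the
macrophage equation and g₆M/(s₃+M) + g₇C/(s₃+C) to the dendritic equation.
With g₅ = g₆ = g₇ = 0 it reduces exactly to the base model; no closed-form
equilibria are derived for it, and its steady states are probed only by
long-time simulation.

## Parameters

Point-valued parameters default to the literature table (s₁ = 1000,
s₂ = s₃ = s₄ = 50, r₁ = 0.3, r₂ = 0.7, β₁ = 0.1, ω = 0.3, β₂ = 0.5,
β₃ = 0.4, β₄ = 0.7, d₁ = 0.008, d₂ = 0.0008, d₃ = 0.0001, ϑ = 1, b = 0.25;
rates per unit time, populations in model cell units).  Interval-valued
parameters (g₁ ∈ [0.1, 0.9], g₂, g₃ ∈ [0.2, 0.9], g₄ ∈ [0.1, 0.9],
δ ∈ [0.15, 0.60]) default to the application baseline g₁ = 0.1, g₂ = 0.2,
g₃ = 0.3, g₄ = 0.1, δ = 0.15 with doses zero.  Values outside the literature
intervals warn rather than fail, because the published sweeps themselves
step through the whole interval.

## Numerical scheme

`D^α x = F(x)` is solved by the fractional Adams–Bashforth–Moulton
predictor–corrector (Diethelm–Ford–Freed): the equivalent Volterra equation
is discretized on a uniform grid with a product-rectangle predictor and a
product-trapezoid corrector (one pass by default, configurable).  Design
choices:

- **Full memory.**  No short-memory truncation: truncation would bias
  exactly the α-dependent transients of interest.  Cost is O(n²) per run,
  cheap at the problem sizes used (≤ 60 000 steps).
- **No clamping.**  The stepper never projects onto the nonnegative orthant;
  a post-hoc check (`TrajectorySolution.undershoot`) flags any component
  below −10⁻⁶ as a step-size failure to be rerun with smaller h.  Zero
  initial tumor stays exactly zero (the tumor-free face is invariant under
  the discrete scheme because every tumor term carries a factor T).
- **σ handling.**  The stepper integrates whatever field it is given; the
  σ^(1−α) prefactor lives in `make_field`, keeping the scheme generic.
- **Verification.**  Against the Mittag-Leffler closed form of linear decay
  (error < 5·10⁻⁴ at h = 5·10⁻⁴; empirical convergence order ≈ 2 at α = 1,
  ≥ 1.5 at α = 0.9, ≥ 1.2 at α = 0.5) and against a classical RK45 solve of
  the full model at α = 1 (max scaled discrepancy < 10⁻³ over [0, 50]).

The Mittag-Leffler evaluator uses the defining power series for z ≥ −2 and,
for more negative arguments where the series cancels catastrophically in
double precision, the complete-monotonicity spectral representation
E_α(−t^α) = ∫₀^∞ e^(−rt) K_α(r) dr integrated with adaptive quadrature;
the two branches agree to < 10⁻⁸ at the switch and the spectral branch
reproduces E_{1/2}(−x) = e^(x²)erfc(x) to machine precision.

## Equilibria

The tumor-free equilibrium is closed-form: P* = u₁/ϑ, G* = r₁/(β₃+d₂),
C* = (r₂ + g₄G*)/D_C with D_C = β₄ + d₃ − u₂ − δP*/(b+P*).  It exists
(as an admissible state) iff D_C > 0.  Two printed-source defects are
corrected and validated by residuals of the full fixed-point system:
the C* numerator reads g₄·r₁ (an undefined symbol r₄ appears in the printed
expression), and the printed coexistence reduction swaps the dendritic and
CD4 branches.  Both printed variants remain available
(`mode="paper_verbatim"`) for comparison; the residual of the full
right-hand side arbitrates objectively — only the corrected reduction
yields residuals < 10⁻⁹.

Coexistence equilibria are roots of the scalar condition
g₁(1 − T/s₁) − β₁M*(T)/(s₂+T) − ωC*(T)/(s₄+T) − u₃ = 0 obtained by
back-substitution.  The solver scans 10⁴ uniform points on (0, s₁] (roots
closer than 10⁻⁶·s₁ merged), polishes each bracket with Brent's method to
|f| < 10⁻¹², back-substitutes, and discards roots with negative or
non-finite components (recorded in the report notes rather than raised).

## Stability

The Jacobian default mode is the exact derivative: several printed entries
disagree with direct differentiation (g₂/s₂² where the derivative at T = 0
is g₂/s₂; spurious (1−T*) and (1−P*) factors; ωC*/s₄² versus ωC*/s₄), and a
central finite-difference oracle arbitrates (max entrywise scaled error
< 10⁻⁵ on random states).  The probiotic row decouples, contributing the
eigenvalue −ϑ; the remaining quartic λ⁴ − R₁λ³ + R₂λ² + R₃λ + R₄ over the
(T, M, G, C) block gives the Hurwitz determinants H₁ = −R₁,
H₂ = −R₁R₂ − R₃, H₃ = −R₁R₂R₃ − R₁²R₄ − R₃², H₄ = R₄H₃.

Positivity of H₁–H₄ is the α-independent sufficient condition (all real
parts negative); the primary classifier is Matignon's criterion
|arg λ| > απ/2, which reduces to Re λ < 0 at α = 1 and can only be *less*
restrictive for α < 1 — so Routh–Hurwitz stability at α = 1 implies
fractional stability for every α, which is how the two criteria are
reconciled.  Eigenvalues within 10⁻⁸ of the critical sector boundary (or a
zero eigenvalue) classify as *marginal*, never stable.

## Well-posedness

Lipschitz constants under sup-norm bounds ‖T‖<b₁, …, ‖P‖<b₅:
L₁ = g₁ + u₃ + 2b₁g₁/s₁ + β₁b₂/s₂ + ωb₄/s₄, L₂ = β₂+d₁, L₃ = β₃+d₂,
L₄ = β₄+d₃+δ+u₂, L₅ = ϑ.  Default bounds (s₁, 2, 2, 10, 2u₁/ϑ+1) are
generous envelopes of the observed scenario trajectories and can be replaced
by `bounds_from_trajectory`.  The comparison constant *a* of the Lipschitz
condition is free in the source analysis; the default a = 1 + max Lᵢ simply
dominates every constant.

The uniqueness condition is implemented literally as stated:
1 − σ^(1−α)Lᵢ/Γ(α) ≥ 0 per equation.  As printed it carries no horizon
factor (the usual contraction constant of the fractional Volterra operator
on [0, t] is σ^(1−α)t^αLᵢ/Γ(α+1)); rather than silently repairing the
condition, the literal form is primary, the horizon-bearing variant at t = 1
is reported alongside, and the Picard demonstrator is restricted to a unit
horizon where the literal condition is meaningful.  Picard iteration uses
the same product-rectangle quadrature as the predictor (exact for constant
kernels — verified against u₁t^α/Γ(α+1)); when all flags hold the
successive-difference sup-norms contract geometrically (ratio < 0.5 from the
third iterate in the demonstrated setting) onto the PECE solution.

## Scenario horizons and steps

The source figures state neither scheme, step nor horizon, so exact curve
replication is out of scope; horizons are package choices sized so every
component settles, from the slowest linearized rate and the α < 1 algebraic
memory tail (a mode with rate λ decays like t^(−α)/(λΓ(1−α)) rather than
exponentially):

| scenario | t_end | h | sized by |
|---|---|---|---|
| app1_i (clearance, α-set) | 200 | 0.05 | tumor rate ≈ 0.42 |
| app1_ii (coexistence, α-set) | 3000 | 0.2 | slowest block rate ≈ 0.089 at α ≥ 0.6 |
| app2_i (baseline robustness) | 6000 | 0.1 | CD4 rate D_C ≈ 0.057 at α = 0.96; h = 0.1 keeps the largest baseline's early transient stable |
| app2_ii (dose comparison) | 500 | 0.1 | lowest-dose tumor rate ≈ 0.01 |
| app3 sweeps | 200 | 0.05 (δ: 0.01) | transient CD4 expansion in the δ sweep stiffens the tumor equation (see below) |

A note on the δ sweep: at α = 0.9 and δ = 0.6 the probiotic's algebraic
tail keeps the CD4 net growth condition positive until t ≈ 136, so C
legitimately expands into the thousands before relaxing — a pure memory
effect absent at α = 1 (where C peaks near 152).  The induced tumor kill
rate ωC/s₄ then demands h = 0.01 for the explicit scheme.

## Synthetic draws

There is no empirical dataset to emulate: the property suites run on seeded
uniform draws anchored to the literature table (interval parameters from
their intervals, point parameters jittered ±20% keeping positivity, doses
from [0, 0.6] — the envelope of every published application dose).  The 200
default draws cover both stable and unstable tumor-free classes.  Passing
property tests therefore demonstrate internal mathematical consistency
(equilibria satisfy the fixed-point system, Hurwitz signs match spectra,
simulations converge where theory predicts), not agreement with biological
data.

## Known limitations

- Uniform grids and full memory only; no adaptive stepping, delay terms or
  non-power-law kernels.
- The explicit predictor–corrector has a bounded stability region; stiff
  transients (large C) require manually refined steps, flagged post hoc by
  the undershoot check rather than handled automatically.
- Attractor classification in scenario summaries compares terminal states
  against base-model equilibria; extended-model runs and runs that have not
  settled report "undetermined".
- The Matignon margin is computed from the numerically obtained spectrum;
  no interval arithmetic is attempted for near-marginal cases beyond the
  10⁻⁸ marginal band.
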