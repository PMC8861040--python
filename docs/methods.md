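# Methods

## The model family

`twodelay` implements the scalar two-delay differential equation

    dx/dt = a1 x(t-τ1) + a2 x(t-τ2) − x(t)² [b2 x(t-τ2) + b1 x(t-τ1)]

with rates a1, a2 (1/time), cubic coefficients b1, b2
(1/(amplitude²·time)), and delays τ1, τ2 ≥ 0 (time). Three regimes:

* **Linear** (b1 = b2 = 0): the two-delay analogue of the damped harmonic
  oscillator. In an RLC-circuit reading, the quarter-period phase lags of
  capacitor and inductor currents at drive frequency f appear as delays
  τ1 = 1/(4f) and τ2 = 3/(4f) (`rlc_delays`), so cos(2πft) satisfies
  dI/dt = −2πf·I(t−τ1) exactly — a useful closed-form solver check.
* **Van der Pol** (b1 = −1, b2 = 1): the cubic term becomes
  −x²[x(t−τ2) − x(t−τ1)], the delayed analogue of the classical
  self-sustained oscillator.
* **Generalized cubic feedback** (b1·b2 < 0, |b1| ≈ |b2|): used as a
  tremor-symptom model for Parkinson's disease, where a1, a2 encode
  negative/positive delayed feedback. Besides the origin it has fixed points
  x* = ±√((a1+a2)/(b1+b2)) whenever the ratio is positive. The constraint
  |b1| → |b2| has no sharp tolerance; the ratio |b1|/|b2| is reported
  (`cubic_imbalance`) but never enforced.

Both signs ±x* are returned even though only the positive root is usually
quoted: the dynamics are odd-symmetric, so both are genuine equilibria;
`FixedPoint.kind` tags keep reports unambiguous.

## Integrator

`integrate` is a fixed-step classical RK4 method-of-steps scheme. Each
stage's delayed state x(s−τ) is read from the history function when
s−τ ≤ 0 and otherwise from cubic Hermite dense output over completed steps
(stored values plus right-hand-side derivatives at every mesh point; exact
at mesh points, exact on cubic polynomials). Requiring
h ≤ min positive delay guarantees every lookup lands in known territory, so
the scheme stays fully explicit. Zero delays read the current stage state
directly. The initial point convention is x(0) := history(0); jump-start
discontinuities are not supported.

A fixed step was chosen over an adaptive embedded pair deliberately: every
registered case is smooth, small, and non-stiff, and a fixed mesh makes all
tests and CSV outputs bit-for-bit deterministic. Accuracy comparable to
adaptive DDE codes is reached by step refinement (the cosine closed form is
tracked to ~1e−10 at h = 0.01).

Solutions of DDEs with constant history lose one order of smoothness at
every breaking point t = k1·τ1 + k2·τ2. These are not mesh-aligned, so the
observed Richardson convergence order fluctuates between ~3 and ~5 around
RK4's nominal 4; `convergence_order` is asserted ≥ 3 for this reason, and
returns the flag `"exact"` when both errors sit at rounding level
(polynomial solutions). A blow-up guard aborts with the failure time once
|x| > 1e8 — unstable parameter sets genuinely diverge and an explicit error
beats a silent overflow.

## Taylor reductions

Expanding x(t−τ) = x − τx′ + (τ²/2)x″ + … and truncating at second order
turns the linear model into x″ + μx′ + βx = 0 with

    μ = −2(1 + a1τ1 + a2τ2)/(a1τ1² + a2τ2²),   β = 2(a1 + a2)/(a1τ1² + a2τ2²),

and, after collapsing x(t−τ2) − x(t−τ1) ≈ (τ2−τ1)x′ in the cubic term
(a mean-value step with no error bound asserted), the Van der Pol form into
x″ + μ(x² − α)x′ + βx = 0 with α = (1 + a1τ1 + a2τ2)/(τ2−τ1) and
μ = 2(τ2−τ1)/(a1τ1² + a2τ2²). The two reductions are mutually consistent
(μ_vdp·α = −μ_linear, equal β), which the suite checks on random parameter
sets. The truncation is the definition here; no third-order remainder is
estimated, and `reduce_vdp` deliberately refuses non-canonical cubics — the
general model has no reduced form in this framework.

The reduction is a *small-delay* approximation and can be qualitatively
wrong outside that regime: for the first registered case (delays 0.2/0.3)
it predicts negative damping while the DDE decays. The `reduce` CLI command
therefore prints the reduced-ODE condition set and the DDE's own
rightmost-root verdict side by side rather than hiding the disagreement.
A related caveat: the distance between the DDE's rightmost root and the
reduced quadratic's dominant root does go to zero as both delays are scaled
down, but not monotonically at every halving — the quadratic's discriminant
can change sign (spiral → node) at a different scale than the DDE's
dominant branch switches character, producing a transient bump in the gap.
The suite asserts the asymptotic agreement; a strictly monotone decrease
over a fixed scale ladder is not a property of the reduction.

## Linearization and stability

At the origin the linearization is (c0, c1, c2) = (0, a1, a2); at the
non-zero fixed point it is c0 = −2(a1+a2), c1 = δ, c2 = −δ with

    δ = (a1·b2 − a2·b1)/(b1 + b2).

The denominator is written in full generality; in the Van der Pol
convention b1 = −1 it equals b2 − 1, the form usually quoted. A central
finite-difference Jacobian (`numerical_jacobian`) serves as an independent
oracle at 1e−6 relative tolerance on seeded random models.

The characteristic equation λ = c0 + c1·e^(−λτ1) + c2·e^(−λτ2) is solved by
Newton iteration from a grid of seeds over a default box
(Re ∈ [−20, 5], Im ∈ [0, 50]); converged roots (residual ≤ 1e−9) are
deduplicated and the maximal-real-part one reported, with conjugates folded
to ω ≥ 0. Multi-seed Newton was preferred over an argument-principle
contour count as the primary method: it is simpler and every model of
interest has its dominant root well inside the box. With both delays zero
the equation is affine and solved exactly. Verdicts use a ±1e−6 marginal
band on Re λ so that exact Hopf configurations (the third registered case
has the root 10i exactly) classify as `marginal` rather than by rounding
luck. `hopf_scan` locates imaginary-axis roots by scanning |g(iω)| for
local minima and polishing with the same Newton step, accepting only roots
that converge onto the axis; an empty list is a valid result.

Small-delay conditions: the origin of the linear model is asymptotically
stable for τ1, τ2 ≪ 1 iff a1 + a2 < 0 (threshold verified by bisection to
1e−3 in the acceptance checks); the non-zero point of the cubic feedback
model has the approximate real root λ ≈ −2(a1+a2) for τ2 > τ1, hence is
stable when a1 + a2 > 0. `approx_root_parkinson` returns that approximation
*with* the residual of the full characteristic equation at it — it is a
diagnostic, never silently substituted for the true rightmost root. Note
the symbol clash in the underlying derivations: μ names both the reduced
ODE's damping coefficient and the real part of λ; the two are kept as
distinct fields here.

## Case registry and classifier

The ten registered cases are stored with their defining parameters verbatim
after one sign normalization: the model's cubic term is
−x²(b2 x(t−τ2) + b1 x(t−τ1)), so a case term written as
+x²[p·x(t−τb) + q·x(t−τa)] enters as b2 = −p, b1 = −q. Cases 9 and 10 use
a cubic delay of 5 that does not occur in their linear parts; the model
type carries optional separate cubic-term delays so these expressions are
stored literally (linearization is refused for them — its derivation
assumes shared delays; they are simulation fixtures).

Expected labels are attached only where the case's qualitative behavior is
well determined (damped decay: cases 1–2; neutral Hopf oscillation: case 3;
relaxation oscillation: case 8; decay to zero: case 9); cases 4–7 ship
`"unspecified"` and are exercised through invariants. Case 10 as written
has (a1+a2)/(b1+b2) = 0.3/(−0.1) = −3 < 0 — no real non-zero fixed point —
and its literal dynamics blow up in finite time, even though its regime
(net positive feedback) is the one expected to stabilize at a non-zero
amplitude; the registry keeps the literal expression and
the √2 endpoint is demonstrated instead with b2 = 1.15 (satisfying
b1·b2 < 0 and |b1| ≈ |b2|), which yields x* = √2 exactly and a stable
verdict under the a1 + a2 > 0 condition. The related caption-level
contradiction (a stability condition quoted as a1 + a2 < 0 for the
non-zero point) is resolved in favor of the derived a1 + a2 > 0.

`classify_trajectory` works on the tail (default: last half) of a
trajectory: tail mean, half peak-to-peak amplitude, period from upward
mean-crossings, and a two-half-window amplitude ratio. Flat tails (below
tol = 0.02 × initial amplitude) are `decays_to_zero` or
`converges_to_constant` by the mean; oscillating tails are
`sustained_oscillation` when the window ratio is within [0.9, 1.1],
`growing` above it, and still-decaying below it. The relaxation flag marks
fast–slow waveforms via the derivative crest factor
max|x′| / (2π·amplitude/period) > 2, which is 1 for a sinusoid. Default
horizons are 40 time units for sub-unit delays and 30× the largest delay
otherwise — long enough to cover every registered case's transient.

## Problem sizes and determinism

Everything in the suite and the acceptance script is deterministic: fixed
steps, fixed seeds for random parameter draws (numpy `default_rng`),
derandomized hypothesis profiles. Default mesh sizes are 2 000–20 000
points per trajectory (h = 0.01 over horizons of 20–200 time units), which
keeps every check at the seconds scale while leaving closed-form errors
4–6 orders of magnitude below their asserted tolerances.

## Known limitations

* One scalar equation; no systems, no more than the two (plus the literal
  cubic) delays, no state-dependent or distributed delays, no neutral terms.
* No adaptive error control or stiff solver; step choice is the user's.
* The bilinear product term a3·x(t−τ1)·x(t−τ2) that appears in related
  tremor models is out of scope; only its associated linear model is used.
* Hopf detection reports imaginary-axis crossings of the linearization; no
  normal-form coefficients, branch continuation, or chaos diagnostics.
* The trajectory classifier assumes the transient has passed within the
  simulated horizon; a too-short run can misread a slow transient as
  sustained.
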