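# Methods

This note records the models implemented in `bmem`, the numerical choices
behind them, and the limits of what the package's tests demonstrate.

## Continuous model

The state x = (μ, b, η) follows the linear stochastic differential equation
dx = f(x) dt + dW with f(x) = −(Γ − Q) Π (x − ϑ) and noise covariance 2Γ dt.
This drift is the stationary decomposition of a Fokker–Planck flow with
quadratic potential ℑ(x) = ½ (x−ϑ)·Π(x−ϑ): a dissipative part −ΓΠ(x−ϑ)
descending the potential against diffusion, and a solenoidal part QΠ(x−ϑ)
circulating along its contours. Because Γ and Q are constant, the Itô /
Stratonovich / anti-Itô readings coincide and no convention switch is
offered. The steady state is N(ϑ, Π⁻¹); Π_{μη} = 0 makes μ ⊥ η | b there.

### Canonical parameterization

State order is fixed as (μ, b, η); the blanket is index 1.

| quantity | value | role |
|---|---|---|
| ϑ | (0, 0, 0) | steady-state mode |
| Γ | ¼ diag(γ, 1, γ) | dissipation; γ scales internal and external channels together (symmetric manipulation) |
| Q | θ · [[0,−1,0],[1,0,−1],[0,1,0]] | solenoidal coupling through the blanket |
| Π | [[2/κ, κ^{−1/2}, 0], [κ^{−1/2}, 2, κ^{−1/2}], [0, κ^{−1/2}, 2/κ]] | steady-state precision |

All three scalars are dimensionally rates (γ, θ) or a variance scale (κ),
in the arbitrary time/state units of the model; all default to 1.

The Π parameterization is chosen so that two kinds of variance separate
cleanly (verified symbolically with sympy and enforced to 1e-12 in tests):
the internal/external marginal variances Σ_μ = Σ_η = ¾κ scale with κ, while
the blanket conditionals Σ_{b|μ} = Σ_{b|η} = ⅔ and the blanket marginal
Σ_b = 1 do not. κ therefore acts like the variance of a "prior": larger κ
flattens the log-density, gradients are shallower, and every flow slows
down — the slowest covariance time constant grows from 0.52 at κ = ¼ to
4.02 at κ = 2. An equally plausible-looking parameterization with Π ∝ κ
inverts this relationship; it is rejected because it contradicts the scalar
expansion of the precision flow (whose solenoidal coefficients are 2/κ and
κ^{−1/2}, see below) and the κ-sweep phenomenology the package is built to
exhibit.

### Density propagation

Under the Laplace (Gaussian) closure the Fokker–Planck equation reduces to

    ξ̇ = −A(ξ − ϑ),   Σ̇ = 2Γ − AΣ − ΣAᵀ,   A = (Γ − Q)Π,

an affine Lyapunov/Sylvester flow with fixed point (ϑ, Π⁻¹). Production
integration is fixed-step classical RK4 at dt = 1/64, with Σ re-symmetrized
((Σ+Σᵀ)/2) every step and a Cholesky check that raises if positive-
definiteness is lost. The affine structure gives a closed form via matrix
exponentials (`closed_form_density`, column-stacking vectorization, under
which vec(AΣ + ΣAᵀ) = (I⊗A + A⊗I) vec Σ); it is kept as an independent test
oracle rather than the production path so the API stays uniform with the
categorical module. RK4 at dt = 1/64 agrees with the closed form to better
than 1e-6 and holds the fixed point to 1e-8 over τ = 16.

The precision Φ = Σ⁻¹ obeys Φ̇ = Π(Γ−Q)ᵀΦ + Φ(Γ−Q)Π − 2ΦΓΦ (the pushforward
−ΦΣ̇Φ). For the canonical model the (μ,η) entry splits into three labelled
channels — internal/external dissipation γ(1/κ − ½Φ_μμ − ½Φ_ηη)Φ_μη,
blanket dissipation ¼(κ^{−1/2}Φ_bη + κ^{−1/2}Φ_μb − 2Φ_μb Φ_bη), and
solenoidal coupling θ(2(Φ_μb − Φ_bη)/κ + κ^{−1/2}(Φ_μμ − Φ_ηη)) — whose sum
equals the matrix form exactly (symbolically verified; tested to 1e-10 on
random SPD precisions). At Φ = Π every channel vanishes. Direct RK4
integration of the precision flow is stiff while the pinned blanket
precision (e⁴) collapses; the consistency test against the covariance route
therefore runs at dt = 1/512, where the two agree entrywise to 1e-5.

### Perturbation protocol

The memory experiments start from the steady-state density with the blanket
*observed*: Φ₀ equals Π except that its (b,b) entry is **set to**
exp(log_precision), default log-precision 4 (e⁴ ≈ 54.6), and ξ₀ = ϑ. Setting
rather than adding is the default because at e⁴ the two differ negligibly
(2 vs 54.6 background); the additive variant is exposed as an option. The
(μ,η)-block of Φ₀ equals Π's, so the initial density still factorizes given
b and the conditional mutual information starts at exactly 0.

### Ensemble simulation

`simulate_ensemble` uses Euler–Maruyama — adequate for linear drift and
additive noise — at default dt = 0.01, with a spectral-radius check of the
update map I − dt·A. Noise streams are Philox generators spawned per path
from one root `SeedSequence`, so path i is bit-reproducible and independent
of the total path count. The scheme's weak bias in the mean is the explicit
Euler recursion (I − dt·A)^k x₀; tests separate this O(dt) bias (≈ 0.05 at
dt = 0.01 over the transient) from Monte-Carlo error when comparing against
the density-dynamics mode.

## Measures

All divergences are in nats. The Gaussian KL uses the standard closed form;
it is checked against 1-D and 2-D numerical quadrature to 1e-4. The
blanket-conditioned mutual information is computed from the Schur complement
Υ of the blanket block of Σ, clipped at 0 against round-off, and checked
against a 10⁶-sample Monte-Carlo plug-in estimate within 3 standard errors.

Information length accumulates dl = √(2 KL(p_{τ+dτ} ‖ p_τ)) on the
integration grid (step equals the density-integration step; refining dt
changes the total by < 1% in the closed-form translation benchmark, which
converges to the exact Fisher length d/σ). It is computed for the joint
density and for the blanket marginal; their difference ("excess") is the
distance travelled that is not attributable to the blanket marginal's own
motion, reported as joint − blanket.

Time constants are 1/|Re λ| over the eigenvalues of the relevant Jacobian —
the 9×9 Kronecker sum −(I⊗A + A⊗I) for the covariance flow, the 27×27
generator for the categorical system — sorted slowest-first, with
eigenvalues within 1e-10 of the imaginary axis excluded as zero modes (the
categorical generator has exactly one, from probability conservation). For
the generator a second reading, mean holding times −1/L_ii, is exposed as
`diagonal_time_constants`; the spectral version is what the analyses use.

## Categorical model

The joint distribution over three ternary variables (axis order (μ, b, η),
C-order vectorization, η fastest) evolves under vec(ṡ) = L vec(s) with
L = ΩΛ, Λ = diag(vec s(∞))⁻¹ and Ω = Γ + Q:

* s_b(∞) = softmax(κ ln(1,3,1)); s_{μ|b}(∞) = s_{η|b}(∞) = column-wise
  softmax of κ ln [[1,3,1],[3,1,1],[1,1,3]] (columns indexed by b, a
  convention choice; the construction's symmetry makes the measured
  quantities insensitive to it);
* joint steady state s(μ,η,b) = s(μ|b) s(η|b) s(b) — a Markov blanket by
  construction;
* Γ = (γ/128)(𝟙 − 27·I): symmetric, generator-shaped (negative diagonal),
  zero row/column sums; alone it satisfies detailed balance w.r.t. s(∞);
* Q = (θ/512) A⊗A⊗A with the 3-cycle A = [[0,−1,1],[1,0,−1],[−1,1,0]]:
  antisymmetric, zero column sums; it breaks detailed balance.

Here κ acts as an inverse temperature applied to both the blanket marginal
and the conditionals. The symmetric component is stored with its generator
sign so that L = (Γ + Q)Λ has nonnegative off-diagonal rates; this requires
θ ≤ 4γ (smallest off-diagonal of Γ + Q is γ/128 − θ/512), and the builder
rejects parameterizations beyond the bound — scaling the detailed-balance-
breaking part too far relative to the dissipative part has no valid
rate-matrix reading.

Integration applies the one-step matrix exponential expm(L·dt) repeatedly
(27×27 is cheap), conserving probability to round-off. The perturbation
protocol collapses the blanket marginal onto its most likely steady-state
level (one-hot, ties to the lowest index) while keeping the steady-state
conditionals, so the initial conditional mutual information is again 0.

Two boundary details. First, the one-hot start has zero-probability states,
so the first forward-KL increment of the information length is infinite even
though the continuum Fisher length from a simplex boundary is finite;
accumulation therefore starts at τ = dt (full support, by irreducibility),
discarding an O(√dt) boundary contribution. Second, the default measure
horizon is T = 8, by which the conditional mutual information is < 1e-9;
total-variation convergence to the steady state reaches 1e-6 only around
τ ≈ 11 (slowest time constant 0.857), so the convergence test integrates to
T = 12.

## Sweeps

Sweeps cover γ, θ, κ ∈ {¼, ½, …, 2} (8 uniform values; endpoints are what
the assertable orderings use), holding the other two scalars at 1, with the
e⁴ blanket pinch (continuous) or one-hot blanket (categorical) protocol.
Reproduced orderings, asserted at the endpoints: larger γ gives a smaller
conditional-MI peak, a shorter information length, and earlier MI
extinction (both systems); larger θ lengthens the continuous path while
moving the slowest time constant by < 20%; larger κ slows the slowest mode.
Categorical grid points violating θ ≤ 4γ are skipped with a logged error.

## What the tests do and do not show

Everything here is synthetic and self-generated: the package's claims are
about this three-state Ornstein–Uhlenbeck family and this 3×3×3 master
equation, in arbitrary units. Passing tests demonstrate internal
consistency (integrators vs closed forms, matrix vs scalar identities,
sampling vs density dynamics) and the qualitative phenomenology of
transient blanket violation. They do not show that real neural or
biological systems have these dynamics, nor how the measures behave for
multidimensional partition cells, state-dependent Γ(x), Q(x), non-quadratic
potentials, or state spaces other than 3×3×3 — all out of scope. The
reported ensemble correlations are stochastic quantities with a sampling
standard error of ≈ 0.04 at 512 paths; only agreement at that resolution is
claimed.
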