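# bmem — transient memory in Markov-blanketed stochastic systems

A Markov blanket *b* renders an internal state μ and an external state η
conditionally independent: p(μ, η | b) = p(μ | b) p(η | b). For a random
dynamical system this independence is a property of the **steady-state
density** — not of every density the system passes through. As soon as an
observation imposes an initial condition (say, the blanket is pinned to a
value), the relaxing density transiently violates the blanket condition:
internal and external states become conditionally dependent through their
*shared past*, and only forget it on the way back to steady state. That
transient dependence is a minimal formal model of memory, and this package
exists to construct it, propagate it, and measure how long it lasts.

`bmem` is aimed at researchers in theoretical neurobiology / stochastic
thermodynamics who want a small, fully seeded toolkit for these
density-dynamics experiments, in two flavours:

**Continuous.** A three-state Ornstein–Uhlenbeck process x = (μ, b, η),

    dx = −(Γ − Q) Π (x − ϑ) dt + dW,     cov(dW) = 2Γ dt,

whose steady state N(ϑ, Π⁻¹) has a blanket because Π_{μη} = 0. Γ (symmetric)
is the dissipative gradient flow, Q (antisymmetric) the solenoidal flow
circulating along the contours of the potential ℑ(x) = ½(x−ϑ)·Π(x−ϑ). Three
scalars parameterize the family: γ scales the internal/external dissipation
(Γ = ¼ diag(γ, 1, γ)), θ the solenoidal coupling, and κ the steady-state
variance scale (Π = [[2/κ, κ^{-1/2}, 0], [κ^{-1/2}, 2, κ^{-1/2}],
[0, κ^{-1/2}, 2/κ]], so Σ_μ = Σ_η = ¾κ while Σ_{b|μ} = Σ_{b|η} = ⅔ for every
κ). Because the potential is quadratic and Γ, Q constant, the Fokker–Planck
equation closes on a Gaussian: the mode and covariance obey

    ξ̇ = −(Γ − Q) Π (ξ − ϑ),
    Σ̇ = 2Γ − (Γ−Q)Π Σ − Σ Π(Γ−Q)ᵀ,

which `bmem` integrates exactly enough to compare against the
matrix-exponential closed form.

**Categorical.** A 3×3×3 master equation vec(ṡ) = L vec(s) with
L = (Γ + Q)Λ, Λ = diag(vec s(∞))⁻¹, whose factorized steady state
s(μ,η,b) = s(μ|b) s(η|b) s(b) again carries a blanket; the symmetric part Γ
preserves detailed balance, the antisymmetric Q breaks it.

**Measures of memory.** Along a relaxation the package records

* the blanket-conditioned mutual information
  I(μ; η | b) = ½ ln det(Υ_ηη) / det(Υ_ηη − Υ_ημ Υ_μμ⁻¹ Υ_ημᵀ), with Υ the
  Schur complement of the blanket block of Σ (zero iff the blanket condition
  holds);
* the internal–external precision entry Φ_μη (continuous case);
* the information length l(τ) = Σ √(2 KL(p_{k+1} ‖ p_k)), the distance the
  density travels on the statistical manifold, for the joint and for the
  blanket marginal;
* spectral time constants 1/|Re λ| of the relevant Jacobian (the covariance
  flow's Kronecker sum, or the master-equation generator).

## Worked example

```python
import numpy as np
import bmem

m = bmem.build_gaussian_model(gamma=1.0, theta_s=1.0, kappa=1.0)
print(bmem.stationary_covariance(m))

series = bmem.continuous_protocol(gamma=1.0, theta_s=1.0, kappa=1.0)
k = int(np.argmax(series.cmi))
print(f"peak CMI {series.cmi[k]:.4f} nats at tau = {series.times[k]:.3f}")
print(f"CMI at tau=16: {series.cmi[-1]:.2e}")
print(f"information length: joint {series.il_joint[-1]:.3f}, "
      f"blanket {series.il_blanket[-1]:.3f}, excess {series.il_excess[-1]:.3f}")
print("slowest time constants:", np.round(series.time_constants_[:3], 3))
```

prints

```
[[ 0.75 -0.5   0.25]
 [-0.5   1.   -0.5 ]
 [ 0.25 -0.5   0.75]]
peak CMI 0.0558 nats at tau = 0.266
CMI at tau=16: 9.52e-10
information length: joint 5.329, blanket 3.159, excess 2.169
slowest time constants: [2.016 1.144 1.144]
```

Reading: at steady state μ and η covary (Σ_μη = ¼) yet are conditionally
independent given b (the CMI of the stationary covariance is exactly 0).
`continuous_protocol` then pins the blanket — it resets the blanket entry of
the initial precision to e⁴ ≈ 54.6, as if b had just been observed at its
expected value — and relaxes the density for τ = 16. The conditional mutual
information rises from 0 to a peak of ≈ 0.056 nats within the first time
unit (memory across the blanket), then decays back below 10⁻⁹: the initial
condition is forgotten. The joint density travels an information length of
≈ 5.3, of which ≈ 2.2 is *not* attributable to the blanket marginal's own
motion. The slowest covariance mode decays with time constant ≈ 2.0, setting
the memory span. The categorical analogue runs as
`bmem.categorical_protocol()` and shows the same rise-and-decay (peak
≈ 0.0016 nats at τ ≈ 0.19).

A command-line interface mirrors the library:

```sh
bmem simulate --n-paths 512 -T 16 --seed 1 --out traj.csv
bmem density --kappa 2 --out density.csv
bmem sweep --system continuous --parameter gamma --out sweep.csv
bmem figure fig1 --seed 1 --outdir out/
```

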