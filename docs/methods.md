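# Methods note

## Model

A population of `N` individuals holds one of two behaviors: the **active**
behavior A with per-capita environmental impact `l_A`, or the **baseline**
behavior B with impact `l_B > l_A`. The state is `(x, e)` with
`x ∈ [0, 1]` the frequency of A and `e ∈ [l_A, l_B]` the perceived
environmental state.

### Microscopic rates

Two mechanisms drive individual switching.

*Social encounters.* Pairs meet at rate `κ`. In an encounter, the
attractiveness of each behavior is an affine function of its frequency:

```
λ_A(x) = γ_A + δ_A x          λ_B(x) = γ_B + δ_B (1 − x)
```

with payoffs `γ_A, γ_B ≥ 0` and conformity pressures `δ_A, δ_B ≥ 0`. A
B-individual meeting an A-individual adopts A at rate proportional to
`λ_A`, and conversely, giving the per-capita channel rates
`κ x(1−x) λ_A(x)` (B→A) and `κ x(1−x) λ_B(x)` (A→B).

*Individual assessment.* Each individual reassesses its behavior against
the perceived environment at rates

```
τ_A(e) = τ (e − l_A)          (B→A: degraded environment favors A)
τ_B(e) = τ (l_B − e)          (A→B)
```

Note `τ_A + τ_B = τ (l_B − l_A)` identically. The **total switching
rate**

```
Ω(x, e) = κ x(1−x)[λ_A(x) + λ_B(x)] + τ_A(e)(1−x) + τ_B(e) x
```

aggregates all four channels; it measures behavioral (in)consistency and is
the diffusion strength of the fluctuation process. At full adoption,
`Ω(1, l_A) = τ (l_B − l_A)` exactly.

*Environment.* The perceived state relaxes logistically toward the
population's mean impact `c(x) = l_A x + l_B (1 − x)`:
`de/dt = h(x, e) = ℓ e (c(x) − e)`. The box
`[0, 1] × [l_A, l_B]` is forward-invariant.

### Deterministic limit

As `N → ∞` the frequency obeys

```
dx/dt = p(x, e) = κ x(1−x)[β + δ_A x − δ_B(1−x)] + τ[e − l_A(1−x) − l_B x]
```

with payoff differential `β = γ_A − γ_B`. Two derived coordinates organize
the phase diagrams: `β` and the **social norm threshold**
`ν = δ_B/(δ_A + δ_B)`. With no environmental coupling (`τ = 0`) the
boundaries `x = 0, 1` are absorbing and the interior equilibrium is
`x* = (δ_B − β)/(δ_A + δ_B) = ν (1 − β/δ_B)`; the system is bistable
exactly when it lies in `(0, 1)`.

### Parameters

| symbol | meaning | unit | default |
| --- | --- | --- | --- |
| `κ` | encounter rate | 1/time | 1 |
| `γ_A`, `γ_B` | payoffs | — | `γ_B = 1`, `γ_A` explicit |
| `δ_A`, `δ_B` | conformity pressures | — | `δ_B = 0.5`, `δ_A` explicit |
| `τ` | environmental sensitivity | 1/time | explicit (presets 0.1, 1, 10) |
| `ℓ` | environmental reactivity | 1/time | explicit (presets 0.1, 0.25) |
| `l_A`, `l_B` | per-capita impacts | — | `l_B = 1`, `l_A` explicit |

`τ`, `ℓ`, `γ_A`, `δ_A` and `l_A` have no scientifically neutral default and
must be supplied; error messages name the preset values used throughout the
regime maps. `params_from_differentials(β, ν, ...)` converts the derived
coordinates back to structural rates with the anchors above
(`δ_A = δ_B (1 − ν)/ν`).

## Equilibria, stability, regimes

On the nullcline `h = 0` the environment is the impact mixture
`e = c(x)`, so equilibria are roots in `[0, 1]` of the **reduced cubic**

```
p(x, c(x)) = κ x(1−x)(β − δ_B + (δ_A + δ_B) x) + τ (l_B − l_A)(1 − 2x)
```

Roots come from the companion-matrix eigenvalues (`numpy.roots`) with
degenerate leading coefficients trimmed, followed by a few Newton steps so
every reported equilibrium has vector-field residual below `1e−9`. Roots
closer than `1e−8` are merged (saddle-node tangencies). Stability uses the
exact Jacobian

```
∂p/∂x = κ[(1−2x)(β−δ_B+(δ_A+δ_B)x) + (δ_A+δ_B) x(1−x)] − τ(l_B−l_A)
∂p/∂e = τ
∂h/∂x = ℓ e (l_A − l_B)
∂h/∂e = ℓ (c(x) − 2e)
```

with eigenvalue real parts compared against `±1e−9`; marginal points are
resolved by perturbed follow-up integration. Regimes: **bistable** (≥ 2
stable points), **monostable** (1), or **limit cycle** — when the unique
equilibrium is unstable, the compact invariant box and the
Poincaré–Bendixson theorem guarantee an attracting periodic orbit, which is
measured from a post-transient trajectory by locating oscillation peaks
with parabolic sub-sample refinement and requiring the last six
inter-peak intervals and peak heights to agree within 1%; otherwise the
measurement is reported as inconclusive rather than guessed.

**Consistent adoption** is a thresholded property of a stable equilibrium:
`x* ≥ x_min` (default 0.9) and `Ω(x*, e*) ≤ ω_max` (default 0.05). The
defaults are strict: at full adoption with strong conformism the exact Ω
contains a social-encounter contribution of order `τ(l_B − l_A)` on top of
the assessment term, so scenario analyses that intend "few residual
switches relative to the impact differential" should pass an explicit
`ω_max` (the scenario examples use 0.15).

## Exact stochastic simulation

The finite-`N` process is a PDMP: the count `k = N x` jumps by ±1 while
`e` follows `de/dt = ℓ e (c(x) − e)` between jumps. Jumps are drawn by
**thinning/uniformization**: candidate times form a Poisson stream at the
dominating rate

```
ξ_N = N [κ (γ_A + γ_B + max(δ_A, δ_B)) + τ (l_B − l_A)] (1 + 1e−12)
```

which bounds `N·Ω` everywhere (λ_A + λ_B is affine in `x`, the assessment
sum is constant). At each candidate, one of the four channels fires with
probability `rate/ξ_N`; otherwise the candidate is a phantom event. The
environment flow between candidates uses the closed-form logistic solution
`e(t+Δ) = c e / (e + (c − e) exp(−ℓ c Δ))` by default; a capped explicit
Euler update is available for fidelity checks. The scheme is exact in
distribution, and the simulator's frozen-environment mode reduces to a
birth–death chain whose detailed-balance stationary law is used as a
correctness oracle (long-run occupancy matches within 0.05 total
variation).

Two backends share the algorithm: a numba-compiled kernel recording the
state on a regular grid (large-`N` ensembles), and a pure-Python loop
recording the full event log (capped at 10⁷ events, after which only the
grid path is kept). Runs are bit-reproducible from `(params, config,
seed)` on a given backend; ensembles use consecutive seeds reduced modulo
`2³¹ − 1`.

## Linear-noise (OU) analysis

√N-scaled deviations `(η_A, η_E)` around a stable equilibrium follow a
linear diffusion with drift equal to the Jacobian at `(x*, e*)` and
diffusion matrix `D = diag(Ω(x*, e*), 0)` — noise enters only through
behavior switching; the environment fluctuates via its coupling to `η_A`.
The stationary covariance solves the Lyapunov equation
`AΣ + ΣAᵀ + D = 0` (`scipy.linalg.solve_continuous_lyapunov`). Note that
`Σ₁₁` equals the raw switching rate Ω only up to the relaxation induced by
the drift; the package reports both, clearly labeled. An Euler–Maruyama
integrator of the OU process and an ensemble estimator of `N·Var(X^N)`
(pooled over a stationary window, batch-means standard errors, drift
diagnostic) provide the empirical counterparts.

## Numerical choices

- **ODE integration**: adaptive RK45 (`scipy.integrate.solve_ivp`),
  `rtol = 1e−8`, `atol = 1e−10`, dense sampling every 0.1 time units.
  Trial stages may overshoot the invariant box by round-off; excursions up
  to `1e−5` are projected back, larger ones raise an error rather than
  being silently truncated.
- **Convergence flag**: a terminal state is "at equilibrium" when
  `‖(p, h)‖∞ < 1e−6`. At the tolerances above, the integrator's
  accumulated drift over horizons of 10³ time units is itself of order
  `1e−6`, so a tighter test would reject genuinely converged runs; `1e−6`
  still separates converged from transient states by orders of magnitude.
  (Root-finding residuals for reported equilibria remain at `1e−9`.)
- **Ensemble-vs-ODE convergence check**: the ensemble mean is compared to
  the ODE at 11 evenly spaced checkpoints on the horizon, each within 3
  Monte-Carlo standard errors. A pointwise test over all ~500 grid samples
  would fail for a correct implementation with high probability (maximum
  of hundreds of correlated standardized deviations exceeds 3), so the
  checkpoint design is part of the package's validation methodology. Even
  at 11 checkpoints the maximum standardized deviation has a few-percent
  chance of exceeding 3 at any given seed; the acceptance test therefore
  pins its seed, and the standalone report script labels the quantity as a
  maximum of 11 standardized deviations rather than a hard bound.
- **Scaled-variance N-independence**: `N·Var(X^N)` at `N = 10³` vs `10⁴`
  is required to agree within a ratio band `[0.8, 1.25]`, sized from the
  Monte-Carlo spread of the estimator plus the genuine `O(1/N)` correction
  at the smaller population.
- **Basin-switching horizon**: at `N = 100` in the bistable showcase, mean
  dwell times near the low-adoption equilibrium are of order 10³–10⁴ time
  units; the switching experiment runs for 10⁵ units so that an escape is
  near-certain for any seed.

## Typical problem sizes

A 101×101 regime map classifies in a few seconds; a 50-run ensemble at
`N = 10⁴` over 50 time units takes a few seconds with the compiled kernel
(first call adds ~2 s of JIT compilation); the full test suite runs in
under a minute on one CPU, and `scripts/acceptance.py` in about half a
minute.

## Limitations

- The environment is a single perceived scalar relaxing to the mean
  impact; no spatial structure, heterogeneity, or memory.
- The OU analysis is local: it is meaningless at unstable points (the
  Lyapunov solve returns no covariance) and degrades near bifurcations and
  at small `N`, where the `O(1/N)` mean bias is visible.
- Limit-cycle measurement is simulation-based; periods are certified only
  when peak sequences stabilize, and cells that fail this check in sweeps
  are flagged inconclusive rather than classified.
- The thinning kernel's efficiency drops when `Ω ≪ ξ_N/N` (phantom-heavy
  regimes, e.g. near absorbed states at small `τ`).
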