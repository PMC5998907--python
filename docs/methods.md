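# Methods

## Lineage model

A mutant lineage is a discrete-time Galton–Watson branching process embedded
in a large wild-type population under serial passage. One *cycle* spans τ
wild-type generations of growth followed by one dilution bottleneck:

* **growth stage** — every individual independently draws a
  Poisson-distributed brood; the wild type has mean r (default 2), so its
  probability generating function (pgf) is y(x) = exp(r(x−1));
* **sampling stage** — each individual survives the bottleneck independently
  with probability c, pgf z(x) = 1 − c + c·x.

The pgf of a full cycle is the composition with the last biological stage
innermost, ϕ = y∘…∘y∘z. The extinction probability q of a lineage founded by
a single mutant is the smallest fixed point of ϕ on [0,1] in a constant
environment, and the nested backward limit q = lim ϕ_0(ϕ_1(⋯ϕ_n(0))) when
the per-cycle pgfs vary; the fixation probability is p = 1 − q. Branching
independence is accurate while the lineage is a negligible fraction of the
population, i.e. for the establishment phase that determines p.

**Bottleneck survival.** With τ growth generations per cycle at wild-type
mean r, the single sampling stage uses survival c = r^(−τ), so the wild-type
composite mean is exactly 1 per cycle (population-size conservation). For
τ = 1 this is the familiar c = 1/r of a constant-size population; the
generalisation to τ > 1 is forced by conservation, since a per-cycle
survival of 1/r would shrink the population r^(τ−1)-fold per cycle.

## Generation-time mutants

A generation-time mutant draws the *same* Poisson(r) brood as the wild type
but completes a generation in t_g = 1/(1+s̃) wild-type units, where
s̃ = log_r(1+s) puts the conventional advantage s on the generation-time
axis (equating total growth (r(1+s))^t = r^(t/t_g)). Its advantage is
realised exclusively through *extra growth stages*: after n bottlenecks the
lineage has completed n·τ + ⌊n·τ·s̃⌋ generations, and the i-th extra
generation first fits at bottleneck n_i = ⌈i/(s̃τ)⌉ (the fitting condition
(n_iτ+i)·t_g ≤ n_iτ is non-strict, so exact ties count). A cycle containing
an extra generation has pgf ϕ⁺ = y_{τ+1}∘z; all others ϕ = y_τ∘z. For τ = 5,
s̃ = 1/20 the first eight cycles read ϕ,ϕ,ϕ,ϕ⁺,ϕ,ϕ,ϕ,ϕ⁺.

**Changing environments.** With a per-generation advantage s_k the package
accumulates D_g = Σ_{j<g} s̃_j (s̃_j = log_r(1+s_j)) over wild-type
generations — the mutant completes 1 + s̃_j generations per wild-type
generation j — and inserts one extra growth stage in a cycle whenever ⌊D⌋
increments across it. This is the unique accounting that preserves the
total-growth calibration defining s̃, and it reduces *exactly* to
n_i = ⌈i/(s̃τ)⌉ when s_k is constant (verified bit-for-bit in the tests).
Extra stages are appended at the end of the growth block; their position
within the block does not change the composite pgf. The per-cycle schedule
is quasi-periodic (spacings alternate between ⌊1/(s̃τ)⌋ and ⌈1/(s̃τ)⌉), so
the numeric route never assumes periodicity.

## Effective selective advantage

Around a constant reference environment with advantage s̄ — the Cesàro mean
of the s_k — the nested recursion linearises: writing the per-generation pgf
as ϕ_k = ϕ̄ + ε_k with ε_k(1) = 0, a first-order expansion gives

    p ≈ p̄ + p̄ Σ_k (s_k − s̄) σ^k,   σ = ϕ̄′(1 − p̄) ≈ 1 − s̄,

using p̄ = s̄/ln 2 and ε_k′(1) ≈ s_k − s̄. Rearranged, p ≈ s_e/ln 2 with
s_e = Σ_k ω_k s_k and geometric weights ω_k = s̄(1−s̄)^k, which sum to one
and decay with k: the effective advantage is a probability-weighted average
of the environments a rare lineage experiences, earliest first. For
fecundity mutants the same construction gives p ≈ 2 s_e.

The truncation horizon is K = ⌈ln tol / ln(1−s̄)⌉ (default tol 1e−10);
beyond the stored trajectory, s_k is taken at s̄, so the truncation error is
bounded by (1−s̄)^K·max_k|s_k − s̄|. The reference p̄ defaults to the
small-s closed form s̄/ln 2; `perturbation_series` accepts a numeric p̄ for
sensitivity checks, and `fecundity_perturbation_exact` keeps *all* reference
ingredients exact (fixed point, decay factor, disturbance values), which is
the form whose residual is purely second order in the fluctuation amplitude
(the fully simplified closed forms add O(s̄·amplitude) terms from σ ≈ 1−s̄
and the linearised disturbance — this is why the quadratic-shrinkage check
uses the exact-ingredient variant).

**Reference advantage.** The Cesàro mean estimator doubles its horizon until
the successive relative change falls below a stopping tolerance (default
1e−6; the running mean converges only as O(1/n) for oscillating
trajectories, so a much tighter stopping rule would be impractical and still
not bound the true error). All scenario constructors carry their analytic
limits, which is what the closed forms use.

## Scenarios

* **Monotone**: s_k = s_0 e^(−k/2) + s_∞(1 − e^(−k/2)); s̄ = s_∞; the
  geometric sum gives s_e = s_∞[1 + (s_0−s_∞)/(1 − e^(−1/2)(1−s_∞))]. The
  decay rate 1/2 per generation is part of the model definition. With
  s_0 = 0 the k = 0 entry is clamped to 1e−6 so the all-positive contract of
  trajectories holds.
* **Cyclic**: s_k = s_mean + Δs·cos(kρ + θ), Δs < s_mean; s̄ = s_mean; the
  damped-cosine geometric sum gives
  s_e = s_mean[1 + Δs((1−s_mean)cos(ρ−θ) − cos θ)/(2(1−s_mean)cos ρ −
  (1−s_mean)² − 1)]. ρ and θ are radians; k is 0-based, so the k = 0 term is
  s_mean + Δs·cos θ.
* **Demography**: constant mutant advantage s in a census following
  Beverton–Holt dynamics N_n = C·N_0/(N_0 + (C−N_0)e^(−gn)). The mutant's
  net mean offspring in generation n is M_n = (N_{n+1}/N_n)(1+s), mapped to
  the trajectory s_n = M_n − 1 with reference s̄ = s (the carrying-capacity
  regime, N_{n+1}/N_n → 1). The exact route keeps the growth mean at r and
  sets the per-generation sampling survival to N_{n+1}/(r·N_n), so the
  wild-type net mean is exactly the census ratio. Generations with s_n ≤ 0
  (a shrinking census overwhelming s) are rejected as outside the
  beneficial-mutant approximation.
* **AR(1)**: s_k = (1−λ)s_mean + λs_{k−1} + ξ_k with Gaussian innovations
  (mean 0, s.d. σ_ξ — the innovation s.d. is distinct from the geometric
  decay factor above). Conditional on s_0, E[s_k|s_0] = (1−λ^k)s_mean +
  λ^k s_0 and the expected fixation probability is
  E[p|s_0] = (s_mean/ln 2)[1 + (s_0−s_mean)/(1 − λ(1−s_mean))]. Draws that
  would leave the beneficial regime are clamped to 1e−6; clamp events are
  counted in the trajectory metadata and warned about. The innovation
  distribution is configurable in principle; Gaussian is the default.

Default scenario parameters throughout the comparisons are the study's
standard sets: s̄ ~ 0.01, monotone s_0 ∈ {0, 0.001}, cyclic Δs = s_mean/2
with θ = π, demography g = 0.01 with N_0 = C/2, AR(1) s_0 = 0.001,
s_mean = 0.02, λ = 0.6, σ_ξ = 0.001.

## Numerical choices

* Fixed-point iteration: tolerance 1e−12 on successive iterates, max 10⁶
  iterations; composites with mean ≤ 1 + 1e−12 short-circuit to p = 0
  (critical convergence is O(1/n) and the limit is known).
* Nested backward iteration: truncation horizon doubled (starting at 256)
  until successive p values differ by < 1e−10; the extinction value
  stabilises geometrically at rate ≈ 1 − s̄ per generation, so the required
  horizon scales like 30/s̄. Finite pgf sequences continue in their final
  environment; a finite sequence that is subcritical in every cycle returns
  p = 0 outright (nonnegative supermartingale), a certainty that is
  undecidable for lazily-indexed sequences, which instead raise a
  convergence error when the horizon budget is exhausted.
* Schedule tie-breaking: accumulated-advantage floors and the ⌈·⌉ formula
  both use a 1e−9 relative guard so exact integer crossings (e.g.
  s̃τ = 1/4) land on the non-strict side consistently in both routes.
* Generation/cycle indices are 0-based internally; bottleneck indices n_i
  are 1-based as in the fitting inequality.
* Monte Carlo: vectorised over replicates in batches of 10⁴, each batch on
  its own `SeedSequence.spawn` substream (growing the replicate count
  extends rather than reshuffles earlier draws). A replicate survives when
  it reaches 1000 individuals — conditional on 1000 copies, loss is
  vanishingly unlikely for s ≥ 10⁻³ — or is still alive after 5000 cycles
  (counted as survived and logged). The 99% CI is the normal approximation
  2.576·√(p̂(1−p̂)/n).

## Problem sizes

The shipped comparisons use nested horizons of 2¹¹–2¹⁹ cycles (chosen by the
doubling rule at tolerance 1e−10), 10⁵ Monte Carlo replicates per scenario
point, AR(1) paths of 2¹⁴ generations, and direct-sum oracles truncated at
tail mass 1e−12. A full test run and the headline-number script each
complete in well under a minute on one core.

## What the generators emulate — and what they do not

The scenario generators produce *per-generation selective-advantage
trajectories* and census series, i.e. the inputs of the theory, under its
own assumptions: Poisson offspring, independent lineages, deterministic
census dynamics, selection acting identically on every individual. Passing
tests therefore demonstrate internal correctness of the formulas and
iterators, and the self-consistency of the approximation against its exact
counterpart — not robustness to features of real populations that the model
excludes: non-Poisson offspring variance, clonal interference and linkage,
density dependence within the mutant lineage, measurement noise in s, or
demographic stochasticity of the wild type.

## Known limitations

* The theory is first order in both s̄ and the fluctuation amplitude. The
  residual of the fully simplified closed forms against the exact iteration
  is a few percent at s̄ ~ 0.01 and grows with both parameters; for the
  demography case at s = 0.001 with g = 0.01 the census-induced
  perturbation is several times s̄ and the relative error reaches ~13% —
  the approximation is simply outside its regime there.
* When s_k ≪ s̄ in early generations the first-order theory systematically
  *underestimates* the fixation probability relative to its reference
  (tested qualitatively on the monotone scenario with s_0 = 0).
* The extinction recursion treats the bottleneck as binomial sampling at a
  deterministic fraction; fluctuations of the census at the bottleneck are
  not modelled.
* Both mechanisms in one mutant (altered fecundity *and* generation time),
  deleterious generation-time mutants (t_g > 1), structured populations and
  multitype processes are out of scope.
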