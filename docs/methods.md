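# Methods

## Model summary and assumptions

The package implements a discrete-time recurrent network of `N` binary
threshold neurons storing a sequence of one-step associations with the
clipped Hebbian (Willshaw) rule under Bernoulli morphological dilution, and a
two-variable mean-field reduction of its replay dynamics.  Core assumptions:

- **Patterns are random and independent.**  Pattern ξ_k activates exactly
  `M_k` of the `N` neurons, uniformly at random, independently across
  patterns.  Coding ratios `f_k = M_k/N` are i.i.d. draws from p_ϕ.
- **Synapses are binary and learning is clipped.**  Repeated potentiation of
  a pre/post pair has no further effect, so the synaptic state is an OR over
  associations — learning is idempotent and order-insensitive given the
  sequence.
- **The mean field treats inputs as Gaussian.**  Hits `m_t` and false alarms
  `n_t` are expectation values over realizations of the connectivity; their
  update uses the normal cdf of the standardized input margins.  This is a
  large-`N`, large-`M` approximation; its known weak spot is the far tail
  that generates false alarms (see *Validation scale* below).
- **Inhibition is instantaneous.**  The threshold is shifted by
  `h(m_t + n_t)` within the same step — there is no inhibitory delay or
  dynamics.  The balanced choice `b = c_m ς` makes the Off-population margin
  equal to `−θ` independent of total activity, which is what pins the
  saturated ("epileptic") state near half activity.

## Coding-ratio distributions

- **Gamma family** (`CodingRatioSpec("gamma", phi0, sigma_phi)`):
  parameterized by mean and sd, shape `ϕ₀²/σ_ϕ²`, scale `σ_ϕ²/ϕ₀`.
  `sigma_phi=0` is the degenerate (homogeneous) case and is handled exactly,
  not as a limit.  Raw moments are closed-form; note the fourth raw moment of
  a Gamma with these parameters is `ϕ₀⁴ + 6σ²ϕ₀² + 11σ⁴ + 6σ⁶/ϕ₀²`
  (the coefficient 11 follows from Γ(k+4)/Γ(k) = k(k+1)(k+2)(k+3) and is
  verified in the tests against quadrature and the exponential special case).
- **Triangular family** (`make_triangular(phi_max, sigma_phi, skew)`): the
  symmetric variant is the isosceles triangle with mode `ϕ_max` and
  half-width `√6·σ_ϕ`; the skewed variants are one-sided right triangles
  with support entirely below (negative) or above (positive) the mode and
  width `3√2·σ_ϕ`.  Widths are chosen so the sd equals `σ_ϕ` *exactly*; the
  mean offset of the one-sided triangles from the mode is then `√2·σ_ϕ` —
  a geometric property of the triangle, which the package reports rather
  than forcing any other offset.
- **Sampling guards**: draws with `f ≥ 1` or with `round(f·N) < 1` (an empty
  integer pattern) are rejected and redrawn, with a cap of 1000 rejections
  per slot.  Pattern sizes are real-valued `f·N` for the mean field and
  `round(f·N)` clamped to ≥ 1 for the binary network.

## Connectivity statistics

Per realization, ς and E[ς_A²] use the closed product forms (evaluated via
`log1p` sums, stable to P ~ 10⁴ and beyond); `V_ς² = (E[ς_A²] − ς²)/ς²` is
floored at 0 against roundoff.  Exhaustive enumeration over all 2^P
activation schedules is kept in the test suite as the independent oracle
(P ≤ 12).

Ensemble moments over random ϕ are computed by a **chain (transfer)
recursion**: conditioning the product `∏(1 − f_k f_{k−1})` on the last
coding ratio gives a conditional expectation polynomial in it (degree 1 for
the mean, 2 for the mean square), so integrating out one factor at a time
yields an exact linear recursion in 2 (resp. 3) coefficients, using only the
first four raw moments of p_ϕ.  This is mathematically identical to the
alternating series over the run combinatorics `n_j(P,k)` but has no
cancellation and costs O(P), so it works unchanged at P ≈ 7000 where a naive
series evaluation loses all significant digits.  The series form (binomials
via `lgamma`) is retained as an independent cross-check of the mean, and
both are validated against Monte-Carlo ϕ-ensembles.

`calibrate_P` fixes the mean connectivity: per-realization mode extends a
sampled ϕ one pattern at a time until the realized ς reaches `c/c_m` (the
returned vector is the one actually used downstream, so replay runs on
exactly the calibrated sequence); ensemble mode bisects the monotone
analytic ⟨ς⟩(P).

## Mean-field numerics

- Replay starts from the intact first pattern (`m₀ = M₀`, `n₀ = 0`); partial
  cues are available as an option but not used in the standard experiments.
- The ς, V_ς² and `b = c_m ς` fed to the map are the realized values of the
  specific sampled ϕ, not ensemble means.
- Zero variance is treated as a hard threshold: Φ((μ−θ)/0) := 1, ½, 0 for
  μ >, =, < θ_eff.  Variances are floored at 0.
- The V_ς² correlation correction enters exactly as the moment formulas
  state: in the Off population for the full input, and in the On population
  only through its noise term.
- **Nonlinear inhibition**: below the operating point `x = ϕ₀N` the linear
  term is replaced by a sigmoid `κ/(1 + e^{−λ(x−ν)})` with `λ = 10⁻⁴/ϕ₀`
  and κ, ν fixed by value- and slope-continuity at the operating point.
  This construction requires `λϕ₀N = 10⁻⁴·N > 1`, i.e. N > 10⁴; the
  constructor raises otherwise.  Supralinearity means h(x) < b·x below the
  operating point — weaker inhibition, an effective boost for small
  patterns.
- Ensemble experiments use a vectorized engine that iterates all
  realizations simultaneously (exactly equal to the scalar path, asserted in
  tests) and reuses the same ϕ draws across a threshold grid (common random
  numbers).

## Experiments and conventions

- Success of a step: `Γ_t > 0.5` strictly; ϱ_t is the ensemble fraction.
- `T90`: the longest *prefix* with ϱ strictly above 0.9 — one bad step ends
  the credited length.  `T = max_θ T90` over an integer θ grid (default
  1..60); the grid is recorded in every output.
- Capacity curves fit `log T = const − α log P` on the strictly decreasing
  branch (points past the argmax with 0 < T < Q, at least three required);
  the cutoff capacity `P_c` is where the fitted line meets the plateau
  `T = Q`.  Both the raw curve and the fit are reported so alternative
  cutoff definitions can be applied post hoc.
- The short-sequence capacity comparison locates the largest P with
  `T ≥ 10` by doubling/halving from the classical capacity and bisecting to
  2 % relative resolution, probing with `Q = 12` (sufficient to decide
  T ≥ 10) and 100 realizations per probe (1 for the deterministic
  homogeneous case).
- Termination statistics define τ as the step before the *first* failure;
  runs that never fail within Q are excluded from the scatter and counted
  separately.  Under the replay dynamics failure states (silent/saturated)
  are effectively absorbing, so first-failure and last-success conventions
  coincide.

## Binary-network validation and its scale

The full simulator materializes only morphological synapses: the Bernoulli
mask is sampled row-block-wise, and potentiation is decided by ANDing
bit-packed pre/post activation schedules, giving a sparse effective-weight
matrix (~c_m ς N² entries).  A neuron exactly at threshold fires (Θ(0) = 1;
switchable), and autapses are excluded.

Validation runs use N = 10⁴ with a *denser* code than the reference
mean-field scale: at N = 10⁴ and ϕ₀ = 0.01 the signal margin
(`c_m(1−ς)M ≈ 5` inputs against σ ≈ 3) is too small for any stable-replay
wedge to exist, in either model.  The scaled validation cell therefore uses
f = 0.1, c = 0.02 (ς = 0.2, P = 22), where the wedge is wide; stability,
silence and saturation are compared against the mean field there.  Ensemble
means of the retrieval quality track the mean-field trajectory to within
0.02; raw false-alarm *counts* are systematically a few neurons above the
mean-field value because the Gaussian approximation underestimates the
binomial tail at these sizes, so agreement is asserted on retrieval quality
and on success/failure classification (the latter is also the criterion the
phase-diagram validation uses), not on raw moments.

In the saturated state at this reduced scale the active subset turns over
only slowly (a percent per step) rather than remixing freely — small
networks freeze into high-degree cores; this is a finite-size effect of the
validation scale, not a property of the reference-scale model.

## Synthetic-data realism

The generators emulate exactly the study conditions of the model:
independent uniform random patterns with i.i.d. coding ratios, Bernoulli
dilution, and noiseless clipped learning.  They do not emulate spatially
structured or correlated patterns, pattern reuse across sequences, synaptic
noise, or any plasticity during retrieval.  Passing tests therefore
demonstrate the internal consistency of the theory and simulator under its
own assumptions, not robustness of real hippocampal replay.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| N | 10⁵ (mean field), 10⁴ (binary validation) | network size (neurons) |
| c_m | 0.1 | morphological connectivity |
| ϕ₀ | 0.01 | mean coding ratio |
| c | 0.05 | target effective connectivity (sets P ≈ 6900 at ϕ₀ = 0.01) |
| θ | ~24–32 | firing threshold (synaptic-input units); wedge center ≈ 28 |
| b | c_m ς | inhibitory weight (balanced) |
| Q | 100 | replay length (steps) |
| n_real | 100 (maps/curves), 10⁴ (termination scatter) | ensemble sizes |

Ensemble sizes and grids in the shipped experiments are chosen so the full
test suite and the acceptance script each run in well under half an hour on
one core; all are plain function arguments.

## Known limitations

- Ensemble moments assume finite first four moments of p_ϕ; heavy-tailed
  families are out of scope.
- The mean-field false-alarm tail is biased low at small N (see above).
- The nonlinear-inhibition construction is undefined for N ≤ 10⁴.
- `P_c` depends on the chosen grid and the plateau-intersection convention;
  the raw T(P) points are always reported alongside.
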