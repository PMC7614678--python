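# Methods

## Model and procedure

`cpssd` performs pre-posterior (design-stage) analysis for a two-arm
comparison of normal means with a common variance σ₀².  The data of the new
experiment enter only through the sufficient statistic x̄_Δ, the difference
in arm sample means, with sampling variance (1/n_A + 1/n_B)σ₀².

**Prior synthesis.**  K pre-experimental sources each provide a normal
summary N(m_k, s_k²) of their effect and an incommensurability weight
w_k ∈ [0, 1].  A commensurate predictive distribution
θ̃_k | θ_k, ν_k ~ N(θ_k, 1/ν_k) projects each source onto the new-trial
parameter space; the predictive precision ν_k has the mixture prior
w_k·Gamma(a₀₁, b₀₁) + (1 − w_k)·Gamma(a₀₂, b₀₂).  Marginalising ν_k yields
a two-component scaled/shifted t mixture (components located at θ_k with
degrees of freedom 2a₀ⱼ and scale √(b₀ⱼ/a₀ⱼ)), which is replaced by the
moment-matched normal N(θ_k, w_k·b₀₁/(a₀₁−1) + (1−w_k)·b₀₂/(a₀₂−1)).  The
match is exact in the first two moments — the mixture's variance equals the
normal's by construction — and its density/CDF accuracy can be quantified
with `normal_approximation_error` (sup-norm and Kolmogorov distance on a
±12-combined-scale grid of 4001 points, doubled once or twice if the
distances have not stabilised to 1e−9; this window captures the heavy
tails of t components with as few as 4 degrees of freedom).  Writing
μ_Δ = Σ p_k θ̃_k with p_k ∝ exp(−w_k²/s₀) gives the collective prior
N(Σ p_k m_k, Σ p_k² ξ_k²).

**Posterior.**  Known σ₀²: conjugate normal update of the collective prior
by x̄_Δ.  Unknown σ₀²: the prior σ₀² ~ Inv-Gamma(c/2, cV/2), where V is the
collective prior variance, makes the marginal posterior of μ_Δ proportional
to a normal kernel times a nonstandardised t kernel (location x̄_Δ,
squared scale (1/n_A + 1/n_B)V, c degrees of freedom).  No closed-form
normaliser exists; `marginal_posterior_unknown_variance` normalises by
adaptive quadrature on a ±15-combined-scale window (absolute tolerance
1e−10) and raises with diagnostics if the quadrature misbehaves.

**Criteria.**  The ACC, ALC and APVC bound average coverage of a
fixed-length HPD interval, average credible length, and average posterior
variance, over the predictive law of x̄_Δ (and of σ₀² when unknown).  The
posterior here is symmetric and unimodal, so HPD intervals are symmetric
about the posterior mean.  Closed forms exist for everything except the
unknown-variance ALC.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| a₀₁, b₀₁ | down-weighting Gamma component (precision scale) | 2, 2 | diffuse: predictive inflation b₀₁/(a₀₁−1) = 2 on the squared-effect scale |
| a₀₂, b₀₂ | borrowing Gamma component | 18, 3 | concentrated near precision 6; inflation 3/17 ≈ 0.18, close to full pooling |
| s₀ | synthesis concentration | 0.05 | small relative to typical w_k so relevance is discriminated; s₀ → ∞ gives equal weights, s₀ → 0⁺ concentrates on the smallest w_k (ties split equally — forced by the softmax form) |
| c | variance-prior degrees of freedom | user-set (3 = minimal, 5 = moderate borrowing) | E[σ₀²] = cV/(c−2) requires c > 2 for ACC/APVC; ALC is defined for all c > 0 |
| ℓ₀ / ℓ, 1−α / 1−α₀, ε₀ | criterion targets | 0.65, 0.95, 0.03 in the examples | effect measured as a log-odds ratio; no field convention exists, these mirror the worked design |
| allocation ratio R = n_B/n_A | arm imbalance | 1 | the effective size e = n_A n_B/(n_A + n_B) is inverted as n_A = e(1+R)/R, n_B = e(1+R) |

Validation: a₀ⱼ ≤ 1 is a hard error (the predictive variance would be
infinite).  If the "down-weighting" component is *less* diffuse than the
"borrowing" one the package warns rather than fails, since the model stays
well defined but the interpretation of w_k inverts.

## Numerical choices

* **Unknown-variance ALC expectation.**  E[(1/V + e/σ₀²)^{−1/2}] is
  computed on the precision scale u = 1/σ₀² ~ Gamma(c/2, rate cV/2) via the
  quantile transform: the integrand, bounded by √V, is integrated over the
  unit interval with adaptive quadrature (absolute tolerance 1e−10).  This
  is stable for every c > 0, including c ≤ 2 where E[σ₀²] diverges.
* **ALC integer search.**  The expected length is strictly decreasing in
  the effective size, so the smallest admissible total is found by
  bisection.  The search runs over integer *totals* in unit steps, each
  total split into the integer pair closest to the allocation ratio that
  maximises the effective size (⌊N/2⌋, ⌈N/2⌉ at R = 1) — odd totals are
  therefore admissible.  A `step` parameter restricts to coarser grids
  (e.g. even totals).  When c > 2 the upper bracket is the ACC solution
  (valid since ALC ≤ ACC by Jensen's inequality: E[σ_N] ≤ √E[σ_N²]);
  otherwise the bracket expands geometrically up to `n_max`.
* **Binding priors.**  When the collective prior alone meets the target
  (e.g. 4z²/ℓ₀² ≤ 1/V), solvers return zero with a `binding` flag instead
  of a negative continuous solution.
* **Integer reporting.**  Closed-form criteria report the continuous total
  (1 d.p. in human-readable output, full precision in JSON) plus the
  smallest integer total whose best split meets the bound; the ALC reports
  integers natively.
* **z-quantiles** come from `scipy.stats.norm.ppf` at full double
  precision; no table lookups.
* **Zero cells in 2×2 tables** (binary endpoints) get the Haldane–Anscombe
  0.5 correction to every cell, flagged in the output; a zero margin is an
  error because the odds ratio is then unidentified.

## Monte-Carlo evaluator

`simulate_average_properties` draws σ₀² first and then x̄_Δ given σ₀² —
the conditional structure of the predictive law — and evaluates coverage
and length on the conditional-normal posterior given the drawn σ₀², the
representation from which the unknown-variance criteria are derived.  A
`use_marginal_posterior` flag instead recomputes per-replicate quantities
from the σ₀²-integrated marginal posterior by quadrature; this is a
cross-check, not an equivalent route — the marginal posterior has heavier
tails, so its fixed-length coverage is systematically slightly lower and
its posterior variance slightly higher than the conditional route's.
Monte-Carlo standard errors use the sample-SD/√reps estimator; defaults
are 10⁵ replicates and seed 20220328, and identical inputs with an
identical seed reproduce a report bit for bit.

The built-in scenarios are summary-level by construction: they emulate
elicited or historical *summaries* (m_k, s_k², w_k), not subject-level
data.  Passing tests therefore demonstrate correctness of the synthesis,
the solvers and the pre-posterior averages under the stated normal/
inverse-gamma model — they do not probe non-normal outcomes, per-subject
variability, mis-elicited w_k, or analyses under the exact t-mixture prior
rather than its normal approximation.

## Design choices where the design was open

* **w_k from Hellinger distances.**  Pairwise Hellinger distances between
  source summaries (closed form for normals, H² = 1 − √(2σ_aσ_b/(σ_a²+σ_b²))·exp(−(μ_a−μ_b)²/(4(σ_a²+σ_b²))))
  are exposed via `hellinger_matrix` as an elicitation aid.  No automatic
  distance-to-weight mapping is imposed: any such rule would be an
  unvalidated modelling commitment, so the weights remain user inputs.
* **Single-source comparison mode** uses the most informative summary
  (smallest s_k²) directly as the prior, without commensurate inflation.
* **Optimal benchmark** equates σ₀² to V (known-variance mode) or sets
  c = 10⁶ (unknown mode), representing perfect commensurability between
  prior and new data.
* **APVC known-variance reporting.**  The closed form is
  e ≥ (1/ε₀ − 1/V)σ₀², cross-checked in the tests against a root-finder on
  the posterior-variance function itself.
* **Both posterior representations** (conditional-normal and integrated
  marginal) are exposed, since design formulas rest on the former while a
  final analysis might report the latter.

## Problem sizes

The test suite and the acceptance script run entirely on the built-in
summary-level scenarios (K = 5 sources).  Simulation oracles use 10⁶ draws
where a distributional identity is being checked and 10⁵ replicates for
the average-property verifications, which puts Monte-Carlo standard errors
near 7×10⁻⁴ on coverage — small enough that 3-SE bands are decisive for
the designs involved.

## Known limitations

* The normal approximation to the predictive t mixture is used throughout
  synthesis and solving; its error is measurable but not propagated.
* Arms share one variance σ₀²; unequal variances are out of scope.
* No frequentist operating characteristics (power, type-I error), no
  design/analysis "two-prior" split, and no interim re-estimation of w_k.
* Time-to-event endpoints are not implemented; binary endpoints are
  supported only through the log-odds-ratio normal approximation.
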