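# Methods

## Null model

Under the null hypothesis a molecule's rank in each of k experiments is
uniform on {1..n}, independent across experiments, so the rank product
RP = ∏ r_i has distribution function G_k(ρ)/n^k with
G_k(ρ) = Σ_{r ∈ {1..n}^k} Θ(ρ − ∏ r_i), Θ the inclusive step function
(the p-value event is ∏ r_i ≤ ρ). G_k is a right-continuous integer step
function: G_k(ρ) = 0 below 1, n^k above n^k, and all information sits at
integer ρ.

## Exact computation (`rpval.exact`)

Conditioning on the first experiment's rank gives
G_k(ρ) = Σ_{r=1}^{min(⌊ρ⌋,n)} G_{k−1}(⌊ρ/r⌋). For integer arguments only
the floor ⌊ρ/r⌋ matters, and consecutive r share the same floor, so the
sum is evaluated over O(√ρ) divisor blocks; memoization is keyed on
(level, floor value). Because ⌊⌊ρ/a⌋/b⌋ = ⌊ρ/(ab)⌋, every argument at
every level lies in the ~2√ρ-element set {⌊ρ/d⌋}, which keeps the whole
computation near O(k·ρ^{3/4}). Counts are Python integers throughout —
no floating accumulation — and the final division by n^k is exact
int/int → float. The worked-example value at ρ ≈ 5.9 × 10⁷ (n = 9047,
k = 4) takes ~2.5 s. Two guards (enumeration ≤ 10⁷ tuples; recursion
ρ ≤ 10⁸ by default) are explicit, overridable errors, not truncations.

## Bounds (`rpval.bounds`)

G_{k−1}(ρ/r) is nonincreasing in r, so the inner sum can be bracketed by
integrals, giving one integral recursion for an upper bound (keep the
r = 1 term plus ∫₁^{min(ρ,n)}) and one for a lower bound (keep the r = n
term, evaluated at max(1, ρ/n), plus the same integral). A single Δ-flag
(0 = lower, 1 = upper) selects between them. Splitting the range of ρ at
powers of n turns the nonlinear integration limit min(ρ, n) into linear
ones: on each interval n^{k−j} ≤ ρ < n^{k−j+1} (index j = 1..k; j = 0 and
j = k+1 are the saturated pieces n^k and 0) the solution has the closed
form

    G̃_kj(ρ) = ε + δρ + Σ_m γ_m ρ (log(ρ/n^{k−j+β_m}))^{α_m},

with integer exponents α_m ∈ {1..k} and offsets β_m ∈ {0,1}. The
parameter sets live on a lattice of nodes (level k′, interval j′):
interior nodes update from (k′−1, j′−1) and (k′−1, j′), diagonal nodes
(j′ = k′) from (k′−1, k′−1) alone, and the left edge (j′ = 0) is the
constant n^{k′} (realized as δ = 0 with an empty term list — a
zero-coefficient term and no term evaluate identically). After every
update, terms with identical (α, β) are merged by summing γ, so a node
never carries more than 2·level terms and a full traversal is O(k³)
parameters. Both traversal orders — on-demand recursion and a
precomputed dependency plan — share one cache and are tested to produce
identical parameters; batch evaluation shares a single traversal across
all requested ρ.

Verified by hand and against enumeration, the first steps give
G̃₁(ρ) = ρ; upper G̃₂₂ = ρ + ρ log ρ, lower G̃₂₂ = 1 + ρ log ρ on [1, n);
upper G̃₂₁ = ρ − ρ log(ρ/n²), lower G̃₂₁ = −n + (1+1/n)ρ − ρ log(ρ/n²) on
[n, n²).

### Numerical choices

- Parameters are kept unscaled in double precision; ε grows like n^{k′},
  so the supported range is n^k below the double overflow threshold
  (ProblemSpec enforces this). Final normalization divides in log space,
  exp(log G̃ − k log n).
- Logarithms log(ρ/n^{k−j+β}) are formed as log ρ − (k−j+β) log n so
  reference scales near the overflow threshold never materialize.
- γ carries mixed signs; compression groups equal (α, β) before summing.
  Against an independent 50-digit re-implementation of the recursion
  (mpmath, tests only), double evaluation drifts ≤ ~3 × 10⁻¹⁴ relative up
  to k = 20, n = 10⁴; tests assert 10⁻⁹.
- Interval membership is decided by comparing ρ with exact integer powers
  of n — never via ceil(k − log ρ/log n), which misassigns boundaries.
  Intervals are left-closed: ρ = n^{k−j} belongs to interval j, and
  ρ = n^k routes to the saturated j = 0 piece.
- Outputs are clamped to [0, 1]; a bound above 1 is vacuous but must not
  propagate into downstream adjustment.

### What the bounds guarantee — and a limitation

The upper bound dominates G_k everywhere: the induction needs
G̃_{k−1} ≥ G_{k−1} at all real arguments, which holds from level 1 up
(G̃₁(ρ) = min(ρ, n) ≥ ⌊min(ρ, n)⌋). The test suite confirms zero
violations over every integer ρ for all n ≤ 12, k ≤ 5 with n^k ≤ 10⁵.

The analogous claim for the lower bound fails pointwise for small n: the
recursion evaluates the level-(k−1) bound at non-integer ρ/r inside the
integral, where the continuous form exceeds the step function (e.g.
G̃₁(9.7) = 9.7 > G₁(9.7) = 9), and for coarse n the accumulated excess can
push the "lower" bound slightly above the exact value at integer ρ near
the top of the range. Concretely, at n = 8, k = 2, ρ = 14 the exact count
is 29 while the recursion gives 1.75 + 6 + 14·ln(8/1.75) ≈ 29.03.
Exhaustively over n ∈ {2..12}, k ∈ {1..5}, n^k ≤ 10⁵, all violations but
one lie in the top interval ρ ≥ n^{k−1}, the worst relative excess is 12%
(n = 2), shrinking roughly like 1/n, and at transcriptomics scale
(n in the thousands) the effect is far below the bounds' own width in the
small-p tail. The package therefore documents the lower bound as reliable
for tail p-values and small only-guaranteed region: unit tests assert it
below n^{k−1}; the upper bound, which is what protects against false
positives, is asserted everywhere.

## Approximations (`rpval.approx`)

- **Geometric mean** √(lower·upper), computed in log space. Accurate to a
  few percent in the tail (within a factor 1.5 of exact across the whole
  small-ρ range at n = 10, k = 4) but not a guaranteed bound.
- **Gamma**: treating r/(n+1) as continuous Uniform(0,1) makes
  −Σ log(r_i/(n+1)) a Gamma(k,1) variable, so
  p ≈ Q(k, x) with x = k log(n+1) − log ρ (regularized upper incomplete
  gamma; for integer k the finite series e^{−x} Σ_{i<k} x^i/i!, which an
  independent series oracle checks to 10⁻¹² relative). The construction
  uses n+1, not n. Biased upward for small ρ — tests assert gamma ≥ upper
  bound there — and accurate only for large ρ.
- **Permutation**: draws k independent uniform ranks per sample (the null
  of the statistic, not a shuffle of any data matrix); binomial standard
  error; products compared in int64 when n^k < 2⁶², otherwise in log
  space. Identical seed and draw count give identical estimates.

## Pipeline (`rpval.pipeline`)

Paired designs only: each input column is one treatment–control
comparison. Rank 1 is the strongest evidence in the chosen direction;
ties are broken by seeded randomization (the only policy consistent with
the permutation null — a deterministic midrank would make tied molecules
share spuriously extreme rank products). Down-regulation ranks are the
reversal n+1−r of the up ranks. Rank products are exact big integers.
p-value methods: exact, upper, lower, geomean, gamma; adjustments: none,
Bonferroni (α = π/n per test), Benjamini–Hochberg (via statsmodels).
Up and down are reported as two one-sided analyses; no two-sided
combination rule is imposed. The default method is geomean for accuracy,
with upper recommended wherever a guaranteed false-positive ceiling is
required. Averaging rank products over random pairings of unpaired
designs is out of scope: its null distribution is not defined by the
machinery here.

## Synthetic data (`rpval.simulate`)

Pure functions of (config, seed). Null rank matrices are independent
uniform permutations per column — exactly the null model, so p-values on
them must be super-uniform (tested). Spiked matrices add a constant shift
`effect` to `n_de` molecules over Normal(0, noise_sd) noise in every
experiment; defaults in tests use effect = 5·noise_sd, n_de = 10, n = 500,
k = 4, which a well-powered replicated profiling screen resembles. The
generator does not emulate molecule–molecule correlation,
intensity-dependent variance, or missingness; passing recovery tests
demonstrate the machinery ranks consistent signals first, not performance
on any particular platform's noise.

## Problem sizes in the test suite

Exhaustive enumeration oracles run at n^k ≤ 10⁵ (42 (n,k) pairs, every
integer ρ); the published 9047-gene example is checked at all four
tabulated rank products including the ρ ≈ 5.9 × 10⁷ exact value;
permutation concordance uses 10⁶ draws at n = 10, k = 3; the spike
recovery study uses 100 seeds. The full suite runs in well under a
minute.
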