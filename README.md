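# rpval — p-values for the rank product statistic

The rank product is a simple, distribution-free statistic for finding
molecules (transcripts, proteins, metabolites) that are consistently
up- or down-regulated across k replicated treatment–control experiments:
rank the n molecules within each experiment by evidence of change, then
multiply each molecule's ranks across experiments. A small rank product
ρ means a molecule sat near the top of every list, and its significance
is the null tail probability

    p(ρ) = P(RP ≤ ρ) = G_k(ρ) / n^k,      G_k(ρ) = #{(r_1,…,r_k) ∈ {1..n}^k : ∏ r_i ≤ ρ}.

Computing that tail is the hard part in practice: exact calculation is
slow for large ρ, permutation sampling cannot reach the p < 10⁻¹⁰ regime
that genome-scale multiple testing demands, and the classical Gamma(k,1)
(Fisher-type) approximation overestimates small p-values by orders of
magnitude. `rpval` provides:

- **exact** p-values via a memoized divisor-block recursion
  G_k(ρ) = Σ_r G_{k−1}(⌊ρ/r⌋), in exact integer arithmetic — fast even for
  rank products around 10⁸;
- **strict bounds**: piecewise closed-form lower and upper bounds on
  G_k(ρ) of the form ε + δρ + Σ_m γ_m ρ (log(ρ/n^{k−j+β_m}))^{α_m},
  obtained by replacing the discrete recursion with integral recursions;
  the parameters follow a lattice recursion whose cost is polynomial in k
  and independent of both ρ and n;
- **approximations**: the geometric mean of the two bounds (accurate but
  not a guaranteed bound), the Gamma(k,1) upper tail at
  x = k·log(n+1) − log ρ, and a seeded Monte-Carlo permutation estimator;
- a small **differential-expression pipeline** (ranking with randomized
  ties, both directions, Bonferroni/Benjamini–Hochberg adjustment) and a
  **CLI** (`rpval pvalue | analyze | curve | simulate`).

## Worked example

The classic application: n = 9047 genes ranked in k = 4 independent
age-association studies. The top up-regulated gene has rank product
ρ = 9282:

```
$ rpval pvalue --n 9047 --k 4 --rho 9282 --methods exact,gamma,upper,geomean,lower
rho     exact        gamma        upper        geomean      lower
9282.0  2.64546e-10  5.25469e-09  3.88761e-10  2.70853e-10  1.88705e-10
```

Reading the row: the exact tail probability is 2.645 × 10⁻¹⁰; the strict
bounds enclose it within about a factor 1.4 on either side, and their
geometric mean (2.709 × 10⁻¹⁰) is within 3% of exact, while the gamma
approximation (5.255 × 10⁻⁹) is off by a factor ~20 — the systematic
conservatism that makes it lose true discoveries after multiple-testing
correction. With a Bonferroni family-wise rate of 0.05 over 9047 genes the
per-test threshold is 0.05/9047 ≈ 5.526 × 10⁻⁶ (`bonferroni_threshold`),
so this gene is significant by every method.

The same numbers from Python:

```python
from rpval import ProblemSpec, pvalue_bundle
bundle = pvalue_bundle(ProblemSpec(9047, 4), 9282, with_exact=True)
print(bundle.exact, bundle.lower, bundle.geomean, bundle.upper, bundle.gamma)
```

End-to-end analysis of a fold-change matrix (TSV with an id column and one
column per experiment):

```
$ rpval simulate --n 500 --k 4 --n-de 10 --effect 5 --seed 1 --out matrix.tsv
$ rpval analyze matrix.tsv --method geomean --adjust bh --out results.tsv
```

`results.tsv` has one row per molecule: `rho_up`, `p_up`, `p_up_adj`,
`significant_up`, and the same for the down direction.

## Guarantees and caveats

The upper bound is strict for every ρ (verified exhaustively against
enumeration for all n ≤ 12, k ≤ 5 with n^k ≤ 10⁵). The lower bound is
strict in the small-p tail that matters for molecule selection, but for
small n it can overshoot the discrete exact value by a few tenths of a
percent at integer ρ inside the top interval ρ ≥ n^{k−1}; see
`docs/methods.md` for the quantified analysis. The geometric mean is an
approximation, not a bound — use `method=upper` when false-positive
protection must be absolute.
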