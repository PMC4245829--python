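"""Approximate rank product p-values: geometric mean, gamma, permutation.

The geometric mean of the strict lower and upper bounds is an accurate
point estimate of the exact p-value (though itself no longer a guaranteed
bound).  The gamma approximation treats the per-experiment ranks as
continuous uniforms — r/(n+1) uniform on (0, 1) — so that the negative sum
of log-transformed per-experiment p-values is Gamma(k, 1) distributed, the
same construction as Fisher's method of combining p-values; for small rank
products it is badly conservative because the true rank distribution is
discrete.  The Monte-Carlo permutation estimator simulates the null of the
statistic directly by drawing independent uniform ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .bounds import LOWER, UPPER, BoundsEngine
from .exact import ProblemSpec

__all__ = [
    "PValueBundle",
    "geomean_pvalue",
    "gamma_pvalue",
    "permutation_pvalue",
    "pvalue_bundle",
]


@dataclass(frozen=True)
class PValueBundle:
    """All p-value estimates for one rank product."""

    rho: float
    lower: float
    upper: float
    geomean: float
    gamma: float
    exact: float | None = None
    permutation: tuple[float, float, int] | None = None  # (estimate, se, n_draws)


def _geomean(lower: float, upper: float) -> float:
    if lower <= 0.0 or upper <= 0.0:
        return math.sqrt(max(lower, 0.0) * max(upper, 0.0))
    # log-space sqrt(l * u) survives subnormal products
    return math.exp(0.5 * (math.log(lower) + math.log(upper)))


def geomean_pvalue(spec: ProblemSpec, rho: float) -> float:
    """sqrt(lower * upper): accurate approximation, not a guaranteed bound."""
    return _geomean(
        BoundsEngine(spec, LOWER).pvalue(rho), BoundsEngine(spec, UPPER).pvalue(rho)
    )


def gamma_pvalue(spec: ProblemSpec, rho: float) -> float:
    """Upper tail of Gamma(k, 1) at x = k*log(n+1) - log(rho).

    For integer shape k this equals the finite sum
    ``exp(-x) * sum_{i<k} x**i / i!`` (the regularized upper incomplete
    gamma function Q(k, x)); x <= 0 maps to probability 1.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    x = spec.k * math.log(spec.n + 1) - math.log(rho)
    if x <= 0.0:
        return 1.0
    return float(special.gammaincc(spec.k, x))


def permutation_pvalue(
    spec: ProblemSpec, rho: float, n_draws: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(RP <= rho) with its binomial standard error.

    Draws ``n_draws`` independent k-tuples of uniform ranks (the null model
    of the statistic, not a permutation of any data matrix).  Products are
    formed in int64 when n**k fits, otherwise compared in log space (a
    floating comparison that is exact away from rho's immediate vicinity).
    Same seed and draw count give identical estimates.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if rho < 1:
        return 0.0, 0.0
    exact_products = spec.n_pow_k < 2**62
    log_rho = math.log(rho)
    hits = 0
    remaining = n_draws
    chunk = 1_000_000
    while remaining > 0:
        m = min(chunk, remaining)
        ranks = rng.integers(1, spec.n + 1, size=(m, spec.k))
        if exact_products:
            prod = np.prod(ranks, axis=1)
            hits += int(np.count_nonzero(prod <= math.floor(rho)))
        else:
            hits += int(np.count_nonzero(np.sum(np.log(ranks), axis=1) <= log_rho))
        remaining -= m
    p_hat = hits / n_draws
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_draws)
    return p_hat, se


def pvalue_bundle(
    spec: ProblemSpec,
    rho: float,
    *,
    with_exact: bool = False,
    n_draws: int | None = None,
    seed: int = 0,
    max_rho: float | None = None,
) -> PValueBundle:
    """Compute every requested estimate for one rank product."""
    from .exact import RECURSION_GUARD, exact_pvalue

    lower = BoundsEngine(spec, LOWER).pvalue(rho)
    upper = BoundsEngine(spec, UPPER).pvalue(rho)
    exact = None
    if with_exact:
        exact = exact_pvalue(
            spec, rho, max_rho=RECURSION_GUARD if max_rho is None else max_rho
        )
    permutation = None
    if n_draws is not None:
        est, se = permutation_pvalue(spec, rho, n_draws, seed)
        permutation = (est, se, n_draws)
    return PValueBundle(
        rho=rho,
        lower=lower,
        upper=upper,
        geomean=_geomean(lower, upper),
        gamma=gamma_pvalue(spec, rho),
        exact=exact,
        permutation=permutation,
    )
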