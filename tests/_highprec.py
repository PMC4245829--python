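"""Independent high-precision re-implementation of the piecewise bound
recursion, used only as a numerical oracle in tests.

Pure-Python lists and mpmath arbitrary precision; no numpy, no code shared
with rpval.bounds beyond the published update formulas themselves.
"""

from __future__ import annotations

import mpmath as mp


def _compress(terms):
    merged = {}
    for a, b, g in terms:
        merged[(a, b)] = merged.get((a, b), mp.mpf(0)) + g
    return [(a, b, g) for (a, b), g in sorted(merged.items())]


def _node(level, j, n, delta_flag, cache):
    key = (level, j)
    if key in cache:
        return cache[key]
    n = mp.mpf(n)
    d = mp.mpf(delta_flag)
    if j == 0:
        params = ([], mp.mpf(0), n**level)
    elif j == level:
        terms_p, delta_p, eps_p = _node(level - 1, level - 1, n, delta_flag, cache)
        terms = [(1, 0, delta_p)]
        terms += [(a, b, d * g) for a, b, g in terms_p]
        terms += [(a + 1, b, g / (a + 1)) for a, b, g in terms_p]
        params = (_compress(terms), d * delta_p + eps_p, (1 - d) * (1 - eps_p))
    else:
        terms_l, delta_l, eps_l = _node(level - 1, j - 1, n, delta_flag, cache)
        terms_s, delta_s, eps_s = _node(level - 1, j, n, delta_flag, cache)
        terms = [(1, 0, delta_l), (1, 1, -delta_s)]
        terms += [(a, b, d * g) for a, b, g in terms_l]
        terms += [(a, b, (1 - d) / n * g) for a, b, g in terms_s]
        terms += [(a + 1, b, g / (a + 1)) for a, b, g in terms_l]
        terms += [(a + 1, b, -g / (a + 1)) for a, b, g in terms_s]
        delta = d * delta_l + (1 - d) / n * delta_s + (eps_l - eps_s) / n ** (level - j)
        delta -= mp.fsum(
            g / (a + 1) * (-b * mp.log(n)) ** (a + 1) for a, b, g in terms_l
        )
        delta += mp.fsum(
            g / (a + 1) * ((1 - b) * mp.log(n)) ** (a + 1) for a, b, g in terms_s
        )
        eps = (1 - d) * (eps_s - eps_l) + n * eps_s
        params = (_compress(terms), delta, eps)
    cache[key] = params
    return params


def hp_bound_pvalue(n: int, k: int, rho, delta_flag: int, dps: int = 50) -> float:
    """Bound p-value computed end to end at ``dps`` decimal digits."""
    with mp.workdps(dps):
        rho_mp = mp.mpf(rho)
        if rho_mp < 1:
            return 0.0
        if rho_mp >= mp.mpf(n) ** k:
            return 1.0
        j = 1
        while rho_mp < mp.mpf(n) ** (k - j):
            j += 1
        terms, delta, eps = _node(k, j, n, delta_flag, {})
        log_rho = mp.log(rho_mp)
        log_n = mp.log(n)
        value = eps + delta * rho_mp
        for a, b, g in terms:
            value += g * rho_mp * (log_rho - (k - j + b) * log_n) ** a
        p = value / mp.mpf(n) ** k
        return float(min(max(p, mp.mpf(0)), mp.mpf(1)))
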