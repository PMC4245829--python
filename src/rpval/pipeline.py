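"""Differential-expression front end for the rank product statistic.

Takes an n-molecule by k-experiment matrix of paired fold changes, ranks
each experiment's column (rank 1 = strongest evidence, ties broken by
seeded randomization), forms per-molecule rank products for up- and
down-regulation, scores them with any of the p-value methods, and applies
a multiple-testing adjustment.  Only paired designs are supported: each
column must be one treatment-control comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .approx import gamma_pvalue
from .bounds import LOWER, UPPER, BoundsEngine
from .errors import DataError
from .exact import RECURSION_GUARD, ProblemSpec, exact_pvalue

__all__ = [
    "RankMatrix",
    "ranks_from_matrix",
    "rank_products",
    "bonferroni_threshold",
    "bh_adjust",
    "analyze",
]

Method = Literal["exact", "upper", "lower", "geomean", "gamma"]
METHODS = ("exact", "upper", "lower", "geomean", "gamma")
ADJUSTMENTS = ("none", "bonferroni", "bh")


@dataclass(frozen=True)
class RankMatrix:
    """Per-experiment ranks of n molecules; each column is a permutation of 1..n."""

    ids: tuple[str, ...]
    ranks: np.ndarray  # (n, k) int64
    direction: Literal["up", "down"]

    def __post_init__(self) -> None:
        n, k = self.ranks.shape
        if len(self.ids) != n:
            raise DataError("ids length must match the number of rows")
        expected = np.arange(1, n + 1)
        for col in range(k):
            if not np.array_equal(np.sort(self.ranks[:, col]), expected):
                raise DataError(f"column {col} is not a permutation of 1..{n}")

    @property
    def spec(self) -> ProblemSpec:
        n, k = self.ranks.shape
        return ProblemSpec(n, k)

    def reversed(self) -> "RankMatrix":
        """Ranks for the opposite direction: rank r becomes n + 1 - r."""
        n = self.ranks.shape[0]
        return RankMatrix(
            ids=self.ids,
            ranks=n + 1 - self.ranks,
            direction="down" if self.direction == "up" else "up",
        )


def ranks_from_matrix(
    values: pd.DataFrame | np.ndarray,
    direction: Literal["up", "down"] = "up",
    tie_policy: Literal["random", "stable"] = "random",
    seed: int | None = None,
    ids: Sequence[str] | None = None,
) -> RankMatrix:
    """Rank each experiment column so rank 1 carries the strongest evidence.

    ``direction='up'`` ranks the largest fold change first, ``'down'`` the
    smallest.  Ties are broken by seeded randomization by default (the only
    policy consistent with the permutation null); ``'stable'`` keeps input
    order instead.  Missing values are an error — impute upstream.
    """
    if isinstance(values, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in values.index]
        mat = values.to_numpy(dtype=float)
    else:
        mat = np.asarray(values, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2:
        raise DataError("values must be a 2-D matrix (molecules x experiments)")
    n, k = mat.shape
    if n < 2:
        raise DataError("need at least two molecules to rank")
    if np.isnan(mat).any():
        raise DataError("missing values are not supported; impute or filter first")

    key = -mat if direction == "up" else mat
    rng = np.random.default_rng(seed)
    ranks = np.empty((n, k), dtype=np.int64)
    for col in range(k):
        if tie_policy == "random":
            tiebreak = rng.random(n)
        elif tie_policy == "stable":
            tiebreak = np.arange(n)
        else:
            raise ValueError(f"unknown tie_policy {tie_policy!r}")
        order = np.lexsort((tiebreak, key[:, col]))
        ranks[order, col] = np.arange(1, n + 1)
    return RankMatrix(ids=tuple(str(i) for i in ids), ranks=ranks, direction=direction)


def rank_products(rm: RankMatrix) -> list[int]:
    """Per-molecule product of ranks, as exact Python integers."""
    return [math.prod(int(r) for r in row) for row in rm.ranks]


def bonferroni_threshold(pi: float, n: int) -> float:
    """Per-test significance level alpha = pi / n for family-wise rate pi."""
    if not 0 < pi <= 1:
        raise ValueError("pi must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return pi / n


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def _pvalues_for(
    spec: ProblemSpec, rhos: Sequence[int], method: Method, max_rho: float
) -> np.ndarray:
    rhos_arr = np.asarray([float(r) for r in rhos])
    if method == "exact":
        memo: dict = {}
        return np.array(
            [exact_pvalue(spec, r, max_rho=max_rho, memo=memo) for r in rhos]
        )
    if method == "gamma":
        return np.array([gamma_pvalue(spec, r) for r in rhos_arr])
    if method in ("upper", "lower", "geomean"):
        lower = BoundsEngine(spec, LOWER).pvalues(rhos_arr)
        upper = BoundsEngine(spec, UPPER).pvalues(rhos_arr)
        if method == "upper":
            return upper
        if method == "lower":
            return lower
        return np.sqrt(lower * upper)
    raise ValueError(f"unknown method {method!r}")


def analyze(
    values: pd.DataFrame | np.ndarray,
    method: Method = "geomean",
    adjust: Literal["none", "bonferroni", "bh"] = "bh",
    alpha_family: float = 0.05,
    seed: int | None = None,
    ids: Sequence[str] | None = None,
    precomputed_ranks: bool = False,
    tie_policy: Literal["random", "stable"] = "random",
    max_rho: float = RECURSION_GUARD,
) -> pd.DataFrame:
    """Full two-direction rank product analysis of a fold-change matrix.

    Returns one row per molecule with rank products and p-values for up-
    and down-regulation, adjusted p-values, and significance calls.  With
    ``precomputed_ranks=True`` the input is taken as up-regulation ranks
    (each column a permutation of 1..n) instead of fold changes.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if adjust not in ADJUSTMENTS:
        raise ValueError(f"adjust must be one of {ADJUSTMENTS}")

    if precomputed_ranks:
        if isinstance(values, pd.DataFrame):
            if ids is None:
                ids = [str(i) for i in values.index]
            mat = values.to_numpy()
        else:
            mat = np.asarray(values)
            if ids is None:
                ids = [str(i) for i in range(mat.shape[0])]
        rm_up = RankMatrix(
            ids=tuple(str(i) for i in ids),
            ranks=mat.astype(np.int64),
            direction="up",
        )
    else:
        rm_up = ranks_from_matrix(
            values, direction="up", tie_policy=tie_policy, seed=seed, ids=ids
        )
    rm_down = rm_up.reversed()
    spec = rm_up.spec

    rho_up = rank_products(rm_up)
    rho_down = rank_products(rm_down)
    p_up = _pvalues_for(spec, rho_up, method, max_rho)
    p_down = _pvalues_for(spec, rho_down, method, max_rho)

    if adjust == "none":
        adj_up, adj_down = p_up.copy(), p_down.copy()
        sig_up, sig_down = p_up <= alpha_family, p_down <= alpha_family
    elif adjust == "bonferroni":
        adj_up = np.minimum(p_up * spec.n, 1.0)
        adj_down = np.minimum(p_down * spec.n, 1.0)
        threshold = bonferroni_threshold(alpha_family, spec.n)
        sig_up, sig_down = p_up <= threshold, p_down <= threshold
    else:
        adj_up, adj_down = bh_adjust(p_up), bh_adjust(p_down)
        sig_up, sig_down = adj_up <= alpha_family, adj_down <= alpha_family

    return pd.DataFrame(
        {
            "id": list(rm_up.ids),
            "rho_up": rho_up,
            "p_up": p_up,
            "p_up_adj": adj_up,
            "significant_up": sig_up,
            "rho_down": rho_down,
            "p_down": p_down,
            "p_down_adj": adj_down,
            "significant_down": sig_down,
            "method": method,
        }
    )
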