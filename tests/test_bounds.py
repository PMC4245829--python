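"""Piecewise bound recursion: closed forms, lattice, numerical stability."""

import math

import numpy as np
import pytest

from rpval import (
    LOWER,
    UPPER,
    BoundsEngine,
    PieceParams,
    ProblemSpec,
    bound_pvalue,
    bound_pvalues_batch,
    compress,
    evaluate_piece,
    init_params,
    interval_index,
    plan_lattice,
    update_diagonal,
    update_interior,
)

from _highprec import hp_bound_pvalue
from conftest import exact_cdf


@pytest.mark.parametrize(
    "n,k,rho,expected_j",
    [
        (10, 4, 10**4, 0),  # rho = n^k routes to the constant piece
        (10, 4, 999, 2),
        (10, 4, 1000, 1),  # intervals are left-closed
        (10, 4, 1, 4),
        (10, 4, 0.5, 5),
        (7, 3, 343 - 1, 1),
        (7, 3, 49, 1),
        (7, 3, 48.999, 2),
    ],
)
def test_interval_index(n, k, rho, expected_j):
    assert interval_index(ProblemSpec(n, k), rho) == expected_j


def test_interval_index_exact_at_large_powers():
    # boundary membership must not rely on floating logs
    spec = ProblemSpec(9047, 4)
    for j in range(1, 5):
        edge = 9047 ** (4 - j)
        assert interval_index(spec, edge) == j
        assert interval_index(spec, edge - 0.5) == (j + 1 if edge > 1 else 5)


@pytest.mark.parametrize("level,n", [(0, 10), (3, 10), (2, 9047)])
@pytest.mark.parametrize("delta_flag", [LOWER, UPPER])
def test_left_edge_piece_is_constant(level, n, delta_flag):
    spec = ProblemSpec(n, 4)
    params = init_params(level, spec, delta_flag)
    assert params.epsilon == float(n) ** level
    assert params.delta == 0.0 and params.n_terms == 0
    for rho in (1.0, 17.3, float(n) ** level):
        assert evaluate_piece(params, spec, rho) == float(n) ** level


@pytest.mark.parametrize("delta_flag", [LOWER, UPPER])
def test_k1_piece_is_identity(delta_flag):
    spec = ProblemSpec(10, 1)
    engine = BoundsEngine(spec, delta_flag)
    params = engine.get(1, 1)
    assert params.delta == 1.0 and params.epsilon == 0.0
    for rho in (1, 4, 7.5, 9.99):
        assert evaluate_piece(params, spec, rho) == pytest.approx(rho, rel=1e-15)


@pytest.mark.parametrize("n", [10, 137])
def test_k2_closed_forms(n):
    """Hand-derived solutions of the first two update steps."""
    spec = ProblemSpec(n, 2)
    up = BoundsEngine(spec, UPPER)
    lo = BoundsEngine(spec, LOWER)
    rho_small, rho_big = 0.6 * n, 3.7 * n
    # diagonal piece on [1, n)
    assert up.raw_bound(rho_small) == pytest.approx(
        rho_small + rho_small * math.log(rho_small), rel=1e-12
    )
    assert lo.raw_bound(rho_small) == pytest.approx(
        1 + rho_small * math.log(rho_small), rel=1e-12
    )
    # interior piece on [n, n^2): delta/epsilon from the update equations
    pu, pl = up.get(2, 1), lo.get(2, 1)
    assert (pu.delta, pu.epsilon) == (1.0, 0.0)
    assert pl.delta == pytest.approx(1 + 1 / n) and pl.epsilon == -float(n)
    assert up.raw_bound(rho_big) == pytest.approx(
        rho_big - rho_big * math.log(rho_big / n**2), rel=1e-12
    )
    assert lo.raw_bound(rho_big) == pytest.approx(
        -n + (1 + 1 / n) * rho_big - rho_big * math.log(rho_big / n**2), rel=1e-12
    )


def test_compress_merges_duplicate_terms():
    spec = ProblemSpec(10, 3)
    params = PieceParams(
        level=3, interval=1, delta_flag=UPPER,
        alpha=np.array([1, 2, 1, 2]), beta=np.array([0, 1, 0, 1]),
        gamma=np.array([0.5, -0.25, 1.5, 0.75]), delta=0.3, epsilon=2.0,
    )
    merged = compress(params)
    assert merged.n_terms == 2
    assert sorted(merged.gamma.tolist()) == [0.5, 2.0]
    # value preserved
    for rho in (3.0, 55.0, 700.0):
        assert evaluate_piece(merged, spec, rho) == pytest.approx(
            evaluate_piece(params, spec, rho), rel=1e-12
        )
    # already-unique params unchanged
    again = compress(merged)
    assert np.array_equal(again.alpha, merged.alpha)
    assert np.array_equal(again.gamma, merged.gamma)


def test_compress_preserves_random_evaluations():
    rng = np.random.default_rng(42)
    spec = ProblemSpec(50, 5)
    for _ in range(50):
        m = rng.integers(1, 12)
        params = PieceParams(
            level=5, interval=int(rng.integers(1, 6)), delta_flag=LOWER,
            alpha=rng.integers(1, 6, m), beta=rng.integers(0, 2, m),
            gamma=rng.normal(size=m), delta=float(rng.normal()),
            epsilon=float(rng.normal()),
        )
        rho = float(np.exp(rng.uniform(0, 5 * math.log(50))))
        assert evaluate_piece(compress(params), spec, rho) == pytest.approx(
            evaluate_piece(params, spec, rho), rel=1e-12, abs=1e-12
        )


def test_term_count_stays_bounded():
    # alpha in {1..level}, beta in {0,1}: at most 2*level distinct terms
    spec = ProblemSpec(10000, 12)
    for flag in (LOWER, UPPER):
        engine = BoundsEngine(spec, flag)
        engine.prepare(range(1, 13))
        for (level, j), params in engine._cache.items():
            assert params.n_terms <= 2 * level
            if params.n_terms:
                assert params.alpha.min() >= 1 and params.alpha.max() <= level
                assert set(np.unique(params.beta)) <= {0, 1}


def test_plan_lattice_minimal_paths():
    # k=5, target interval 3: the dependency closure of node (5,3)
    expected = {
        (0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2),
        (3, 1), (3, 2), (3, 3), (4, 2), (4, 3), (5, 3),
    }
    plan = plan_lattice(5, {3})
    assert {(lv, j) for lv, j, _ in plan} == expected

    assert [(lv, j) for lv, j, _ in plan_lattice(1, {1})] == [(0, 0), (1, 1)]

    plan = plan_lattice(4, {1, 4})
    nodes = [(lv, j) for lv, j, _ in plan]
    assert len(nodes) == len(set(nodes))  # no duplicates
    assert all(j <= 4 for _, j in nodes)


def test_plan_orders_dependencies_first():
    for targets in ({1}, {3}, {1, 4}, {2, 5}):
        plan = plan_lattice(5, targets)
        seen = set()
        for level, j, kind in plan:
            if kind == "interior":
                assert {(level - 1, j - 1), (level - 1, j)} <= seen
            elif kind == "diagonal":
                assert (level - 1, j - 1) in seen
            seen.add((level, j))


def test_update_contract_errors():
    spec = ProblemSpec(10, 3)
    up = BoundsEngine(spec, UPPER)
    lo = BoundsEngine(spec, LOWER)
    with pytest.raises(ValueError):
        update_interior(up.get(1, 1), lo.get(1, 1), spec)  # mixed selectors
    with pytest.raises(ValueError):
        update_interior(up.get(1, 0), up.get(2, 1), spec)  # mismatched levels
    with pytest.raises(ValueError):
        update_diagonal(up.get(2, 1))  # not a diagonal node


@pytest.mark.parametrize("delta_flag", [LOWER, UPPER])
def test_traversal_invariance(delta_flag):
    """Recursive and planned traversals give identical compressed parameters."""
    spec = ProblemSpec(100, 8)
    planned = BoundsEngine(spec, delta_flag, mode="planned")
    recursive = BoundsEngine(spec, delta_flag, mode="recursive")
    for j in range(1, 9):
        a, b = planned.get(8, j), recursive.get(8, j)
        order_a = np.lexsort((a.beta, a.alpha))
        order_b = np.lexsort((b.beta, b.alpha))
        assert np.array_equal(a.alpha[order_a], b.alpha[order_b])
        assert np.array_equal(a.beta[order_a], b.beta[order_b])
        np.testing.assert_allclose(a.gamma[order_a], b.gamma[order_b], rtol=1e-12)
        assert a.delta == pytest.approx(b.delta, rel=1e-12)
        assert a.epsilon == pytest.approx(b.epsilon, rel=1e-12)


def test_batch_equals_scalar_and_never_recomputes():
    spec = ProblemSpec(137, 5)
    rng = np.random.default_rng(3)
    rhos = np.exp(rng.uniform(0, 5 * math.log(137), size=10_000))
    engine = BoundsEngine(spec, UPPER)
    batch = engine.pvalues(rhos)
    calls_after_first = engine.update_calls
    assert engine.pvalues(rhos).tolist() == batch.tolist()
    assert engine.update_calls == calls_after_first  # cache hit, no recompute
    for i in (0, 17, 4_242):
        assert batch[i] == pytest.approx(bound_pvalue(spec, rhos[i], UPPER), rel=1e-14)


@pytest.mark.parametrize("delta_flag", [LOWER, UPPER])
def test_endpoints_and_clamping(delta_flag):
    for n in (10, 100):
        for k in range(1, 7):
            spec = ProblemSpec(n, k)
            engine = BoundsEngine(spec, delta_flag)
            assert engine.pvalue(float(n) ** k) == 1.0
            assert engine.pvalue(0.2) == 0.0
            # G~(1) = 1 numerically
            assert engine.raw_bound(1.0) == pytest.approx(1.0, rel=1e-9)


def test_adjacent_pieces_agree_at_boundaries():
    n = 10
    for k in range(2, 9):
        spec = ProblemSpec(n, k)
        for flag in (LOWER, UPPER):
            engine = BoundsEngine(spec, flag)
            for j in range(1, k):
                edge = float(n) ** (k - j)
                left = evaluate_piece(engine.get(k, j), spec, edge)
                right = evaluate_piece(engine.get(k, j + 1), spec, edge)
                assert right == pytest.approx(left, rel=1e-9)


def test_bounds_monotone_in_rho():
    spec = ProblemSpec(10, 4)
    rhos = np.arange(1, 10**4 + 1, dtype=float)
    lower, upper = bound_pvalues_batch(spec, rhos)
    assert np.all(np.diff(lower) >= -1e-12)
    assert np.all(np.diff(upper) >= -1e-12)


def test_upper_bound_dominates_exact_everywhere():
    """The upper bound must exceed the enumerated G_k at every integer rho."""
    for n, k in [(2, 5), (3, 4), (5, 3), (10, 4), (12, 3), (7, 2)]:
        spec = ProblemSpec(n, k)
        exact = exact_cdf(n, k) / n**k
        upper = BoundsEngine(spec, UPPER).pvalues(np.arange(1, n**k + 1, dtype=float))
        assert np.all(exact <= upper * (1 + 1e-9) + 1e-15), (n, k)


def test_lower_bound_holds_below_top_interval():
    """Lower bound <= exact at integer rho < n^(k-1).

    Inside the top interval the continuous lower bound can slightly
    overshoot the discrete distribution for small n (documented
    limitation), so that region is checked separately by the exhaustive
    acceptance sweep.
    """
    for n, k in [(3, 4), (5, 3), (10, 4), (12, 3), (10, 2), (8, 2)]:
        spec = ProblemSpec(n, k)
        top = n ** (k - 1)
        exact = exact_cdf(n, k)[: top - 1] / n**k
        lower = BoundsEngine(spec, LOWER).pvalues(np.arange(1, top, dtype=float))
        assert np.all(lower <= exact * (1 + 1e-9) + 1e-15), (n, k)


def test_tightness_at_profiling_scale():
    # n=10000, k=4: bounds stay within ~a factor 3 of exact for small rho
    spec = ProblemSpec(10000, 4)
    rhos = np.unique(np.round(np.exp(np.linspace(0, math.log(1e5), 60)))).astype(float)
    memo = {}
    from rpval import exact_pvalue

    exact = np.array([exact_pvalue(spec, r, memo=memo) for r in rhos])
    lower = BoundsEngine(spec, LOWER).pvalues(rhos)
    upper = BoundsEngine(spec, UPPER).pvalues(rhos)
    assert np.all(upper / exact <= 3.0)
    assert np.all(exact / lower <= 3.0)


@pytest.mark.parametrize("n,k", [(9047, 4), (10000, 10), (10000, 20)])
def test_double_precision_matches_50_digit_oracle(n, k):
    """Cancellation control: float evaluation vs an independent mpmath
    re-implementation of the recursion at 50 decimal digits."""
    spec = ProblemSpec(n, k)
    rng = np.random.default_rng(11)
    for _ in range(5):
        rho = float(np.exp(rng.uniform(0, k * math.log(n))))
        for flag in (LOWER, UPPER):
            p = BoundsEngine(spec, flag).pvalue(rho)
            p_hp = hp_bound_pvalue(n, k, repr(rho), flag)
            if p_hp > 0:
                assert p == pytest.approx(p_hp, rel=1e-9)
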