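"""Aggregator algebra: pooling identities, softmax behavior, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from wsip2p.aggregators import (
    AggregatorConfig,
    AttentionParams,
    attention_pool,
    attention_scores,
    ktop_pool,
    max_pool,
    mean_pool,
    raw_scores,
    score_max_pool,
    temperature_softmax,
    top_k_indices,
)

matrices = arrays(
    np.float64, st.tuples(st.integers(1, 12), st.integers(1, 6)),
    elements=st.floats(-50, 50, allow_nan=False),
)


def params_for(d: int, m: int = 4, seed: int = 0) -> AttentionParams:
    return AttentionParams.init(d, m, seed)


@pytest.mark.parametrize(
    "pool,rows,expected",
    [
        (mean_pool, [[1, 3], [3, 1]], [2, 2]),
        (mean_pool, [[5, -2, 0.5]], [5, -2, 0.5]),
        (max_pool, [[1, 3], [3, 1]], [3, 3]),
        (max_pool, [[5, -2, 0.5]], [5, -2, 0.5]),
    ],
)
def test_pool_examples(pool, rows, expected):
    assert np.allclose(pool(np.asarray(rows, float)).vector, expected)


@settings(deadline=None, max_examples=50)
@given(matrices)
def test_pools_match_column_oracles(F):
    assert np.allclose(mean_pool(F).vector, [np.mean(F[:, k]) for k in range(F.shape[1])])
    assert np.allclose(max_pool(F).vector, [np.max(F[:, k]) for k in range(F.shape[1])])


def test_empty_matrix_rejected():
    for fn in (mean_pool, max_pool):
        with pytest.raises(ValueError):
            fn(np.zeros((0, 3)))


def test_temperature_softmax_closed_forms():
    assert np.allclose(temperature_softmax(np.array([0.0, 0.0]), 3.7), [0.5, 0.5])
    assert np.allclose(
        temperature_softmax(np.array([np.log(2), 0.0]), 1.0), [2 / 3, 1 / 3]
    )
    p = temperature_softmax(np.array([1000.0, 0.0]), 1.0)
    assert np.isfinite(p).all() and p[0] > 0.999  # no overflow
    with pytest.raises(ValueError):
        temperature_softmax(np.array([1.0, 2.0]), 0.0)


def test_zero_scorer_gives_uniform_attention():
    F = np.random.default_rng(0).normal(size=(7, 5))
    p = AttentionParams(V=np.ones((3, 5)), w=np.zeros(3))
    assert np.allclose(attention_scores(F, p), np.full(7, 1 / 7))
    assert np.allclose(attention_pool(F, p).vector, F.mean(axis=0))


def test_huge_temperature_flattens_attention():
    F = np.random.default_rng(1).normal(size=(9, 4))
    p = params_for(4)
    alpha = attention_scores(F, p, tau=1e6)
    assert np.abs(alpha - 1 / 9).max() < 1e-4


@settings(deadline=None, max_examples=40)
@given(matrices, st.integers(0, 5))
def test_attention_pool_matches_explicit_sum(F, seed):
    p = params_for(F.shape[1], seed=seed)
    rep = attention_pool(F, p)
    alpha = rep.attention_weights
    assert abs(alpha.sum() - 1.0) < 1e-9 and (alpha >= 0).all()
    assert np.allclose(rep.vector, sum(a * f for a, f in zip(alpha, F)))


def test_identical_instances_attention_is_uniform():
    F = np.tile([2.0, -1.0, 0.5], (6, 1))
    rep = attention_pool(F, params_for(3))
    assert np.allclose(rep.attention_weights, 1 / 6)
    assert np.allclose(rep.vector, F[0])


@settings(deadline=None, max_examples=40)
@given(matrices, st.integers(0, 5))
def test_ktop_reduction_identities(F, seed):
    """K = n reduces K-TOP to mean (uniform) / attention (renormalized)."""
    n = F.shape[0]
    p = params_for(F.shape[1], seed=seed)
    assert np.allclose(
        ktop_pool(F, p, k=n, weighting="uniform").vector, mean_pool(F).vector,
        atol=1e-6,
    )
    assert np.allclose(
        ktop_pool(F, p, k=n, weighting="renormalized").vector,
        attention_pool(F, p).vector, atol=1e-6,
    )


def test_ktop_k1_selects_best_instance():
    F = np.random.default_rng(3).normal(size=(8, 4))
    p = params_for(4, seed=3)
    s = raw_scores(F, p)
    rep = ktop_pool(F, p, k=1)
    assert rep.selected_indices[0] == int(np.argmax(s))
    assert np.allclose(rep.vector, F[np.argmax(s)])


def test_ktop_tie_break_prefers_lower_index():
    assert list(top_k_indices(np.array([1.0, 5.0, 5.0, 5.0]), 2)) == [1, 2]
    assert list(top_k_indices(np.zeros(4), 3)) == [0, 1, 2]


def test_ktop_k_out_of_range_message():
    F = np.zeros((3, 2))
    with pytest.raises(ValueError, match="K=7.*n=3"):
        ktop_pool(F, params_for(2), k=7)


@settings(deadline=None, max_examples=30)
@given(matrices, st.integers(0, 5), st.data())
def test_permutation_invariance(F, seed, data):
    """Pooled outputs do not depend on instance order (no-tie case for K-TOP)."""
    p = params_for(F.shape[1], seed=seed)
    s = raw_scores(F, p)
    perm = data.draw(st.permutations(range(F.shape[0])))
    Fp = F[list(perm)]
    assert np.allclose(mean_pool(F).vector, mean_pool(Fp).vector, atol=1e-8)
    assert np.allclose(max_pool(F).vector, max_pool(Fp).vector, atol=1e-8)
    assert np.allclose(attention_pool(F, p).vector, attention_pool(Fp, p).vector,
                       atol=1e-8)
    if len(np.unique(s)) == len(s):  # ties are order-dependent by contract
        k = max(1, F.shape[0] // 2)
        assert np.allclose(ktop_pool(F, p, k=k).vector,
                           ktop_pool(Fp, p, k=k).vector, atol=1e-8)


def test_score_max_pool_examples_and_oracle():
    assert np.allclose(score_max_pool([[1.5, -2.0, 0.0]]), [1.5, -2.0, 0.0])
    assert np.allclose(score_max_pool([[5, 0], [0, 5]]), [5, 5])
    L = np.random.default_rng(4).normal(size=(10, 5))
    assert np.allclose(score_max_pool(L), [L[:, c].max() for c in range(5)])
    with pytest.raises(ValueError):
        score_max_pool(np.zeros((0, 5)))


@settings(deadline=None, max_examples=40)
@given(
    arrays(np.float64, st.integers(2, 8), elements=st.floats(-20, 20, allow_nan=False)),
    st.floats(0.05, 50), st.floats(0.05, 50),
)
def test_entropy_nondecreasing_in_temperature(z, t1, t2):
    lo, hi = min(t1, t2), max(t1, t2)

    def entropy(tau):
        p = temperature_softmax(z, tau)
        return float(-(p * np.log(np.clip(p, 1e-300, None))).sum())

    assert entropy(hi) >= entropy(lo) - 1e-9


def test_ktop_renormalized_scorer_on_gradient_path():
    """Finite differences: perturbing the scorer changes the K<n output."""
    rng = np.random.default_rng(5)
    F = rng.normal(size=(10, 4))
    p = params_for(4, seed=5)
    base = ktop_pool(F, p, k=3).vector
    bumped = AttentionParams(V=p.V, w=p.w + 1e-3 * rng.normal(size=p.w.shape),
                             c=p.c, b=p.b)
    assert not np.allclose(ktop_pool(F, bumped, k=3).vector, base, atol=1e-12)


def test_aggregator_config_validation():
    with pytest.raises(ValueError):
        AggregatorConfig(kind="median")
    with pytest.raises(ValueError):
        AggregatorConfig(temperature=0)
    with pytest.raises(ValueError):
        AggregatorConfig(ktop_weighting="softmax2")
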