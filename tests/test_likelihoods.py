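"""Collapsed component likelihoods: closed forms, oracles, invariants."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mdifuse.data import DatasetView
from mdifuse.likelihoods import (BagOfWordsModel, GaussianProcessModel,
                                 MultinomialModel, _se_kernel,
                                 bag_of_words_log_marginal, gp_log_marginal,
                                 multinomial_log_marginal)


# ---------------------------------------------------------------------------
# closed-form examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("items, pseudo, expected", [
    ([[0]], [(1.0, 1.0)], math.log(0.5)),          # symmetric prior -> 1/2
    ([[0], [0]], [(1.0, 1.0)], math.log(1 / 3)),   # rule of succession 1/2*2/3
    ([], [(1.0, 1.0)], 0.0),                       # empty product
])
def test_multinomial_marginal_examples(items, pseudo, expected):
    items = np.asarray(items, dtype=int).reshape(-1, 1)
    got = multinomial_log_marginal(items, [np.array(p) for p in pseudo])
    assert got == pytest.approx(expected, abs=1e-12)


def test_bag_of_words_marginal_examples():
    # one item with counts (2,0) under Dirichlet(1,1): integral of theta^2 = 1/3
    assert bag_of_words_log_marginal([[2, 0]], [1.0, 1.0]) == pytest.approx(
        math.log(1 / 3), abs=1e-12)
    assert bag_of_words_log_marginal(np.empty((0, 2), int), [1.0, 1.0]) == 0.0


def test_gp_marginal_examples():
    # single observation, unit signal kernel, zero noise: standard normal
    assert gp_log_marginal([[0.0]], [0.0], 1.0, 1.0, 0.0) == pytest.approx(
        -0.5 * math.log(2 * math.pi), abs=1e-9)
    assert gp_log_marginal(np.empty((0, 3)), [0.0, 1.0, 2.0], 1.0, 1.0, 0.1) == 0.0


def test_gp_shared_function_coupling():
    # two identical profiles are far more probable than profile + negation
    t = np.linspace(0, 5, 6)
    y = np.sin(t)
    same = gp_log_marginal([y, y], t, 1.0, 2.0, 1e-6)
    flipped = gp_log_marginal([y, -y], t, 1.0, 2.0, 1e-6)
    assert same > flipped + 100


def test_unknown_category_rejected():
    with pytest.raises(ValueError, match="feature 0"):
        multinomial_log_marginal([[5]], [np.array([1.0, 1.0])])
    with pytest.raises(ValueError, match="empty alphabet"):
        multinomial_log_marginal([[0]], [np.array([])])
    with pytest.raises(ValueError, match="negative"):
        bag_of_words_log_marginal([[-1, 2]], [1.0, 1.0])


# ---------------------------------------------------------------------------
# enumeration oracles: marginals are proper ordered-outcome probabilities
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("m, p, A", [(1, 1, 2), (2, 1, 3), (3, 2, 2), (2, 2, 3)])
def test_multinomial_normalizes_over_all_outcomes(m, p, A, rng):
    """Sum of exp(log_marginal) over all A^(m*p) ordered item sets is 1.

    With the multinomial coefficient omitted, the marginal is the
    probability of one specific ordered sequence of items, so the
    exhaustive sum over outcome assignments must be exactly 1.
    """
    pseudo = [rng.gamma(2.0, 1.0, size=A) + 0.1 for _ in range(p)]
    total = 0.0
    for combo in itertools.product(range(A), repeat=m * p):
        items = np.array(combo).reshape(m, p)
        total += math.exp(multinomial_log_marginal(items, pseudo))
    assert total == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("n_draws, V", [(2, 2), (3, 2), (2, 3)])
def test_bag_of_words_normalizes_over_sequences(n_draws, V, rng):
    """Enumerating ordered word sequences of one pooled document sums to 1."""
    pseudo = rng.gamma(2.0, 1.0, size=V) + 0.1
    total = 0.0
    for seq in itertools.product(range(V), repeat=n_draws):
        counts = np.bincount(seq, minlength=V)[None, :]
        total += math.exp(bag_of_words_log_marginal(counts, pseudo))
    assert total == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("m", [1, 2, 3, 4])
def test_gp_marginal_matches_dense_gaussian(m, rng):
    """Eigenbasis evaluation equals the explicitly assembled mT-dim Gaussian."""
    t = np.array([0.0, 1.0, 2.5, 4.0, 5.0])
    Y = rng.standard_normal((m, t.size))
    sf2, ell, sn2 = 1.3, 2.0, 0.4
    got = gp_log_marginal(Y, t, sf2, ell, sn2)
    K = _se_kernel(t, sf2, ell)
    cov = np.kron(np.ones((m, m)), K) + sn2 * np.eye(m * t.size)
    want = multivariate_normal(mean=np.zeros(m * t.size), cov=cov).logpdf(
        Y.reshape(-1))
    assert got == pytest.approx(want, abs=1e-8)


# ---------------------------------------------------------------------------
# class contracts: stats, predictives, telescoping, permutation invariance
# ---------------------------------------------------------------------------

def _models(rng, n=8):
    t = np.linspace(0, 10, 5)
    views = [
        DatasetView("cat", "categorical", rng.integers(0, 3, (n, 3)),
                    [f"g{i}" for i in range(n)],
                    alphabets=[np.arange(3)] * 3),
        DatasetView("bow", "bag_of_words", rng.poisson(2.0, (n, 6)),
                    [f"g{i}" for i in range(n)]),
        DatasetView("tc", "timecourse", rng.standard_normal((n, 5)),
                    [f"g{i}" for i in range(n)], time=t),
    ]
    return [MultinomialModel(views[0]), BagOfWordsModel(views[1]),
            GaussianProcessModel(views[2], standardize=False)]


def test_add_remove_restores_stats(rng):
    for model in _models(rng):
        st = model.new_stats(3)
        for i in range(6):
            model.add(st, i % 3, i)
        before = {k: np.array(getattr(st, k), dtype=float)
                  for k in ("m", "counts", "S", "q", "tot")
                  if getattr(st, k, None) is not None}
        model.add(st, 1, 6)
        model.remove(st, 1, 6)
        for k, v in before.items():
            assert np.allclose(np.asarray(getattr(st, k), dtype=float), v,
                               atol=1e-10)


def test_empty_component_marginal_is_zero(rng):
    for model in _models(rng):
        st = model.new_stats(2)
        assert model.component_log_marginal(st, 0) == pytest.approx(0.0, abs=1e-12)
        assert model.log_marginal_items([]) == 0.0


def test_predictive_chain_rule_telescopes(rng):
    """Sum of predictives along any insertion order equals the set marginal."""
    for model in _models(rng):
        for _ in range(5):
            order = rng.permutation(8)[:6]
            st = model.new_stats(2)
            total = 0.0
            for i in order:
                total += float(model.log_predictive_all(st, int(i))[0])
                model.add(st, 0, int(i))
            want = model.log_marginal_items(list(order))
            assert total == pytest.approx(want, abs=1e-8)
            assert model.component_log_marginal(st, 0) == pytest.approx(
                want, abs=1e-8)


def test_predictive_matches_difference_of_marginals(rng):
    """Incremental predictives vs the from-scratch marginal difference."""
    for model in _models(rng):
        for _ in range(30):
            size = int(rng.integers(0, 6))
            subset = [int(x) for x in rng.choice(7, size=size, replace=False)]
            query = 7
            st = model.new_stats(1)
            for i in subset:
                model.add(st, 0, i)
            got = float(model.log_predictive_all(st, query)[0])
            want = (model.log_marginal_items(subset + [query])
                    - model.log_marginal_items(subset))
            assert got == pytest.approx(want, abs=1e-8)


def test_marginal_invariant_under_item_order(rng):
    for model in _models(rng):
        idx = [0, 2, 5, 6]
        base = model.log_marginal_items(idx)
        for _ in range(4):
            perm = [idx[j] for j in rng.permutation(len(idx))]
            assert model.log_marginal_items(perm) == pytest.approx(base, abs=1e-10)


def test_multinomial_rule_of_succession_predictive():
    view = DatasetView("d", "categorical", np.array([[0], [0]]),
                       ["a", "b"], alphabets=[np.arange(2)])
    model = MultinomialModel(view, pseudo_count=1.0)
    st = model.new_stats(1)
    model.add(st, 0, 0)   # one item of category A observed
    assert float(model.log_predictive_all(st, 1)[0]) == pytest.approx(
        math.log(2 / 3), abs=1e-12)


def test_gp_hyper_update_leaves_stats_consistent(rng):
    model = _models(rng)[2]
    st = model.new_stats(2)
    for i in range(8):
        model.add(st, i % 2, i)
    accepted = 0
    for _ in range(50):
        accepted += model.update_hypers(st, rng)
    # rotated stats must still match a from-scratch rebuild
    fresh = model.new_stats(2)
    for i in range(8):
        model.add(fresh, i % 2, i)
    assert np.allclose(st.S, fresh.S, atol=1e-8)
    assert model.component_log_marginal(st, 0) == pytest.approx(
        model.log_marginal_items([0, 2, 4, 6]), abs=1e-8)
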