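import numpy as np
import pytest

from mdifuse.data import DatasetView
from mdifuse.likelihoods import ComponentModel


class FlatModel(ComponentModel):
    """Likelihood that is constant in the allocations (prior-only sampling)."""

    def __init__(self, n_items, n_components):
        self.n_items = n_items
        self._n = n_components

    def new_stats(self, n_components):
        class S:
            n = n_components
        return S()

    def add(self, stats, c, i):
        pass

    def remove(self, stats, c, i):
        pass

    def log_predictive_all(self, stats, i):
        return np.zeros(self._n)

    def component_log_marginal(self, stats, c):
        return 0.0

    def log_marginal_items(self, indices):
        return 0.0

    def swap_components(self, stats, c1, c2):
        pass


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_categorical_views(n, K, rng, n_features=1, n_categories=2, labels=None,
                           concentration=None):
    """K categorical views; near-deterministic per cluster when labels given."""
    views = []
    X_all = []
    for k in range(K):
        if labels is None:
            X = rng.integers(0, n_categories, size=(n, n_features))
        else:
            n_cl = int(np.max(labels)) + 1
            conc = 0.05 if concentration is None else concentration
            theta = rng.dirichlet(np.full(n_categories, conc), size=(n_cl, n_features))
            X = np.empty((n, n_features), dtype=np.int64)
            for j in range(n_features):
                for cl in range(n_cl):
                    rows = np.asarray(labels) == cl
                    X[rows, j] = rng.choice(n_categories, size=rows.sum(),
                                            p=theta[cl, j])
        X_all.append(X)
        views.append(DatasetView(
            name=f"d{k}", data_type="categorical", matrix=X,
            gene_ids=[f"g{i:03d}" for i in range(n)],
            alphabets=[np.arange(n_categories)] * n_features))
    return views


def all_partitions(items):
    """Every partition of a list, as lists of blocks (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_to_labels(part, items):
    pos = {it: j for j, block in enumerate(part) for it in block}
    return np.array([pos[it] for it in items])
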