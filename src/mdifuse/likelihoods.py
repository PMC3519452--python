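"""Conjugate / marginalizable component likelihoods.

Each dataset is modelled by an N-component mixture whose component
parameters are never represented explicitly: the three families here expose
the *marginal* likelihood of the set of items currently allocated to a
component, and the posterior-predictive density of one item given that set.
This is what allows fully collapsed allocation updates in the Gibbs
sampler.

Families
--------
multinomial
    Independent per-feature Dirichlet-multinomial.  Each component holds a
    categorical distribution per feature with a symmetric-by-default
    Dirichlet prior (pseudo-counts).
bag of words
    One shared word distribution per component; the marginal is the
    Dirichlet-multinomial of the component's summed count vector.  The
    multinomial coefficient is omitted everywhere (items are distinguishable
    and the coefficient is constant with respect to the allocations, so it
    cancels in the sampler; absolute marginal values depend on this
    convention).
gaussian process
    All items in a component share one latent function drawn from a
    zero-mean GP with a squared-exponential kernel, observed with i.i.d.
    Gaussian noise.  The stacked m*T-dimensional Gaussian marginal is
    evaluated in the kernel eigenbasis, where it factorizes into T
    independent one-factor models; sufficient statistics per component are
    the item count, the per-direction sums and the total sum of squares, so
    add/remove/predict are all O(T).

Every family satisfies: ``log_marginal(empty) == 0`` and
``log_marginal(S + y) == log_marginal(S) + log_predictive(y | S)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import DatasetView

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# stand-alone marginals (also the reference contracts used by the classes)
# ---------------------------------------------------------------------------

def multinomial_log_marginal(items, pseudo_counts) -> float:
    """Dirichlet-multinomial log marginal of a set of categorical vectors.

    Parameters
    ----------
    items : array-like of shape (m, p)
        Category codes ``0..A_f-1`` per feature.  May be empty.
    pseudo_counts : sequence of 1-D arrays
        Per-feature Dirichlet pseudo-counts (length ``A_f`` each, > 0).

    The marginal is a product over independent features of
    ``B(beta + counts) / B(beta)`` written with gamma functions; the
    multinomial coefficient is omitted (see module docstring).
    """
    items = np.asarray(items, dtype=np.int64).reshape(-1, len(pseudo_counts))
    out = 0.0
    for j, beta in enumerate(pseudo_counts):
        beta = np.asarray(beta, dtype=float)
        if beta.size == 0:
            raise ValueError(f"empty alphabet for feature {j}")
        if np.any(beta <= 0):
            raise ValueError(f"non-positive pseudo-count for feature {j}")
        col = items[:, j]
        if col.size and (col.min() < 0 or col.max() >= beta.size):
            bad = col[(col < 0) | (col >= beta.size)][0]
            raise ValueError(f"category code {bad} outside alphabet of feature {j}")
        counts = np.bincount(col, minlength=beta.size).astype(float)
        out += (
            gammaln(beta.sum()) - gammaln(beta.sum() + counts.sum())
            + np.sum(gammaln(beta + counts) - gammaln(beta))
        )
    return float(out)


def bag_of_words_log_marginal(items, pseudo_counts) -> float:
    """Dirichlet-multinomial log marginal of pooled word counts.

    ``items`` is (m, V) non-negative integer counts; the component pools all
    items into one count vector drawn from a single word distribution with
    Dirichlet prior ``pseudo_counts``.  Multinomial coefficient omitted.
    """
    beta = np.asarray(pseudo_counts, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("pseudo-counts must be positive")
    items = np.asarray(items, dtype=np.int64).reshape(-1, beta.size)
    if items.size and items.min() < 0:
        raise ValueError("negative word counts")
    counts = items.sum(axis=0).astype(float)
    return float(
        gammaln(beta.sum()) - gammaln(beta.sum() + counts.sum())
        + np.sum(gammaln(beta + counts) - gammaln(beta))
    )


def _se_kernel(time: np.ndarray, signal_var: float, length_scale: float) -> np.ndarray:
    d = time[:, None] - time[None, :]
    return signal_var * np.exp(-0.5 * (d / length_scale) ** 2)


def gp_log_marginal(items, time, signal_var, length_scale, noise_var) -> float:
    """Log marginal of profiles sharing one latent GP function.

    The stacked covariance of m profiles on a common grid of T points is
    ``J_m (x) K + noise_var * I`` with ``K`` the squared-exponential kernel
    matrix and ``J_m`` the all-ones matrix; evaluated in the eigenbasis of
    ``K`` (see module docstring).  ``noise_var`` is floored at 1e-12.
    """
    time = np.asarray(time, dtype=float)
    items = np.asarray(items, dtype=float).reshape(-1, time.size)
    m = items.shape[0]
    if m == 0:
        return 0.0
    lam, U = _kernel_eig(time, signal_var, length_scale)
    sn2 = max(float(noise_var), 1e-12)
    z = items @ U                      # items in the eigenbasis
    S = z.sum(axis=0)
    q = float(np.sum(z * z))
    return _gp_component_logmarg(m, S, q, lam, sn2, time.size)


def _kernel_eig(time, signal_var, length_scale):
    K = _se_kernel(np.asarray(time, float), float(signal_var), float(length_scale))
    lam, U = np.linalg.eigh(K)
    if not np.all(np.isfinite(lam)):
        raise ValueError(
            "kernel eigendecomposition failed for "
            f"signal_var={signal_var}, length_scale={length_scale}"
        )
    return np.clip(lam, 0.0, None), U


def _gp_component_logmarg(m, S, q, lam, sn2, T) -> float:
    denom = sn2 + m * lam
    logdet = (m - 1) * T * math.log(sn2) + float(np.sum(np.log(denom)))
    quad = (q - float(np.sum(lam * S * S / denom))) / sn2
    return -0.5 * (m * T * _LOG2PI + logdet + quad)


# ---------------------------------------------------------------------------
# component-model classes used by the sampler
# ---------------------------------------------------------------------------

class ComponentModel:
    """Interface shared by all collapsed likelihood families.

    A model instance is bound to one dataset's (preprocessed) observations.
    Sufficient statistics for the N components live in a separate ``stats``
    object so the sampler can snapshot/rebuild them cheaply.
    """

    has_hyper_updates = False

    def new_stats(self, n_components: int):
        raise NotImplementedError

    def add(self, stats, c: int, i: int) -> None:
        raise NotImplementedError

    def remove(self, stats, c: int, i: int) -> None:
        raise NotImplementedError

    def log_predictive_all(self, stats, i: int) -> np.ndarray:
        """log p(item i | items in component c), as a length-N vector."""
        raise NotImplementedError

    def component_log_marginal(self, stats, c: int) -> float:
        raise NotImplementedError

    def log_marginal_items(self, indices) -> float:
        """From-scratch marginal of an arbitrary item set (testing contract)."""
        raise NotImplementedError

    def swap_components(self, stats, c1: int, c2: int) -> None:
        raise NotImplementedError

    def total_log_marginal(self, stats) -> float:
        return float(sum(self.component_log_marginal(stats, c) for c in range(stats.n)))

    def update_hypers(self, stats, rng) -> bool:
        """Metropolis move on likelihood hyperparameters; returns acceptance."""
        return False

    def hyper_state(self) -> dict:
        return {}


@dataclass
class _DiscreteStats:
    n: int
    counts: np.ndarray   # (N, p, A_max) category counts, or (N, V) word counts
    m: np.ndarray        # (N,) item counts
    tot: np.ndarray | None = None  # (N,) total word counts (bag of words)


class MultinomialModel(ComponentModel):
    """Independent per-feature Dirichlet-multinomial components."""

    def __init__(self, view: DatasetView, pseudo_count: float = 0.5):
        if view.data_type != "categorical":
            raise ValueError("MultinomialModel requires a categorical view")
        self.view = view
        self.codes = view.codes
        self.arity = np.array([len(a) for a in view.alphabets])
        p, amax = self.codes.shape[1], int(self.arity.max())
        # padded (p, A_max) pseudo-count table; pad entries are never indexed
        self.beta = np.zeros((p, amax))
        for j, a in enumerate(self.arity):
            self.beta[j, :a] = pseudo_count
        self.beta_tot = self.beta.sum(axis=1)          # (p,)
        self._cols = np.arange(p)

    def new_stats(self, n_components: int) -> _DiscreteStats:
        p, amax = self.beta.shape
        return _DiscreteStats(
            n=n_components,
            counts=np.zeros((n_components, p, amax), dtype=np.int64),
            m=np.zeros(n_components, dtype=np.int64),
        )

    def add(self, stats, c, i):
        stats.counts[c, self._cols, self.codes[i]] += 1
        stats.m[c] += 1

    def remove(self, stats, c, i):
        stats.counts[c, self._cols, self.codes[i]] -= 1
        stats.m[c] -= 1

    def log_predictive_all(self, stats, i):
        x = self.codes[i]
        num = self.beta[self._cols, x][None, :] + stats.counts[:, self._cols, x]
        den = self.beta_tot[None, :] + stats.m[:, None]
        return np.sum(np.log(num) - np.log(den), axis=1)

    def component_log_marginal(self, stats, c):
        out = 0.0
        for j, a in enumerate(self.arity):
            beta = self.beta[j, :a]
            cnt = stats.counts[c, j, :a].astype(float)
            out += (
                gammaln(self.beta_tot[j]) - gammaln(self.beta_tot[j] + cnt.sum())
                + np.sum(gammaln(beta + cnt) - gammaln(beta))
            )
        return float(out)

    def log_marginal_items(self, indices):
        pcs = [self.beta[j, :a] for j, a in enumerate(self.arity)]
        return multinomial_log_marginal(self.codes[list(indices)], pcs)

    def swap_components(self, stats, c1, c2):
        stats.counts[[c1, c2]] = stats.counts[[c2, c1]]
        stats.m[[c1, c2]] = stats.m[[c2, c1]]


class BagOfWordsModel(ComponentModel):
    """Single shared word distribution per component, counts pooled."""

    def __init__(self, view: DatasetView, pseudo_count: float = 0.5):
        if view.data_type != "bag_of_words":
            raise ValueError("BagOfWordsModel requires a bag_of_words view")
        self.view = view
        self.X = view.matrix.astype(np.int64)
        self.beta = np.full(self.X.shape[1], float(pseudo_count))
        self.beta_tot = float(self.beta.sum())
        self.item_tot = self.X.sum(axis=1)
        # nonzero support per item, for sparse predictive updates
        self._nz = [np.nonzero(self.X[i])[0] for i in range(self.X.shape[0])]

    def new_stats(self, n_components):
        return _DiscreteStats(
            n=n_components,
            counts=np.zeros((n_components, self.X.shape[1]), dtype=np.int64),
            m=np.zeros(n_components, dtype=np.int64),
            tot=np.zeros(n_components, dtype=np.int64),
        )

    def add(self, stats, c, i):
        stats.counts[c] += self.X[i]
        stats.tot[c] += self.item_tot[i]
        stats.m[c] += 1

    def remove(self, stats, c, i):
        stats.counts[c] -= self.X[i]
        stats.tot[c] -= self.item_tot[i]
        stats.m[c] -= 1

    def log_predictive_all(self, stats, i):
        nz = self._nz[i]
        z = self.X[i, nz].astype(float)
        base = self.beta[nz][None, :] + stats.counts[:, nz]
        word_part = np.sum(gammaln(base + z[None, :]) - gammaln(base), axis=1)
        tot = self.beta_tot + stats.tot.astype(float)
        return word_part - (gammaln(tot + self.item_tot[i]) - gammaln(tot))

    def component_log_marginal(self, stats, c):
        cnt = stats.counts[c].astype(float)
        return float(
            gammaln(self.beta_tot) - gammaln(self.beta_tot + cnt.sum())
            + np.sum(gammaln(self.beta + cnt) - gammaln(self.beta))
        )

    def log_marginal_items(self, indices):
        return bag_of_words_log_marginal(self.X[list(indices)], self.beta)

    def swap_components(self, stats, c1, c2):
        stats.counts[[c1, c2]] = stats.counts[[c2, c1]]
        stats.m[[c1, c2]] = stats.m[[c2, c1]]
        stats.tot[[c1, c2]] = stats.tot[[c2, c1]]


@dataclass
class _GPStats:
    n: int
    m: np.ndarray   # (N,) item counts
    S: np.ndarray   # (N, T) per-eigendirection sums of transformed items
    q: np.ndarray   # (N,) total sum of squares (basis independent)


class GaussianProcessModel(ComponentModel):
    """Shared-function GP components for time-course data.

    Hyperparameters (signal variance, length-scale, noise variance) are
    shared across components within the dataset.  ``update_hypers`` performs
    a joint random-walk Metropolis step on their logs, with independent
    log-normal priors centred at the defaults; accepted moves rebuild the
    eigenbasis and rotate the sufficient statistics in place.
    """

    has_hyper_updates = True

    def __init__(self, view: DatasetView, signal_var: float | None = None,
                 length_scale: float | None = None, noise_var: float | None = None,
                 standardize: bool = True, step: float = 0.15):
        if view.data_type != "timecourse":
            raise ValueError("GaussianProcessModel requires a timecourse view")
        self.view = view
        self.time = view.time
        span = float(self.time[-1] - self.time[0]) if self.time.size > 1 else 1.0
        self.signal_var = 1.0 if signal_var is None else float(signal_var)
        self.length_scale = (span / 4.0 if span > 0 else 1.0) if length_scale is None else float(length_scale)
        self.noise_var = 0.25 if noise_var is None else float(noise_var)
        self.step = float(step)
        # log-normal prior locations = the defaults above
        self._prior_mu = np.log([self.signal_var if self.signal_var > 0 else 1.0,
                                 self.length_scale, max(self.noise_var, 1e-12)])
        self._prior_sd = np.array([1.0, 0.5, 1.0])

        Y = view.matrix.astype(float)
        if standardize:
            mu = Y.mean(axis=1, keepdims=True)
            sd = Y.std(axis=1, keepdims=True)
            sd[sd < 1e-12] = 1.0
            Y = (Y - mu) / sd
        self.Y = Y
        self._rebuild_basis()
        self.n_proposed = 0
        self.n_accepted = 0

    # -- basis management ---------------------------------------------------
    def _rebuild_basis(self):
        self.lam, self.U = _kernel_eig(self.time, self.signal_var, self.length_scale)
        self.Z = self.Y @ self.U
        self.qi = np.sum(self.Z * self.Z, axis=1)
        self.sn2 = max(self.noise_var, 1e-12)

    # -- stats --------------------------------------------------------------
    def new_stats(self, n_components):
        T = self.time.size
        return _GPStats(
            n=n_components,
            m=np.zeros(n_components, dtype=np.int64),
            S=np.zeros((n_components, T)),
            q=np.zeros(n_components),
        )

    def add(self, stats, c, i):
        stats.m[c] += 1
        stats.S[c] += self.Z[i]
        stats.q[c] += self.qi[i]

    def remove(self, stats, c, i):
        stats.m[c] -= 1
        stats.S[c] -= self.Z[i]
        stats.q[c] -= self.qi[i]

    def _logmarg_vec(self, m, S, q):
        """Vectorized component log marginals; zero for empty components."""
        T = self.time.size
        mf = m.astype(float)
        denom = self.sn2 + mf[:, None] * self.lam[None, :]
        logdet = (mf - 1.0) * T * math.log(self.sn2) + np.sum(np.log(denom), axis=1)
        quad = (q - np.sum(self.lam[None, :] * S * S / denom, axis=1)) / self.sn2
        out = -0.5 * (mf * T * _LOG2PI + logdet + quad)
        out[m == 0] = 0.0
        return out

    def log_predictive_all(self, stats, i):
        z, qy = self.Z[i], self.qi[i]
        cur = self._logmarg_vec(stats.m, stats.S, stats.q)
        new = self._logmarg_vec(stats.m + 1, stats.S + z[None, :], stats.q + qy)
        return new - cur

    def component_log_marginal(self, stats, c):
        return float(self._logmarg_vec(stats.m[c:c + 1], stats.S[c:c + 1], stats.q[c:c + 1])[0])

    def log_marginal_items(self, indices):
        idx = list(indices)
        if not idx:
            return 0.0
        m = len(idx)
        S = self.Z[idx].sum(axis=0)
        q = float(self.qi[idx].sum())
        return _gp_component_logmarg(m, S, q, self.lam, self.sn2, self.time.size)

    def swap_components(self, stats, c1, c2):
        stats.m[[c1, c2]] = stats.m[[c2, c1]]
        stats.S[[c1, c2]] = stats.S[[c2, c1]]
        stats.q[[c1, c2]] = stats.q[[c2, c1]]

    # -- hyperparameter Metropolis ------------------------------------------
    def _log_prior(self, logh):
        return float(np.sum(-0.5 * ((logh - self._prior_mu) / self._prior_sd) ** 2))

    def update_hypers(self, stats, rng) -> bool:
        self.n_proposed += 1
        logh = np.log([self.signal_var, self.length_scale, self.sn2])
        cur = float(np.sum(self._logmarg_vec(stats.m, stats.S, stats.q))) + self._log_prior(logh)

        logh_new = logh + self.step * rng.standard_normal(3)
        sf2, ell, sn2 = np.exp(logh_new)
        try:
            lam_new, U_new = _kernel_eig(self.time, sf2, ell)
        except ValueError:
            return False
        # rotate stats into the proposed basis: S' = (S U_old^T) U_new
        S_new = (stats.S @ self.U.T) @ U_new
        denom = sn2 + stats.m.astype(float)[:, None] * lam_new[None, :]
        T = self.time.size
        mf = stats.m.astype(float)
        logdet = (mf - 1.0) * T * math.log(sn2) + np.sum(np.log(denom), axis=1)
        quad = (stats.q - np.sum(lam_new[None, :] * S_new * S_new / denom, axis=1)) / sn2
        lm = -0.5 * (mf * T * _LOG2PI + logdet + quad)
        lm[stats.m == 0] = 0.0
        prop = float(np.sum(lm)) + self._log_prior(logh_new)

        if math.log(rng.random()) < prop - cur:
            self.signal_var, self.length_scale, self.noise_var = float(sf2), float(ell), float(sn2)
            self._rebuild_basis()
            stats.S[:] = S_new
            self.n_accepted += 1
            return True
        return False

    def hyper_state(self):
        return {
            "signal_var": self.signal_var,
            "length_scale": self.length_scale,
            "noise_var": self.noise_var,
        }


def component_model_for(view: DatasetView, pseudo_count: float = 0.5,
                        gp_kwargs: dict | None = None) -> ComponentModel:
    """Build the matching collapsed likelihood for a dataset view."""
    if view.data_type == "timecourse":
        return GaussianProcessModel(view, **(gp_kwargs or {}))
    if view.data_type == "categorical":
        return MultinomialModel(view, pseudo_count=pseudo_count)
    return BagOfWordsModel(view, pseudo_count=pseudo_count)
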