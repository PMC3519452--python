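"""Gibbs sampler for the correlated-allocation mixture model.

Per sweep the chain updates, in order:

1. the auxiliary variable ``v ~ Gamma(n, Z)`` that linearizes the ``Z^-n``
   prior factor;
2. every allocation ``c_ik`` from its collapsed full conditional
   (remove-before-score, add-after-draw), genes in index order within each
   dataset;
3. every unnormalized weight ``gamma[c, k] ~ Gamma(alpha_k/N + n_ck,
   1 + v dZ/dgamma[c, k])`` — exact because Z is multilinear in each entry;
   derivatives are refreshed after every single draw;
4. every association parameter ``phi_kl``.  Its exact conditional is
   ``phi^(a-1) (1+phi)^rho exp(-(b + v dZ/dphi) phi)`` with ``rho`` the
   label-agreement count: a finite mixture of Gamma densities obtained by
   binomially expanding ``(1+phi)^rho``, sampled exactly in one shot;
5. each mass parameter ``alpha_k`` by slice sampling
   ``p(alpha | gamma_k) ∝ p(alpha) prod_c Gamma(gamma_ck; alpha/N, 1)``
   (the conditional of the unnormalized-weight parameterization the chain
   actually keeps);
6. a Metropolis step on each GP dataset's kernel hyperparameters;
7. one Metropolis component-label-swap proposal per dataset — exchanging
   two component labels (weights + allocations simultaneously) inside one
   dataset, accepted by the coupling ratio times ``exp(-v (Z' - Z))``.
   This leaves the posterior invariant and repairs poor initial label
   correspondence between datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln, logsumexp

from .core import (CouplingWorkspace, MDIState, agreement_count, edge_index,
                   phi_edges_to_matrix)
from .data import DatasetView, check_aligned
from .likelihoods import ComponentModel, component_model_for

logger = logging.getLogger(__name__)


@dataclass
class ChainConfig:
    """MCMC run settings and priors.

    ``prior_mass`` and ``prior_phi`` are (shape, rate) pairs of Gamma
    priors shared by all ``alpha_k`` and all ``phi_kl`` respectively.
    Defaults (2000 sweeps, 1000 burn-in, thin 5) are floor settings for
    library-scale problems.
    """

    n_iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 5
    seed: int | None = None
    prior_mass: tuple = (2.0, 4.0)
    prior_phi: tuple = (1.0, 0.2)
    update_phi: bool = True
    update_mass: bool = True
    update_hypers: bool = True
    swap_moves: bool = True
    randomized_order: bool = False
    # during burn-in only: every this many sweeps, relabel each dataset's
    # components to best match dataset 0 (Hungarian assignment on the
    # agreement contingency).  A deterministic initialization aid — the
    # burn-in state is arbitrary, so this does not touch the post-burn-in
    # kernel; 0 disables.
    burnin_realign_every: int = 50

    def __post_init__(self):
        if self.n_iterations <= 0 or self.thinning < 1:
            raise ValueError("n_iterations must be positive and thinning >= 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")

    @property
    def n_snapshots(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorSamples:
    """Thinned chain output.

    ``allocations`` is (S, n, K) integer; ``phi`` (S, E) in canonical edge
    order; ``mass`` (S, K); ``v`` (S,); ``hypers`` a list of per-snapshot
    per-dataset hyperparameter dicts; ``iterations`` the 1-based sweep index
    of each snapshot.
    """

    allocations: np.ndarray
    phi: np.ndarray
    mass: np.ndarray
    v: np.ndarray
    iterations: np.ndarray
    gene_ids: list
    dataset_names: list
    n_components: int
    hypers: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n_snapshots(self) -> int:
        return self.allocations.shape[0]

    @property
    def n_datasets(self) -> int:
        return self.allocations.shape[1 + 1]

    def phi_matrix_trace(self) -> np.ndarray:
        """(S, K, K) symmetric matrices with NaN diagonals."""
        K = self.allocations.shape[2]
        return np.stack([phi_edges_to_matrix(row, K) for row in self.phi])


def _slice_sample_positive(logf, x0, rng, width=0.5, max_steps=100):
    """Univariate slice sampler on (0, inf) with stepping-out.

    Returns ``x0`` unchanged (with a warning) if bracketing fails.
    """
    fx0 = logf(x0)
    if not np.isfinite(fx0):
        logger.warning("slice sampler started at a zero-density point; keeping value")
        return x0
    logy = fx0 + math.log(rng.random())
    left = x0 - width * rng.random()
    right = left + width
    steps = max_steps
    while left > 0 and logf(left) > logy and steps > 0:
        left -= width
        steps -= 1
    left = max(left, 1e-12)
    steps = max_steps
    while logf(right) > logy and steps > 0:
        right += width
        steps -= 1
    if steps == 0:
        logger.warning("slice bracket failure after %d expansions; keeping value", max_steps)
        return x0
    for _ in range(1000):
        x1 = left + (right - left) * rng.random()
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    logger.warning("slice shrinkage failure; keeping value")
    return x0


def sample_phi_conditional(rho, shape, rate, rng):
    """Exact draw from  p(phi) ∝ phi^(shape-1) (1+phi)^rho exp(-rate*phi).

    Binomial expansion of ``(1+phi)^rho`` gives a mixture of
    ``Gamma(shape+m, rate)`` components, m = 0..rho, with log weights
    ``log C(rho, m) + loggamma(shape+m) - (shape+m) log rate``.
    """
    if rate <= 0 or not np.isfinite(rate):
        raise FloatingPointError(f"non-positive/non-finite rate {rate} in phi update")
    m = np.arange(rho + 1)
    logw = (gammaln(rho + 1) - gammaln(m + 1) - gammaln(rho - m + 1)
            + gammaln(shape + m) - (shape + m) * math.log(rate))
    w = np.exp(logw - logsumexp(logw))
    mstar = rng.choice(rho + 1, p=w / w.sum())
    return rng.gamma(shape + mstar, 1.0 / rate)


def mass_log_conditional(alpha, gamma_col, prior):
    """Log density (up to a constant) of alpha_k given dataset k's weights."""
    if alpha <= 0:
        return -np.inf
    a0, b0 = prior
    N = gamma_col.size
    return ((a0 - 1.0) * math.log(alpha) - b0 * alpha
            + (alpha / N) * float(np.sum(np.log(gamma_col)))
            - N * gammaln(alpha / N))


class GibbsSampler:
    """Driver bound to a set of aligned views and their component models."""

    def __init__(self, views, n_components, config: ChainConfig | None = None,
                 models=None, pseudo_count=0.5, gp_kwargs=None):
        if len(views) >= 2:
            check_aligned(views)
        for v in views:
            if v.n_genes < 2:
                raise ValueError("need at least 2 genes")
        self.views = list(views)
        self.n = views[0].n_genes
        self.K = len(views)
        self.N = int(n_components)
        if self.N < 1:
            raise ValueError("n_components must be >= 1")
        self.config = config or ChainConfig()
        self.models = (list(models) if models is not None else
                       [component_model_for(v, pseudo_count=pseudo_count,
                                            gp_kwargs=gp_kwargs) for v in views])
        self.edges = edge_index(self.K)

    # -- initialization -----------------------------------------------------
    def _features_for_init(self, k):
        v = self.views[k]
        if v.data_type == "timecourse":
            Y = v.matrix.astype(float)
            mu, sd = Y.mean(1, keepdims=True), Y.std(1, keepdims=True)
            sd[sd < 1e-12] = 1.0
            return (Y - mu) / sd
        if v.data_type == "categorical":
            cols = []
            for j, a in enumerate(v.alphabets):
                onehot = np.zeros((v.n_genes, len(a)))
                onehot[np.arange(v.n_genes), v.codes[:, j]] = 1.0
                cols.append(onehot)
            return np.hstack(cols)
        X = v.matrix.astype(float)
        tot = X.sum(1, keepdims=True)
        tot[tot == 0] = 1.0
        return X / tot

    def _init_allocations(self, rng):
        """Greedy k-means seeding per dataset, labels aligned to dataset 0."""
        from sklearn.cluster import KMeans

        k_init = min(8, self.N, self.n)
        alloc = np.zeros((self.n, self.K), dtype=np.int64)
        for k in range(self.K):
            feats = self._features_for_init(k)
            km = KMeans(n_clusters=k_init, n_init=4,
                        random_state=int(rng.integers(2 ** 31)))
            alloc[:, k] = km.fit_predict(feats)
        if self.K > 1:
            self._align_columns(alloc, lambda child, perm: None)
        return alloc

    def _align_columns(self, alloc, apply_relabel) -> None:
        """Make the component labels correspond across datasets.

        Datasets are visited along the maximum matched-overlap spanning tree
        rooted at dataset 0, and each is Hungarian-matched to its (already
        aligned) parent.  Matching everything directly to dataset 0 fails
        whenever the direct agreement between distant datasets is near
        chance: the correspondence is then only identifiable transitively
        through high-agreement intermediates, which the tree walks.
        ``apply_relabel(child, perm)`` performs any side effects of
        relabeling dataset ``child`` (weights, statistics); ``alloc`` is
        mutated in place.
        """
        N, K = self.N, self.K

        def contingency(a, b):
            cont = np.zeros((N, N))
            np.add.at(cont, (a, b), 1.0)
            return cont

        def matched_overlap(a, b):
            cont = contingency(a, b)
            rows, cols = linear_sum_assignment(-cont)
            return cont[rows, cols].sum()

        W = np.zeros((K, K))
        for k in range(K):
            for l in range(k + 1, K):
                W[k, l] = W[l, k] = matched_overlap(alloc[:, k], alloc[:, l])
        in_tree = [0]
        remaining = set(range(1, K))
        while remaining:
            best = None
            for l in remaining:
                for k in in_tree:
                    if best is None or W[k, l] > W[best]:
                        best = (k, l)
            parent, child = best
            cont = contingency(alloc[:, child], alloc[:, parent])
            rows, cols = linear_sum_assignment(-cont)
            perm = np.empty(N, dtype=np.int64)
            perm[rows] = cols
            if not np.array_equal(perm, np.arange(N)):
                alloc[:, child] = perm[alloc[:, child]]
                apply_relabel(child, perm)
            in_tree.append(child)
            remaining.discard(child)

    def init_state(self, rng) -> MDIState:
        cfg = self.config
        alloc = self._init_allocations(rng)
        gamma = np.full((self.N, self.K), 1.0 / self.N)
        phi_mean = cfg.prior_phi[0] / cfg.prior_phi[1]
        phi = np.full(len(self.edges), phi_mean if cfg.update_phi else 0.0)
        mass = np.full(self.K, cfg.prior_mass[0] / cfg.prior_mass[1])
        ws = CouplingWorkspace(gamma, phi)
        v = self.n / ws.z()
        hypers = [m.hyper_state() for m in self.models]
        return MDIState(allocations=alloc, gamma=gamma, mass=mass,
                        phi_edges=phi, v=v, hypers=hypers)

    def _build_stats(self, state):
        return [self._build_stats_for(state, k) for k in range(self.K)]

    # -- individual updates -------------------------------------------------
    def update_v(self, state, ws, rng) -> float:
        z = ws.z()
        if not (np.isfinite(z) and z > 0):
            raise FloatingPointError(f"normalizing constant Z={z}")
        state.v = float(rng.gamma(self.n, 1.0 / z))
        return state.v

    def update_allocations(self, state, ws, stats, rng) -> None:
        alloc = state.allocations
        phi_m = phi_edges_to_matrix(ws.phi, self.K)
        log1p_phi = np.log1p(np.nan_to_num(phi_m, nan=0.0))
        for k in range(self.K):
            model = self.models[k]
            st = stats[k]
            log_gamma_k = np.log(ws.gamma[:, k])
            order = (rng.permutation(self.n) if self.config.randomized_order
                     else range(self.n))
            for i in order:
                c_old = int(alloc[i, k])
                model.remove(st, c_old, i)
                logw = log_gamma_k.copy()
                for l in range(self.K):
                    if l != k:
                        logw[alloc[i, l]] += log1p_phi[k, l]
                logw += model.log_predictive_all(st, i)
                logw -= logw.max()
                p = np.exp(logw)
                c_new = int(np.searchsorted(np.cumsum(p), rng.random() * p.sum()))
                c_new = min(c_new, self.N - 1)
                model.add(st, c_new, i)
                alloc[i, k] = c_new

    def update_weights(self, state, ws, rng) -> None:
        a_mass = state.mass
        for k in range(self.K):
            n_ck = np.bincount(state.allocations[:, k], minlength=self.N)
            for c in range(self.N):
                dz = ws.dz_dgamma(c, k)
                rate = 1.0 + state.v * dz
                if not (np.isfinite(rate) and rate > 0):
                    raise FloatingPointError(
                        f"invalid Gamma rate {rate} for gamma[{c},{k}] "
                        f"(v={state.v}, dZ={dz})")
                # floor far below anything that affects the posterior but
                # high enough that K-fold products of weights cannot
                # underflow to an exact zero Z
                val = max(rng.gamma(a_mass[k] / self.N + n_ck[c], 1.0 / rate), 1e-150)
                ws.set_gamma(c, k, val)
        state.gamma = ws.gamma.copy()

    def update_phi(self, state, ws, rng) -> None:
        a, b = self.config.prior_phi
        for e, (k, l) in enumerate(self.edges):
            rho = agreement_count(k, l, state.allocations)
            dz = ws.dz_dphi(e)
            rate = b + state.v * dz
            val = sample_phi_conditional(rho, a, rate, rng)
            ws.set_phi(e, val)
        state.phi_edges = ws.phi.copy()

    def update_mass(self, state, ws, rng) -> None:
        for k in range(self.K):
            gamma_col = ws.gamma[:, k]
            logf = lambda a: mass_log_conditional(a, gamma_col, self.config.prior_mass)
            state.mass[k] = _slice_sample_positive(logf, state.mass[k], rng)

    def update_hyperparameters(self, state, stats, rng) -> None:
        for k, model in enumerate(self.models):
            if model.has_hyper_updates:
                model.update_hypers(stats[k], rng)
                state.hypers[k] = model.hyper_state()

    def label_swap_move(self, state, ws, stats, rng, k=None,
                        datasets=None) -> bool:
        """Metropolis swap of two component labels inside a dataset subset.

        Exchanging labels c1 <-> c2 simultaneously in every dataset of T
        (weights and allocations together) leaves each dataset's likelihood
        and weight-prior contribution unchanged; only the coupling factors
        of pairs crossing the boundary of T, and Z, enter the acceptance
        ratio.  Subset proposals are what lets the chain repair a component
        correspondence that has drifted apart between two groups of
        datasets: the single-dataset move can be blocked when a dataset
        agrees with strong partners on both sides of the split.
        """
        if self.N < 2:
            return False
        if datasets is None:
            datasets = [int(rng.integers(self.K)) if k is None else int(k)]
        T = sorted(set(int(d) for d in datasets))
        if len(T) == self.K:
            # swapping in every dataset is a pure global relabeling
            T = T[:-1]
        if not T:
            return False
        c1, c2 = (int(x) for x in rng.choice(self.N, size=2, replace=False))
        alloc = state.allocations
        phi_m = phi_edges_to_matrix(ws.phi, self.K)
        inT = np.zeros(self.K, dtype=bool)
        inT[T] = True
        swapped_cols = {}
        log_ratio = 0.0
        for kk in T:
            in_c1 = alloc[:, kk] == c1
            in_c2 = alloc[:, kk] == c2
            col = alloc[:, kk].copy()
            col[in_c1] = c2
            col[in_c2] = c1
            swapped_cols[kk] = col
            affected = in_c1 | in_c2
            for l in range(self.K):
                if inT[l]:
                    continue  # pairs inside T keep their agreements
                old_agree = int(np.sum(alloc[affected, l] == alloc[affected, kk]))
                new_agree = int(np.sum(alloc[affected, l] == col[affected]))
                log_ratio += math.log1p(phi_m[kk, l]) * (new_agree - old_agree)
        z_old = ws.z()
        for kk in T:
            ws.swap_gamma(kk, c1, c2)
        z_new = ws.z()
        log_ratio += -state.v * (z_new - z_old)
        if math.log(rng.random()) < log_ratio:
            for kk in T:
                alloc[:, kk] = swapped_cols[kk]
                self.models[kk].swap_components(stats[kk], c1, c2)
            state.gamma = ws.gamma.copy()
            return True
        for kk in T:
            ws.swap_gamma(kk, c1, c2)  # undo
        return False

    def _propose_swaps(self, state, ws, stats, rng) -> None:
        """One single-dataset proposal per dataset plus K random-subset
        proposals per sweep."""
        for k in range(self.K):
            self.label_swap_move(state, ws, stats, rng, k=k)
        if self.K > 2:
            for _ in range(self.K):
                size = int(rng.integers(2, self.K))
                T = rng.choice(self.K, size=size, replace=False)
                self.label_swap_move(state, ws, stats, rng, datasets=T)

    def _realign_burnin(self, state, ws, stats) -> None:
        """Repair the cross-dataset component correspondence (burn-in only).

        Pure relabeling via :meth:`_align_columns` — allocations, weights
        and component statistics move together, so each dataset's likelihood
        is untouched.  Applied only inside burn-in, where the state is
        arbitrary; no snapshot is recorded before burn-in ends, so the
        recorded chain is untouched MCMC.
        """

        def apply_relabel(child, perm):
            new_col = np.empty(self.N)
            new_col[perm] = state.gamma[:, child]
            state.gamma[:, child] = new_col
            ws.set_gamma_column(child, new_col)
            stats[child] = self._build_stats_for(state, child)

        self._align_columns(state.allocations, apply_relabel)

    def _build_stats_for(self, state, k):
        st = self.models[k].new_stats(self.N)
        for i in range(self.n):
            self.models[k].add(st, int(state.allocations[i, k]), i)
        return st

    # -- driver -------------------------------------------------------------
    def run(self, rng=None, progress_every: int = 100) -> PosteriorSamples:
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        state = self.init_state(rng)
        stats = self._build_stats(state)
        ws = CouplingWorkspace(state.gamma, state.phi_edges)

        S = cfg.n_snapshots
        snap_alloc = np.zeros((S, self.n, self.K), dtype=np.int16)
        snap_phi = np.zeros((S, len(self.edges)))
        snap_mass = np.zeros((S, self.K))
        snap_v = np.zeros(S)
        snap_it = np.zeros(S, dtype=np.int64)
        snap_hypers = []
        s = 0
        for it in range(1, cfg.n_iterations + 1):
            try:
                self.update_v(state, ws, rng)
                self.update_allocations(state, ws, stats, rng)
                self.update_weights(state, ws, rng)
                if cfg.update_phi:
                    self.update_phi(state, ws, rng)
                if cfg.update_mass:
                    self.update_mass(state, ws, rng)
                if cfg.update_hypers:
                    self.update_hyperparameters(state, stats, rng)
                if cfg.swap_moves:
                    self._propose_swaps(state, ws, stats, rng)
                if (cfg.burnin_realign_every and self.K > 1
                        and it <= cfg.burn_in
                        and it % cfg.burnin_realign_every == 0):
                    self._realign_burnin(state, ws, stats)
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"sampler update failed at iteration {it}: {exc}; "
                    f"state: v={state.v}, phi={state.phi_edges}, "
                    f"mass={state.mass}") from exc
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0 and s < S:
                snap_alloc[s] = state.allocations
                snap_phi[s] = state.phi_edges
                snap_mass[s] = state.mass
                snap_v[s] = state.v
                snap_it[s] = it
                snap_hypers.append([dict(h) for h in state.hypers])
                s += 1
            if progress_every and it % progress_every == 0:
                logger.info("sweep %d/%d (occupied: %s)", it, cfg.n_iterations,
                            [int(np.unique(state.allocations[:, k]).size)
                             for k in range(self.K)])
        return PosteriorSamples(
            allocations=snap_alloc[:s], phi=snap_phi[:s], mass=snap_mass[:s],
            v=snap_v[:s], iterations=snap_it[:s],
            gene_ids=list(self.views[0].gene_ids),
            dataset_names=[v.name for v in self.views],
            n_components=self.N, hypers=snap_hypers, config=asdict(cfg))


def run_chain(views, config: ChainConfig | None = None, n_components=None,
              **kwargs) -> PosteriorSamples:
    """Convenience wrapper: build a sampler for the views and run it."""
    n = views[0].n_genes
    if n_components is None:
        n_components = min(50, math.ceil(n / 2))
    sampler = GibbsSampler(views, n_components, config=config, **kwargs)
    return sampler.run()
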