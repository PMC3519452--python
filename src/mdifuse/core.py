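"""The correlated-allocation prior and its normalizing constant.

Each gene carries one component label per dataset, ``c = (c_1..c_K)`` with
``c_k in 0..N-1``.  The (unnormalized) joint prior weight of a label row is

    w(c) = prod_k gamma[c_k, k] * prod_{k<l} (1 + phi_kl * [c_k == c_l])

where ``gamma[:, k]`` are the unnormalized component weights of dataset k
(their normalized version is the mixture proportion vector) and ``phi_kl >= 0``
up-weights label agreement between datasets k and l.  With all ``phi = 0``
the model reduces to K independent mixtures.

The per-gene normalizing constant ``Z = sum over N^K label rows of w(c)``
is evaluated by expanding the pairwise product over subsets of dataset
pairs: each subset S of pairs contributes ``prod_{e in S} phi_e`` times a
product, over the connected components of the graph (datasets, S), of
``sum_c prod_{k in block} gamma[c, k]``.  The combinatorics (edge subsets,
their induced partitions) depend only on K and are precomputed once; the
per-state evaluation is a handful of vectorized reductions.  Z is
multilinear in every ``gamma[c, k]`` and every ``phi_kl``, which is what
makes the Gamma full conditionals in the sampler exact; the workspace
exposes those partial derivatives.

K is capped at 6 (2^15 edge subsets); larger K is rejected rather than
approximated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

K_MAX = 6


# ---------------------------------------------------------------------------
# combinatorial tables, per K
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _tables(K: int):
    """Edge list, per-edge-subset induced partitions, and index tables.

    Returns an object with:
      edges          list of (k, l), k < l
      pid            (2^E,) partition id of each edge subset
      edge_member    (E, 2^E) bool, subset contains edge e
      part_blocks    (P, K) int, padded block bitmasks of each partition
                     (pad value 0; block-product of the empty set is 1)
      blockk         (P, K) int, bitmask of the block containing node k
      node_subsets   per node k: (subsets containing k, same minus k)
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > K_MAX:
        raise ValueError(
            f"K={K} exceeds the supported maximum {K_MAX}; the pair-subset "
            "expansion grows as 2^(K(K-1)/2). Fit fewer datasets jointly."
        )
    edges = [(k, l) for k in range(K) for l in range(k + 1, K)]
    E = len(edges)
    nsub = 1 << E

    part_index: dict = {}
    part_blocks_list = []
    pid = np.empty(nsub, dtype=np.int64)
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for S in range(nsub):
        for k in range(K):
            parent[k] = k
        for e in range(E):
            if S >> e & 1:
                a, b = find(edges[e][0]), find(edges[e][1])
                if a != b:
                    parent[a] = b
        blocks: dict = {}
        for k in range(K):
            blocks.setdefault(find(k), 0)
            blocks[find(k)] |= 1 << k
        key = tuple(sorted(blocks.values()))
        if key not in part_index:
            part_index[key] = len(part_blocks_list)
            part_blocks_list.append(key)
        pid[S] = part_index[key]

    P = len(part_blocks_list)
    part_blocks = np.zeros((P, K), dtype=np.int64)
    blockk = np.zeros((P, K), dtype=np.int64)
    for p, key in enumerate(part_blocks_list):
        for j, b in enumerate(key):
            part_blocks[p, j] = b
        for k in range(K):
            for b in key:
                if b >> k & 1:
                    blockk[p, k] = b

    subs = np.arange(nsub)
    edge_member = np.array([(subs >> e & 1).astype(bool) for e in range(E)])

    node_subsets = []
    allB = np.arange(1, 1 << K)
    for k in range(K):
        Bk = allB[(allB >> k & 1) == 1]
        node_subsets.append((Bk, Bk ^ (1 << k)))

    return _Tables(K, edges, pid, edge_member, part_blocks, blockk, node_subsets, P)


@dataclass(frozen=True)
class _Tables:
    K: int
    edges: list
    pid: np.ndarray
    edge_member: np.ndarray
    part_blocks: np.ndarray
    blockk: np.ndarray
    node_subsets: list
    n_partitions: int


# ---------------------------------------------------------------------------
# state-dependent workspace
# ---------------------------------------------------------------------------

class CouplingWorkspace:
    """Caches of the pair-subset expansion for one (gamma, phi) setting.

    Supports in-place single-entry updates of ``gamma`` and ``phi`` so that
    the sequential Gibbs draws can refresh derivatives after every draw at
    O(2^K) / O(2^E) cost instead of recomputing everything.
    """

    def __init__(self, gamma: np.ndarray, phi_edges: np.ndarray):
        gamma = np.asarray(gamma, dtype=float)
        self.N, self.K = gamma.shape
        self.t = _tables(self.K)
        if phi_edges is None:
            phi_edges = np.zeros(len(self.t.edges))
        self.gamma = gamma.copy()
        self.phi = np.asarray(phi_edges, dtype=float).copy()
        if self.phi.shape != (len(self.t.edges),):
            raise ValueError("phi_edges must have length K(K-1)/2")
        if np.any(self.gamma <= 0):
            raise ValueError("component weights must be positive")
        if np.any(self.phi < 0):
            raise ValueError("phi must be non-negative")
        self._rebuild_gamma()
        self._rebuild_phi()

    # -- full rebuilds ------------------------------------------------------
    def _rebuild_gamma(self):
        K, N = self.K, self.N
        self.gvec = np.empty((1 << K, N))
        self.gvec[0] = 1.0
        for B in range(1, 1 << K):
            k0 = (B & -B).bit_length() - 1
            self.gvec[B] = self.gamma[:, k0] * self.gvec[B ^ (1 << k0)]
        self.g = self.gvec.sum(axis=1)
        self.g[0] = 1.0
        self._refresh_gprod()

    def _refresh_gprod(self):
        self.gprod = np.prod(self.g[self.t.part_blocks], axis=1)

    def _rebuild_phi(self):
        E = len(self.t.edges)
        s = np.ones(1 << E)
        for e in range(E):
            s[self.t.edge_member[e]] *= self.phi[e]
        self.s = s
        self.A = np.bincount(self.t.pid, weights=s, minlength=self.t.n_partitions)

    # -- queries ------------------------------------------------------------
    def z(self) -> float:
        return float(self.A @ self.gprod)

    def dz_dgamma_col(self, k: int) -> np.ndarray:
        """Vector of dZ/dgamma[c, k] over components c."""
        w = self.A * self.gprod
        coeff = np.bincount(self.t.blockk[:, k], weights=w, minlength=1 << self.K)
        Bk, Bk_minus = self.t.node_subsets[k]
        return (coeff[Bk] / self.g[Bk]) @ self.gvec[Bk_minus]

    def dz_dgamma(self, c: int, k: int) -> float:
        w = self.A * self.gprod
        coeff = np.bincount(self.t.blockk[:, k], weights=w, minlength=1 << self.K)
        Bk, Bk_minus = self.t.node_subsets[k]
        return float((coeff[Bk] / self.g[Bk]) @ self.gvec[Bk_minus, c])

    def dz_dphi(self, e: int) -> float:
        mask = self.t.edge_member[e]
        if self.phi[e] > 1e-250:
            Ae = np.bincount(self.t.pid[mask], weights=self.s[mask],
                             minlength=self.t.n_partitions)
            return float(Ae @ self.gprod) / self.phi[e]
        t = np.ones(self.s.size)
        for e2 in range(len(self.phi)):
            if e2 != e:
                t[self.t.edge_member[e2]] *= self.phi[e2]
        Ae = np.bincount(self.t.pid[mask], weights=t[mask],
                         minlength=self.t.n_partitions)
        return float(Ae @ self.gprod)

    # -- in-place updates ---------------------------------------------------
    def set_gamma(self, c: int, k: int, value: float):
        if value <= 0:
            raise ValueError("component weights must be positive")
        self.gamma[c, k] = value
        Bk, Bk_minus = self.t.node_subsets[k]
        self.gvec[Bk, c] = value * self.gvec[Bk_minus, c]
        # re-sum rather than add a delta: entries span many orders of
        # magnitude and additive updates can cancel catastrophically
        self.g[Bk] = self.gvec[Bk].sum(axis=1)
        self._refresh_gprod()

    def set_gamma_column(self, k: int, values: np.ndarray):
        self.gamma[:, k] = values
        self._rebuild_gamma()

    def set_phi(self, e: int, value: float):
        if value < 0:
            raise ValueError("phi must be non-negative")
        old = self.phi[e]
        self.phi[e] = value
        if old > 1e-250:
            self.s[self.t.edge_member[e]] *= value / old
        else:
            self._rebuild_phi()
            return
        self.A = np.bincount(self.t.pid, weights=self.s,
                             minlength=self.t.n_partitions)

    def swap_gamma(self, k: int, c1: int, c2: int):
        g1, g2 = self.gamma[c1, k], self.gamma[c2, k]
        self.set_gamma(c1, k, g2)
        self.set_gamma(c2, k, g1)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def edge_index(K: int):
    """List of (k, l) dataset pairs in the canonical edge order."""
    return list(_tables(K).edges)


def phi_matrix_to_edges(phi: np.ndarray) -> np.ndarray:
    K = phi.shape[0]
    return np.array([phi[k, l] for k, l in edge_index(K)], dtype=float)


def phi_edges_to_matrix(phi_edges: np.ndarray, K: int) -> np.ndarray:
    out = np.full((K, K), np.nan)
    for e, (k, l) in enumerate(edge_index(K)):
        out[k, l] = out[l, k] = phi_edges[e]
    return out


def allocation_prior_weight(c_row, gamma, phi) -> float:
    """Unnormalized prior weight of one gene's label row (Z applied by callers).

    ``phi`` may be a symmetric (K, K) matrix or a flat edge vector.
    """
    gamma = np.asarray(gamma, dtype=float)
    N, K = gamma.shape
    c_row = np.asarray(c_row, dtype=int)
    if np.any(c_row < 0) or np.any(c_row >= N):
        raise ValueError(f"label out of range 0..{N - 1}: {c_row}")
    phi = np.asarray(phi, dtype=float)
    phi_e = phi_matrix_to_edges(phi) if phi.ndim == 2 else phi
    w = float(np.prod(gamma[c_row, np.arange(K)]))
    for e, (k, l) in enumerate(edge_index(K)):
        if c_row[k] == c_row[l]:
            w *= 1.0 + phi_e[e]
    return w


def normalizing_constant(gamma, phi) -> float:
    """Z = sum of allocation_prior_weight over all N^K label rows.

    Evaluated via the pair-subset expansion (see module docstring), never by
    brute force; K is capped at ``K_MAX``.
    """
    gamma = np.asarray(gamma, dtype=float)
    phi = np.asarray(phi, dtype=float)
    phi_e = phi_matrix_to_edges(phi) if phi.ndim == 2 else phi
    return CouplingWorkspace(gamma, phi_e).z()


def allocation_conditional(i: int, k: int, alloc: np.ndarray, gamma: np.ndarray,
                           phi: np.ndarray, log_pred: np.ndarray | None = None
                           ) -> np.ndarray:
    """Full-conditional probabilities of gene i's label in dataset k.

    ``alloc`` is the (n, K) allocation matrix (gene i's other columns supply
    the coupling terms); ``log_pred`` is the length-N vector of collapsed
    predictive log densities with gene i removed (flat likelihood if None).
    """
    gamma = np.asarray(gamma, dtype=float)
    N, K = gamma.shape
    phi = np.asarray(phi, dtype=float)
    phi_m = phi if phi.ndim == 2 else phi_edges_to_matrix(phi, K)
    w = gamma[:, k].astype(float).copy()
    for l in range(K):
        if l != k:
            w[alloc[i, l]] *= 1.0 + phi_m[k, l]
    logw = np.log(w)
    if log_pred is not None:
        logw = logw + np.asarray(log_pred, dtype=float)
    logw -= logw.max()
    p = np.exp(logw)
    return p / p.sum()


def agreement_count(k: int, l: int, alloc: np.ndarray) -> int:
    """Number of genes with identical labels in datasets k and l."""
    return int(np.sum(alloc[:, k] == alloc[:, l]))


def agreement_matrix(alloc: np.ndarray) -> np.ndarray:
    """(K, K) table of pairwise label-agreement counts (n on the diagonal)."""
    K = alloc.shape[1]
    out = np.zeros((K, K), dtype=int)
    for k in range(K):
        for l in range(K):
            out[k, l] = agreement_count(k, l, alloc)
    return out


# ---------------------------------------------------------------------------
# MCMC state container
# ---------------------------------------------------------------------------

@dataclass
class MDIState:
    """One state of the chain.

    ``allocations`` is (n, K) with labels in ``0..N-1``; ``gamma`` is (N, K)
    positive unnormalized weights; ``mass`` the K concentration parameters;
    ``phi_edges`` the flat vector of pairwise association parameters in
    canonical edge order; ``v`` the positive auxiliary variable standing in
    for the ``Z^-n`` prior factor; ``hypers`` per-dataset likelihood
    hyperparameter dictionaries.
    """

    allocations: np.ndarray
    gamma: np.ndarray
    mass: np.ndarray
    phi_edges: np.ndarray
    v: float
    hypers: list = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.allocations.shape[0]

    @property
    def n_datasets(self) -> int:
        return self.allocations.shape[1]

    @property
    def n_components(self) -> int:
        return self.gamma.shape[0]

    @property
    def phi(self) -> np.ndarray:
        """Symmetric (K, K) association matrix with NaN diagonal."""
        return phi_edges_to_matrix(self.phi_edges, self.n_datasets)

    def validate(self) -> None:
        n, K = self.allocations.shape
        N = self.gamma.shape[0]
        if self.gamma.shape != (N, K):
            raise ValueError("gamma must be (N, K)")
        if self.allocations.min() < 0 or self.allocations.max() >= N:
            raise ValueError("allocations out of range")
        if np.any(self.gamma <= 0):
            raise ValueError("gamma entries must be positive")
        if np.any(self.phi_edges < 0):
            raise ValueError("phi must be non-negative")
        if not self.v > 0:
            raise ValueError("v must be positive")
        if self.mass.shape != (K,) or np.any(self.mass <= 0):
            raise ValueError("mass parameters must be positive, one per dataset")
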