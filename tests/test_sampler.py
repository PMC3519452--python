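"""Full-conditional updates: closed forms, derivative oracles, mixing aids."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, kstest

from mdifuse.core import (CouplingWorkspace, MDIState, agreement_count,
                          allocation_prior_weight)
from mdifuse.sampler import (ChainConfig, GibbsSampler, mass_log_conditional,
                             run_chain, sample_phi_conditional,
                             _slice_sample_positive)
from mdifuse.simulate import SyntheticSpec, make_discrete_views

from .conftest import FlatModel, make_categorical_views


def brute_force_z(gamma, phi_edges):
    N, K = gamma.shape
    return sum(allocation_prior_weight(c, gamma, phi_edges)
               for c in itertools.product(range(N), repeat=K))


# ---------------------------------------------------------------------------
# v update
# ---------------------------------------------------------------------------

def test_update_v_empirical_mean(rng):
    views = make_categorical_views(12, 2, rng)
    smp = GibbsSampler(views, 3, ChainConfig(n_iterations=10, burn_in=0))
    state = smp.init_state(rng)
    ws = CouplingWorkspace(state.gamma, state.phi_edges)
    z = ws.z()
    draws = np.array([smp.update_v(state, ws, rng) for _ in range(100_000)])
    n = views[0].n_genes
    se = math.sqrt(n) / z / math.sqrt(draws.size)
    assert abs(draws.mean() - n / z) < 3 * se
    assert np.all(draws > 0)
    # doubling Z (scaling every weight by 2^(1/K)) halves the conditional mean
    ws2 = CouplingWorkspace(state.gamma * 2 ** (1 / 2), np.zeros_like(state.phi_edges))
    state.phi_edges = np.zeros_like(state.phi_edges)
    draws2 = np.array([smp.update_v(state, ws2, rng) for _ in range(50_000)])
    assert draws2.mean() == pytest.approx(n / ws2.z(), rel=0.03)
    assert ws2.z() == pytest.approx(
        2 * CouplingWorkspace(state.gamma, state.phi_edges).z(), rel=1e-9)


# ---------------------------------------------------------------------------
# weight update
# ---------------------------------------------------------------------------

def test_dz_dgamma_matches_finite_differences(rng):
    for _ in range(100):
        K = int(rng.integers(1, 5))
        N = int(rng.integers(1, 4))
        gamma = rng.gamma(1.0, 1.0, (N, K)) + 0.05
        phi = rng.gamma(1.0, 2.0, K * (K - 1) // 2)
        ws = CouplingWorkspace(gamma, phi)
        c, k = int(rng.integers(N)), int(rng.integers(K))
        eps = 1e-6
        g2 = gamma.copy()
        g2[c, k] += eps
        fd = (brute_force_z(g2, phi) - brute_force_z(gamma, phi)) / eps
        assert ws.dz_dgamma(c, k) == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_dz_dphi_matches_finite_differences(rng):
    for _ in range(50):
        K = int(rng.integers(2, 5))
        N = int(rng.integers(1, 4))
        gamma = rng.gamma(1.0, 1.0, (N, K)) + 0.05
        E = K * (K - 1) // 2
        phi = rng.gamma(1.0, 2.0, E)
        ws = CouplingWorkspace(gamma, phi)
        e = int(rng.integers(E))
        eps = 1e-6
        p2 = phi.copy()
        p2[e] += eps
        fd = (brute_force_z(gamma, p2) - brute_force_z(gamma, phi)) / eps
        assert ws.dz_dphi(e) == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_single_dataset_weight_rate_reduces_to_one_plus_v(rng):
    """With K=1, Z = sum(gamma) so dZ/dgamma = 1: the standard Dirichlet
    normalized-Gamma update with rate 1 + v."""
    gamma = rng.gamma(1.0, 1.0, (4, 1)) + 0.05
    ws = CouplingWorkspace(gamma, np.zeros(0))
    assert np.allclose(ws.dz_dgamma_col(0), 1.0)


def test_empty_components_keep_positive_weights(rng):
    views = make_categorical_views(6, 2, rng)
    smp = GibbsSampler(views, 5, ChainConfig(n_iterations=30, burn_in=10,
                                             thinning=1, seed=0))
    samples = smp.run()
    # N=5 with 6 genes leaves components empty most sweeps; weights stay legal
    assert samples.n_snapshots == 20


# ---------------------------------------------------------------------------
# phi update
# ---------------------------------------------------------------------------

def test_phi_conditional_is_prior_when_uncoupled(rng):
    """rho = 0 and v -> 0 collapse the conditional to the Gamma prior."""
    a, b = 1.3, 0.7
    draws = np.array([sample_phi_conditional(0, a, b + 1e-12, rng)
                      for _ in range(20_000)])
    ks = kstest(draws, gamma_dist(a, scale=1 / b).cdf)
    assert ks.statistic < 0.02


def test_phi_conditional_matches_numeric_density(rng):
    """Mixture-of-Gammas draw vs the numerically normalized target
    phi^(a-1) (1+phi)^rho exp(-rate*phi)."""
    a, rho, rate = 1.0, 5, 2.0
    draws = np.array([sample_phi_conditional(rho, a, rate, rng)
                      for _ in range(20_000)])
    grid = np.linspace(1e-9, 60, 60_001)
    dens = grid ** (a - 1) * (1 + grid) ** rho * np.exp(-rate * grid)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    ks = kstest(draws, lambda x: np.interp(x, grid, cdf))
    assert ks.statistic < 0.02


def test_identical_datasets_drive_phi_above_prior_mean(rng):
    labels = np.arange(30) % 3
    views = make_categorical_views(30, 2, rng, n_features=6, labels=labels)
    cfg = ChainConfig(n_iterations=300, burn_in=100, thinning=2, seed=1)
    samples = GibbsSampler(views, 5, cfg).run()
    prior_mean = cfg.prior_phi[0] / cfg.prior_phi[1]
    assert samples.phi.mean() > prior_mean


# ---------------------------------------------------------------------------
# mass update
# ---------------------------------------------------------------------------

def test_mass_conditional_matches_direct_oracle(rng):
    """Our log conditional vs independent evaluation as
    log prior + sum of Gamma(alpha/N, 1) log densities, up to a constant."""
    prior = (2.0, 4.0)
    for _ in range(20):
        N = int(rng.integers(2, 6))
        gcol = rng.gamma(1.0, 1.0, N) + 1e-3
        a1, a2 = rng.gamma(2.0, 0.5) + 0.05, rng.gamma(2.0, 0.5) + 0.05

        def oracle(al):
            return (gamma_dist(prior[0], scale=1 / prior[1]).logpdf(al)
                    + gamma_dist(al / N, scale=1.0).logpdf(gcol).sum())

        got = mass_log_conditional(a1, gcol, prior) - mass_log_conditional(
            a2, gcol, prior)
        assert got == pytest.approx(oracle(a1) - oracle(a2), abs=1e-10)


def test_mass_conditional_n1_reduces_to_prior_shape():
    """With a single component the gamma-dependent terms drop to the
    Gamma(gamma; alpha, 1) likelihood of the lone weight."""
    prior = (2.0, 4.0)
    gcol = np.array([1.0])   # log gamma = 0 kills the data term's alpha slope
    d1 = mass_log_conditional(1.0, gcol, prior) - mass_log_conditional(2.0, gcol, prior)
    want = (gamma_dist(*[prior[0]], scale=1 / prior[1]).logpdf(1.0)
            - gamma_dist(prior[0], scale=1 / prior[1]).logpdf(2.0)
            - (math.lgamma(1.0) - math.lgamma(2.0)))
    assert d1 == pytest.approx(want, abs=1e-10)


def test_slice_sampler_targets_gamma_density(rng):
    logf = gamma_dist(3.0, scale=0.5).logpdf
    x = 1.0
    draws = []
    for _ in range(20_000):
        x = _slice_sample_positive(logf, x, rng)
        draws.append(x)
    ks = kstest(np.array(draws[1000:]), gamma_dist(3.0, scale=0.5).cdf)
    assert ks.statistic < 0.02


def test_mass_stays_positive_over_many_updates(rng):
    views = make_categorical_views(10, 2, rng)
    samples = GibbsSampler(views, 4, ChainConfig(
        n_iterations=200, burn_in=0, thinning=1, seed=2)).run()
    assert np.all(samples.mass > 0)


# ---------------------------------------------------------------------------
# allocation sweep and chain driver
# ---------------------------------------------------------------------------

def test_strong_coupling_forces_agreement(rng):
    """Flat likelihood with phi ~ 1e6 on a pair drives columns identical."""
    n, N = 20, 3
    views = make_categorical_views(n, 2, rng)
    smp = GibbsSampler(views, N, ChainConfig(n_iterations=10, burn_in=0,
                                             update_phi=False, update_mass=False,
                                             update_hypers=False))
    smp.models = [FlatModel(n, N), FlatModel(n, N)]
    state = smp.init_state(rng)
    state.phi_edges = np.array([1e6])
    stats = smp._build_stats(state)
    ws = CouplingWorkspace(state.gamma, state.phi_edges)
    for _ in range(50):
        smp.update_v(state, ws, rng)
        smp.update_allocations(state, ws, stats, rng)
        smp.update_weights(state, ws, rng)
    assert agreement_count(0, 1, state.allocations) == n


def test_snapshot_count_and_reproducibility(rng):
    views = make_categorical_views(8, 2, rng, n_features=2)
    cfg = ChainConfig(n_iterations=40, burn_in=15, thinning=4, seed=77)
    s1 = GibbsSampler(views, 3, cfg).run()
    s2 = GibbsSampler(views, 3, cfg).run()
    assert s1.n_snapshots == (40 - 15) // 4
    assert np.array_equal(s1.allocations, s2.allocations)
    assert np.array_equal(s1.phi, s2.phi)
    assert np.array_equal(s1.mass, s2.mass)
    assert np.all((s1.allocations >= 0) & (s1.allocations < 3))


def test_run_chain_smoke_trivial(rng):
    views = make_categorical_views(4, 2, rng)
    cfg = ChainConfig(n_iterations=10, burn_in=2, thinning=1, seed=5)
    samples = run_chain(views, config=cfg, n_components=2)
    assert samples.n_snapshots == 8
    assert samples.allocations.shape == (8, 4, 2)


def test_degenerate_inputs_rejected(rng):
    views = make_categorical_views(1, 2, rng)
    with pytest.raises(ValueError, match="at least 2 genes"):
        GibbsSampler(views, 2)


def test_label_swap_preserves_likelihood_bookkeeping(rng):
    labels = np.arange(20) % 4
    views = make_categorical_views(20, 2, rng, n_features=4, labels=labels)
    smp = GibbsSampler(views, 6, ChainConfig(n_iterations=5, burn_in=0, seed=3))
    state = smp.init_state(rng)
    stats = smp._build_stats(state)
    ws = CouplingWorkspace(state.gamma, state.phi_edges)
    for _ in range(30):
        smp.label_swap_move(state, ws, stats, rng)
    # stats must still match a from-scratch rebuild of the current allocations
    fresh = smp._build_stats(state)
    for k in range(2):
        assert np.array_equal(stats[k].counts, fresh[k].counts)
        assert np.array_equal(stats[k].m, fresh[k].m)
    assert np.allclose(ws.gamma, state.gamma)


def test_phi_ordering_recovered_on_paired_vs_independent(rng):
    """Identically-labelled pair shows larger posterior phi than an
    independently labelled pair (ordering, not absolute values)."""
    labels = np.arange(24) % 3
    shuffled = rng.permutation(labels)
    v_same = make_categorical_views(24, 2, rng, n_features=6, labels=labels)
    v_diff_a = make_categorical_views(24, 1, rng, n_features=6, labels=labels)
    v_diff_b = make_categorical_views(24, 1, rng, n_features=6, labels=shuffled)
    v_diff_b[0].gene_ids = list(v_diff_a[0].gene_ids)
    cfg = ChainConfig(n_iterations=400, burn_in=150, thinning=2, seed=9)
    phi_same = GibbsSampler(v_same, 5, cfg).run().phi.mean()
    phi_diff = GibbsSampler([v_diff_a[0], v_diff_b[0]], 5, cfg).run().phi.mean()
    assert phi_same > phi_diff
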