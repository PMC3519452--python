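"""Synthetic multi-dataset collections with known ground truth.

The flagship design mirrors the six-dataset permutation experiment: a base
dataset of ~100 time courses partitioned into seven well-separated
clusters, with each successive dataset obtained from its predecessor by
picking 25 rows at random and permuting the gene names among them (profiles
keep their cluster labels; the gene-to-cluster map changes for at most 25
genes per step).  Cluster mean curves are phase-shifted sinusoids — a
parametric stand-in with comparable separability to the yeast cell-cycle
subset the design is modelled on, so the repository needs no external data.

Discrete analogues (categorical, binary, bag-of-words views driven by the
same labels) are provided for testing the discrete likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DatasetView


@dataclass
class SyntheticSpec:
    """Generator settings; defaults reproduce the six-dataset design."""

    n_genes: int = 100
    n_clusters: int = 7
    n_datasets: int = 6
    n_permuted: int = 25
    n_timepoints: int = 17
    time_step: float = 10.0          # minutes between observations
    amplitude: float = 2.0           # cluster mean-curve amplitude
    period: float = 80.0             # minutes per oscillation
    noise_sd: float = 0.3            # i.i.d. Gaussian noise on each profile
    concentration: float = 0.1      # Dirichlet concentration for discrete views
    n_features: int = 12             # features in discrete analogues
    n_categories: int = 3
    vocab_size: int = 30
    doc_length: int = 60
    seed: int | None = None

    def __post_init__(self):
        if self.n_permuted > self.n_genes:
            raise ValueError("n_permuted cannot exceed n_genes")
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters cannot exceed n_genes")

    def rng(self):
        return np.random.default_rng(self.seed)


def _balanced_labels(spec: SyntheticSpec, rng) -> np.ndarray:
    base = np.arange(spec.n_genes) % spec.n_clusters
    return rng.permutation(base)


def cluster_mean_curves(spec: SyntheticSpec) -> np.ndarray:
    """(n_clusters, T) distinct smooth mean curves (phase-shifted sinusoids)."""
    t = np.arange(spec.n_timepoints) * spec.time_step
    phases = 2.0 * np.pi * np.arange(spec.n_clusters) / spec.n_clusters
    return spec.amplitude * np.sin(2.0 * np.pi * t[None, :] / spec.period
                                   + phases[:, None])


def make_base_timecourses(spec: SyntheticSpec, rng=None):
    """Base dataset: cluster mean curve + i.i.d. Gaussian noise per gene.

    Returns ``(view, labels)`` with labels balanced up to rounding.
    """
    rng = spec.rng() if rng is None else rng
    labels = _balanced_labels(spec, rng)
    means = cluster_mean_curves(spec)
    Y = means[labels] + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, spec.n_timepoints))
    view = DatasetView(
        name="dataset_1", data_type="timecourse", matrix=Y,
        gene_ids=[f"g{i + 1:03d}" for i in range(spec.n_genes)],
        time=np.arange(spec.n_timepoints) * spec.time_step)
    return view, labels


def chain_permuted_views(base_view: DatasetView, base_labels, spec: SyntheticSpec,
                         rng=None):
    """Datasets 2..K from the permutation chain; returns (views, label_matrix).

    Each step keeps the profile-to-cluster pairing intact and reassigns the
    profiles of ``n_permuted`` randomly chosen genes among those same genes,
    so per-gene labels change between consecutive datasets for at most
    ``n_permuted`` genes.
    """
    if spec.n_datasets < 2:
        raise ValueError("the permutation chain needs at least 2 datasets")
    rng = spec.rng() if rng is None else rng
    n, K = base_view.n_genes, spec.n_datasets
    base_labels = np.asarray(base_labels)
    assignment = np.arange(n)          # gene position -> profile row
    views = [base_view]
    label_matrix = np.zeros((n, K), dtype=np.int64)
    label_matrix[:, 0] = base_labels
    for d in range(1, K):
        assignment = assignment.copy()
        if spec.n_permuted > 0:
            chosen = rng.choice(n, size=spec.n_permuted, replace=False)
            assignment[chosen] = assignment[chosen[rng.permutation(spec.n_permuted)]]
        views.append(DatasetView(
            name=f"dataset_{d + 1}", data_type="timecourse",
            matrix=base_view.matrix[assignment],
            gene_ids=list(base_view.gene_ids), time=base_view.time))
        label_matrix[:, d] = base_labels[assignment]
    return views, label_matrix


def agreement_table(label_matrix) -> pd.DataFrame:
    """K x K table of pairwise label-agreement counts between datasets."""
    L = np.asarray(label_matrix)
    K = L.shape[1]
    tab = np.zeros((K, K), dtype=int)
    for k in range(K):
        for l in range(K):
            tab[k, l] = int(np.sum(L[:, k] == L[:, l]))
    names = [f"dataset_{k + 1}" for k in range(K)]
    return pd.DataFrame(tab, index=names, columns=names)


def synthetic_experiment(spec: SyntheticSpec | None = None, seed=None):
    """Full six-dataset design in one call: (views, label_matrix, spec)."""
    if spec is None:
        spec = SyntheticSpec(seed=seed)
    elif seed is not None:
        raise ValueError("pass the seed inside the spec or alone, not both")
    rng = spec.rng()
    base, labels = make_base_timecourses(spec, rng)
    views, label_matrix = chain_permuted_views(base, labels, spec, rng)
    return views, label_matrix, spec


def make_discrete_views(labels, spec: SyntheticSpec, rng=None,
                        kinds=("categorical", "categorical")):
    """Discrete views driven by given labels (one view per entry of kinds).

    ``categorical`` draws per-cluster per-feature category distributions
    from Dirichlet(concentration) — near-deterministic clusters as the
    concentration approaches 0; ``binary`` draws sparse per-cluster
    Bernoulli profiles (interaction-screen-like); ``bag_of_words`` draws
    per-cluster word distributions and fixed-length multinomial documents.
    """
    labels = np.asarray(labels)
    rng = spec.rng() if rng is None else rng
    n = labels.size
    n_cl = int(labels.max()) + 1
    gene_ids = [f"g{i + 1:03d}" for i in range(n)]
    views = []
    for d, kind in enumerate(kinds):
        name = f"{kind}_{d + 1}"
        if kind == "categorical":
            theta = rng.dirichlet(np.full(spec.n_categories, spec.concentration),
                                  size=(n_cl, spec.n_features))
            X = np.empty((n, spec.n_features), dtype=np.int64)
            for j in range(spec.n_features):
                for cl in range(n_cl):
                    rows = labels == cl
                    X[rows, j] = rng.choice(spec.n_categories, size=rows.sum(),
                                            p=theta[cl, j])
            views.append(DatasetView(
                name=name, data_type="categorical", matrix=X, gene_ids=gene_ids,
                alphabets=[np.arange(spec.n_categories)] * spec.n_features))
        elif kind == "binary":
            rates = rng.beta(0.3, 1.7, size=(n_cl, spec.n_features))
            X = (rng.random((n, spec.n_features)) < rates[labels]).astype(np.int64)
            views.append(DatasetView(
                name=name, data_type="categorical", matrix=X, gene_ids=gene_ids,
                alphabets=[np.arange(2)] * spec.n_features))
        elif kind == "bag_of_words":
            theta = rng.dirichlet(np.full(spec.vocab_size, spec.concentration),
                                  size=n_cl)
            X = np.vstack([rng.multinomial(spec.doc_length, theta[cl])
                           for cl in labels])
            views.append(DatasetView(
                name=name, data_type="bag_of_words", matrix=X, gene_ids=gene_ids))
        else:
            raise ValueError(f"unknown discrete kind {kind!r}")
    return views
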