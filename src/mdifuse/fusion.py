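"""Posterior fusion analysis.

A gene is *fused* across a subset S of datasets when its component labels
agree across all of S; its fusion probability is the proportion of posterior
snapshots in which that happens, and genes exceeding a threshold (default
0.5) form the fused set.  The fused set is then summarized by a single
partition: among the partitions actually visited by the chain (restricted
to the fused genes, labels taken from the reference dataset ``min(S)``),
the one maximizing the posterior expected adjusted Rand index is returned
(the maxpear criterion of Fritsch & Ickstadt, written in pair counts
against the posterior similarity matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)


def adjusted_rand_index(partition_a, partition_b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings of one item set."""
    a = np.asarray(partition_a).ravel()
    b = np.asarray(partition_b).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"partitions label different item sets ({a.size} vs {b.size} items)")
    return float(adjusted_rand_score(a, b))


def pairwise_ari_matrix(label_matrix) -> np.ndarray:
    """(K, K) symmetric matrix of ARIs between the columns of (n, K) labels."""
    L = np.asarray(label_matrix)
    K = L.shape[1]
    out = np.ones((K, K))
    for k in range(K):
        for l in range(k + 1, K):
            out[k, l] = out[l, k] = adjusted_rand_index(L[:, k], L[:, l])
    return out


def fusion_probabilities(samples, subset) -> np.ndarray:
    """Per-gene probability of identical labels across ``subset`` of datasets.

    ``samples`` is a :class:`~mdifuse.sampler.PosteriorSamples`; ``subset``
    a list of >= 2 dataset indices.  Computed as the proportion of snapshots
    with all labels equal.
    """
    subset = sorted(set(int(k) for k in subset))
    if len(subset) < 2:
        raise ValueError("fusion requires a subset of at least 2 datasets")
    alloc = samples.allocations
    if alloc.shape[0] == 0:
        raise ValueError("no posterior snapshots")
    if max(subset) >= alloc.shape[2]:
        raise ValueError(f"dataset index out of range: {subset}")
    sub = alloc[:, :, subset]
    eq = np.all(sub == sub[:, :, :1], axis=2)
    return eq.mean(axis=0)


def posterior_similarity(labels) -> np.ndarray:
    """(m, m) co-clustering frequency across the rows of (S, m) labels."""
    L = np.asarray(labels)
    return np.mean(L[:, :, None] == L[:, None, :], axis=0)


def expected_ari(candidate_labels, psm) -> float:
    """Posterior expected ARI of a candidate partition against a PSM.

    Fritsch-Ickstadt pair-count form: with delta_ij = [same candidate
    cluster], pi_ij the posterior co-clustering probabilities and
    C = m(m-1)/2 pairs,

        (sum delta*pi - sum delta * sum pi / C)
        / ((sum delta + sum pi)/2 - sum delta * sum pi / C)

    summed over unordered pairs.  Degenerate denominators (candidate and
    PSM both trivial) score 1 when the numerator also vanishes.
    """
    cand = np.asarray(candidate_labels).ravel()
    m = cand.size
    psm = np.asarray(psm, dtype=float)
    if psm.shape != (m, m):
        raise ValueError("PSM shape does not match the candidate partition")
    iu = np.triu_indices(m, k=1)
    delta = (cand[:, None] == cand[None, :])[iu].astype(float)
    pi = psm[iu]
    C = delta.size
    if C == 0:
        return 1.0
    exp_term = delta.sum() * pi.sum() / C
    num = float(delta @ pi - exp_term)
    den = float(0.5 * (delta.sum() + pi.sum()) - exp_term)
    if abs(den) < 1e-12:
        return 1.0 if abs(num) < 1e-12 else 0.0
    return num / den


def phi_summary(samples) -> np.ndarray:
    """(K, K) posterior-mean association matrix; diagonal NaN (undefined)."""
    from .core import phi_edges_to_matrix

    K = samples.allocations.shape[2]
    return phi_edges_to_matrix(samples.phi.mean(axis=0), K)


@dataclass
class FusionReport:
    """Fusion analysis of one dataset subset."""

    subset: list
    threshold: float
    fusion_probs: pd.Series           # indexed by gene id, all genes
    fused_genes: list                 # gene ids with prob > threshold
    fused_partition: pd.Series        # cluster label per fused gene
    expected_ari: float               # maxpear score of the chosen partition
    reference_dataset: int
    psm: pd.DataFrame | None = None   # reference-dataset PSM over fused genes
    per_dataset_psm: dict = field(default_factory=dict)

    @property
    def n_fused(self) -> int:
        return len(self.fused_genes)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-gene table (gene_id, subset, probability, fused, cluster)."""
        subset_tag = "+".join(str(k) for k in self.subset)
        df = pd.DataFrame({
            "gene_id": self.fusion_probs.index,
            "subset": subset_tag,
            "probability": self.fusion_probs.values,
        })
        df["fused"] = df["probability"] > self.threshold
        cl = self.fused_partition.reindex(df["gene_id"])
        df["cluster"] = cl.values
        return df


def fused_clusters(samples, subset, threshold: float = 0.5,
                   compute_psms: bool = True) -> FusionReport:
    """Fusion probabilities, fused gene set and maxpear fused partition.

    Candidate partitions are the distinct sampled label patterns over the
    fused genes in the reference dataset ``min(subset)`` (first occurrence
    in chain order wins ties).  Component labels are re-coded to consecutive
    integers in order of first appearance for the returned partition.
    """
    subset = sorted(set(int(k) for k in subset))
    probs = fusion_probabilities(samples, subset)
    gene_ids = list(samples.gene_ids)
    prob_series = pd.Series(probs, index=gene_ids, name="fusion_probability")
    fused_mask = probs > threshold
    fused_idx = np.nonzero(fused_mask)[0]
    fused_genes = [gene_ids[i] for i in fused_idx]
    ref = subset[0]

    if fused_idx.size == 0:
        logger.warning("no gene exceeds the fusion threshold %.3g for subset %s",
                       threshold, subset)
        return FusionReport(subset=subset, threshold=threshold,
                            fusion_probs=prob_series, fused_genes=[],
                            fused_partition=pd.Series(dtype=int),
                            expected_ari=float("nan"), reference_dataset=ref)

    labels = samples.allocations[:, fused_idx, ref]        # (S, m)
    psm = posterior_similarity(labels)

    best_score, best_row, ties = -np.inf, None, 0
    seen = set()
    for s in range(labels.shape[0]):
        key = tuple(labels[s])
        if key in seen:
            continue
        seen.add(key)
        score = expected_ari(labels[s], psm)
        if score > best_score + 1e-12:
            best_score, best_row = score, labels[s]
        elif abs(score - best_score) <= 1e-12:
            ties += 1
    if ties:
        logger.info("maxpear: %d tied candidate partition(s); keeping the "
                    "first in chain order", ties)

    # re-code component labels to consecutive ids in order of appearance
    recode, out = {}, np.empty(best_row.size, dtype=int)
    for j, lab in enumerate(best_row):
        out[j] = recode.setdefault(int(lab), len(recode))
    partition = pd.Series(out, index=fused_genes, name="cluster")

    per_ds = {}
    psm_df = None
    if compute_psms:
        psm_df = pd.DataFrame(psm, index=fused_genes, columns=fused_genes)
        for k in subset:
            per_ds[k] = pd.DataFrame(
                posterior_similarity(samples.allocations[:, fused_idx, k]),
                index=fused_genes, columns=fused_genes)

    return FusionReport(subset=subset, threshold=threshold,
                        fusion_probs=prob_series, fused_genes=fused_genes,
                        fused_partition=partition, expected_ari=float(best_score),
                        reference_dataset=ref, psm=psm_df, per_dataset_psm=per_ds)
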