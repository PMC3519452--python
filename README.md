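# mdifuse

Bayesian correlated clustering of genes across multiple heterogeneous
datasets (MDI — Multiple Dataset Integration), with posterior fusion
analysis.

## The problem

Modern functional-genomics studies measure the same genes on several
platforms at once — expression time courses, transcription-factor binding
(ChIP–chip) compendia, protein–protein interaction screens.  Each dataset
carries its own clustering structure, and those structures are related but
not identical: a set of co-regulated genes may share expression dynamics
*and* a common set of promoter-binding proteins, while other genes cluster
differently in different assays.  `mdifuse` is for analysts who want to
cluster each dataset on its own terms while *sharing* clustering
information between datasets, and then to ask the integrative question
directly: **which genes cluster together consistently across some or all of
the datasets, and what are those shared clusters?**

## The model

Each of the K datasets is modelled by a Dirichlet-multinomial allocation
(DMA) mixture — a finite approximation to a Dirichlet process mixture with
N components, where N is an upper bound and the number of *occupied*
components (clusters) is inferred.  Gene i has one allocation variable per
dataset, c_ik, and the K mixtures are coupled only through these
allocations:

    p(c_i1, …, c_iK | π, Φ)  ∝  Π_k π_{c_ik,k} · Π_{k<l} (1 + φ_kl · 1[c_ik = c_il])

The pairwise association parameters φ_kl ≥ 0 up-weight the prior
probability that gene i takes the same component label in datasets k and l;
φ = 0 recovers K independent mixtures, and the posterior of φ_kl measures
how similar two datasets' clustering structures are.  Mixture weights get
symmetric Dirichlet(α_k/N) priors with inferred mass parameters α_k; the
per-dataset likelihoods are collapsed conjugate families — Gaussian
processes for time courses, Dirichlet-multinomials for categorical/binary
data, a bag-of-words model for count data — so datasets of different types
never have to be compared directly.

Inference is by Gibbs sampling, with the intractable normalizing constant
of the coupled allocation prior handled exactly via an auxiliary Gamma
variable and a pair-subset expansion (K ≤ 6).  From the posterior samples
the package computes, for any dataset subset S:

* **fusion probabilities** p_i(S) — the posterior probability that gene i's
  labels agree across all of S (a gene is *fused* when p_i(S) > 0.5), and
* **fused clusters** — the sampled partition of the fused genes maximizing
  the posterior expected adjusted Rand index (maxpear).

See `docs/methods.md` for the full model, sampler and design choices.

## Worked example

Three synthetic datasets of 60 genes in 4 clusters, where each successive
dataset permutes the gene names of 12 randomly chosen rows of its
predecessor (so consecutive datasets disagree on at most 12 gene labels):

```python
from mdifuse import MDIModel, SyntheticSpec, synthetic_experiment

spec = SyntheticSpec(n_genes=60, n_clusters=4, n_datasets=3,
                     n_permuted=12, seed=0)
views, truth, _ = synthetic_experiment(spec)

model = MDIModel(views, n_components=10)
results = model.fit(n_iterations=800, burn_in=400, thinning=4, seed=0)
print(results.summary())

report = results.fused_clusters([0, 1, 2], threshold=0.5)
print(f"fused genes across all three datasets: {report.n_fused} / 60")
```

which prints:

```
Multiple-dataset correlated clustering (MDI) — posterior summary
==================================================================
genes: 60   datasets: 3   components (upper bound N): 10
snapshots: 100  (iterations 800, burn-in 400, thin 4)

dataset        occupied components (posterior mode)   mass alpha (mean ± sd)
dataset_1                        4                    0.548 ± 0.224
dataset_2                        4                    0.841 ± 0.378
dataset_3                        4                    1.012 ± 0.473

pairwise association phi (posterior mean ± sd):
  dataset_1 ~ dataset_2: 13.52 ± 5.58
  dataset_1 ~ dataset_3: 2.42 ± 1.81
  dataset_2 ~ dataset_3: 10.48 ± 4.38

fused genes across all three datasets: 48 / 60
```

Reading the output: every dataset's posterior concentrates on the 4 true
clusters (out of an upper bound of 10); the association parameters are
large for the directly-permuted-from-each-other pairs (1–2 and 2–3) and
smaller for the more weakly coupled pair 1–3; and 48 genes keep the same
label in all three datasets — the genes whose names were never permuted
away plus those permuted within their own cluster.  The fused partition of
those 48 genes recovers the four clusters of 12 exactly (maxpear expected
ARI 1.000).

## Command line

The same workflow from a shell: `simulate` writes a synthetic collection
(data, ground truth and a ready `run_config.yaml`), `run` fits the model
and stores posterior samples plus summary tables, `fuse` turns stored
samples into per-gene fusion tables, and `ari` compares two partition
files.

```bash
mdifuse simulate --output-dir sim --seed 3
mdifuse run --config sim/run_config.yaml --output-dir fit --seed 3
mdifuse fuse --samples fit --subset 1,2
```

`run` writes `manifest.yaml` (config echo + version), the sample store
(`allocations.csv`, `phi_trace.csv`, `alpha_trace.csv`, `v_trace.csv`),
`phi_mean.csv` and `ari_matrix.csv`; `fuse` writes
`fusion_<subset>.csv` with columns gene_id, subset, probability, fused,
cluster.

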