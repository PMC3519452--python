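"""Model / Results surface for correlated multi-dataset clustering.

``MDIModel`` binds K aligned dataset views to their collapsed component
likelihoods and priors; ``fit`` runs the Gibbs sampler and returns
``MDIResults``, which carries the thinned posterior samples and exposes the
headline summaries: posterior-mean association matrix, fusion
probabilities and maxpear fused clusters for any dataset subset, occupied
component counts, posterior similarity matrices, and a text ``summary()``.

Example
-------
>>> from mdifuse import MDIModel, SyntheticSpec, synthetic_experiment
>>> views, truth, spec = synthetic_experiment(seed=3)
>>> res = MDIModel(views, n_components=15).fit(
...     n_iterations=400, burn_in=200, thinning=5, seed=3)
>>> res.phi_mean().shape
(6, 6)
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import fusion as _fusion
from .data import DatasetView, align_views, check_aligned
from .sampler import ChainConfig, GibbsSampler, PosteriorSamples


class MDIModel:
    """Correlated Dirichlet-multinomial allocation mixtures over K datasets.

    Parameters
    ----------
    views : sequence of DatasetView
        Aligned views (identical gene ids in identical order); use
        ``MDIModel.from_views`` to align automatically.
    n_components : int, optional
        Upper bound N on the number of clusters, shared by all datasets;
        defaults to ``min(50, ceil(n/2))``.
    prior_mass, prior_phi : (shape, rate)
        Gamma priors for the mass parameters and the pairwise association
        parameters.
    pseudo_count : float
        Dirichlet pseudo-count per category/word for the discrete models.
    gp_kwargs : dict, optional
        Keyword arguments for the GP likelihood (signal_var, length_scale,
        noise_var, standardize, step).
    """

    def __init__(self, views, n_components: int | None = None,
                 prior_mass=(2.0, 4.0), prior_phi=(1.0, 0.2),
                 pseudo_count: float = 0.5, gp_kwargs: dict | None = None):
        views = list(views)
        if not views:
            raise ValueError("at least one dataset view is required")
        if len(views) >= 2:
            check_aligned(views)
        self.views = views
        self.n_genes = views[0].n_genes
        self.n_datasets = len(views)
        self.n_components = (min(50, math.ceil(self.n_genes / 2))
                             if n_components is None else int(n_components))
        self.prior_mass = tuple(prior_mass)
        self.prior_phi = tuple(prior_phi)
        self.pseudo_count = float(pseudo_count)
        self.gp_kwargs = dict(gp_kwargs or {})

    @classmethod
    def from_views(cls, views, **kwargs) -> "MDIModel":
        """Align views on their common genes, then construct the model."""
        if len(views) >= 2:
            views = align_views(views)
        return cls(views, **kwargs)

    @classmethod
    def from_dataframes(cls, frames, data_types, names=None, times=None,
                        **kwargs) -> "MDIModel":
        """Build from pandas DataFrames indexed by gene id.

        ``times`` supplies the time grid per time-course frame; when omitted
        the column labels are parsed as numbers.
        """
        views = []
        for j, (df, dtype) in enumerate(zip(frames, data_types)):
            name = names[j] if names else f"dataset_{j + 1}"
            time = None
            if dtype == "timecourse":
                time = (np.asarray(times[j], dtype=float) if times and times[j]
                        is not None else df.columns.to_numpy(dtype=float))
            views.append(DatasetView(name=name, data_type=dtype,
                                     matrix=df.to_numpy(),
                                     gene_ids=list(df.index.astype(str)),
                                     time=time))
        return cls.from_views(views, **kwargs)

    def fit(self, n_iterations: int = 2000, burn_in: int = 1000,
            thinning: int = 5, seed: int | None = None,
            update_phi: bool = True, update_mass: bool = True,
            update_hypers: bool = True, swap_moves: bool = True,
            progress_every: int = 100) -> "MDIResults":
        """Run the Gibbs sampler and return the results object."""
        config = ChainConfig(n_iterations=n_iterations, burn_in=burn_in,
                             thinning=thinning, seed=seed,
                             prior_mass=self.prior_mass, prior_phi=self.prior_phi,
                             update_phi=update_phi, update_mass=update_mass,
                             update_hypers=update_hypers, swap_moves=swap_moves)
        sampler = GibbsSampler(self.views, self.n_components, config=config,
                               pseudo_count=self.pseudo_count,
                               gp_kwargs=self.gp_kwargs or None)
        samples = sampler.run(progress_every=progress_every)
        return MDIResults(self, samples)


class MDIResults:
    """Posterior samples plus the summaries computed from them."""

    def __init__(self, model: MDIModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self.dataset_names = samples.dataset_names
        self.gene_ids = samples.gene_ids

    # -- association parameters --------------------------------------------
    def phi_mean(self) -> pd.DataFrame:
        """Posterior-mean association matrix (diagonal undefined -> NaN)."""
        return pd.DataFrame(_fusion.phi_summary(self.samples),
                            index=self.dataset_names, columns=self.dataset_names)

    def phi_trace(self) -> pd.DataFrame:
        """Tidy long-format trace of every pairwise association parameter."""
        from .core import edge_index
        rows = []
        for e, (k, l) in enumerate(edge_index(self.samples.allocations.shape[2])):
            name = f"phi[{self.dataset_names[k]},{self.dataset_names[l]}]"
            for it, val in zip(self.samples.iterations, self.samples.phi[:, e]):
                rows.append((int(it), name, float(val)))
        return pd.DataFrame(rows, columns=["iteration", "parameter", "value"])

    def mass_trace(self) -> pd.DataFrame:
        rows = []
        for k, name in enumerate(self.dataset_names):
            for it, val in zip(self.samples.iterations, self.samples.mass[:, k]):
                rows.append((int(it), f"alpha[{name}]", float(val)))
        return pd.DataFrame(rows, columns=["iteration", "parameter", "value"])

    # -- fusion --------------------------------------------------------------
    def fusion_probabilities(self, subset) -> pd.Series:
        probs = _fusion.fusion_probabilities(self.samples, subset)
        return pd.Series(probs, index=self.gene_ids, name="fusion_probability")

    def fused_clusters(self, subset, threshold: float = 0.5) -> _fusion.FusionReport:
        return _fusion.fused_clusters(self.samples, subset, threshold=threshold)

    # -- partitions ----------------------------------------------------------
    def occupied_components(self, k: int) -> np.ndarray:
        """Trace of the number of occupied components in dataset k."""
        return np.array([np.unique(a[:, k]).size for a in self.samples.allocations])

    def posterior_similarity(self, k: int) -> pd.DataFrame:
        psm = _fusion.posterior_similarity(self.samples.allocations[:, :, k])
        return pd.DataFrame(psm, index=self.gene_ids, columns=self.gene_ids)

    def mean_pairwise_ari(self) -> pd.DataFrame:
        """Snapshot-averaged ARI between every pair of datasets' partitions."""
        mats = [_fusion.pairwise_ari_matrix(a) for a in self.samples.allocations]
        return pd.DataFrame(np.mean(mats, axis=0),
                            index=self.dataset_names, columns=self.dataset_names)

    def map_partition(self, k: int) -> pd.Series:
        """maxpear partition of dataset k over all genes."""
        labels = self.samples.allocations[:, :, k]
        psm = _fusion.posterior_similarity(labels)
        best, best_score = None, -np.inf
        seen = set()
        for row in labels:
            key = tuple(row)
            if key in seen:
                continue
            seen.add(key)
            score = _fusion.expected_ari(row, psm)
            if score > best_score + 1e-12:
                best, best_score = row, score
        recode, out = {}, np.empty(len(best), dtype=int)
        for j, lab in enumerate(best):
            out[j] = recode.setdefault(int(lab), len(recode))
        return pd.Series(out, index=self.gene_ids, name=f"cluster_{k}")

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        s = self.samples
        K = len(self.dataset_names)
        lines = [
            "Multiple-dataset correlated clustering (MDI) — posterior summary",
            "=" * 66,
            f"genes: {len(self.gene_ids)}   datasets: {K}   "
            f"components (upper bound N): {s.n_components}",
            f"snapshots: {s.n_snapshots}  "
            f"(iterations {s.config.get('n_iterations')}, "
            f"burn-in {s.config.get('burn_in')}, thin {s.config.get('thinning')})",
            "",
            "dataset        occupied components (posterior mode)   mass alpha (mean ± sd)",
        ]
        for k, name in enumerate(self.dataset_names):
            occ = self.occupied_components(k)
            vals, counts = np.unique(occ, return_counts=True)
            mode = int(vals[np.argmax(counts)])
            lines.append(f"{name:<14} {mode:^38d} "
                         f"{s.mass[:, k].mean():.3f} ± {s.mass[:, k].std():.3f}")
        if K >= 2 and s.phi.shape[1]:
            lines += ["", "pairwise association phi (posterior mean ± sd):"]
            from .core import edge_index
            for e, (k, l) in enumerate(edge_index(K)):
                lines.append(f"  {self.dataset_names[k]} ~ {self.dataset_names[l]}: "
                             f"{s.phi[:, e].mean():.2f} ± {s.phi[:, e].std():.2f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<MDIResults: {len(self.gene_ids)} genes, "
                f"{len(self.dataset_names)} datasets, "
                f"{self.samples.n_snapshots} snapshots>")
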