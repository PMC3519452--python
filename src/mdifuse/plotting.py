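"""Minimal figure export: association heatmap and parameter traces.

Requires matplotlib (the ``plot`` extra); everything returns the Axes so
callers can restyle.
"""

from __future__ import annotations

import numpy as np


def plot_phi_heatmap(results, ax=None, path=None):
    """Heatmap of the posterior-mean association matrix (diagonal masked)."""
    import matplotlib.pyplot as plt

    pm = results.phi_mean()
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    data = np.ma.masked_invalid(pm.values)
    im = ax.imshow(data, cmap="viridis")
    ax.set_xticks(range(len(pm.columns)), pm.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pm.index)), pm.index)
    ax.figure.colorbar(im, ax=ax, label="posterior mean association")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def plot_traces(results, parameters=("phi", "alpha"), ax=None, path=None):
    """Thinned-chain traces of the association and/or mass parameters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    s = results.samples
    if "phi" in parameters:
        for e in range(s.phi.shape[1]):
            ax.plot(s.iterations, s.phi[:, e], lw=0.7)
        ax.set_ylabel("phi")
    if "alpha" in parameters and "phi" not in parameters:
        for k in range(s.mass.shape[1]):
            ax.plot(s.iterations, s.mass[:, k], lw=0.7,
                    label=results.dataset_names[k])
        ax.set_ylabel("alpha")
        ax.legend(fontsize=7)
    ax.set_xlabel("iteration")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
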