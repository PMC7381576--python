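"""Simple diagnostic figures (PCA scatter, condition-index contrast)."""

from __future__ import annotations

import numpy as np


def plot_pca(pca, labels, ax=None):
    """PC1/PC2 scatter colored by group label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(list(labels), dtype=object)
    for grp in sorted(set(labels)):
        m = labels == grp
        ax.scatter(pca.scores[m, 0], pca.scores[m, 1], s=12, label=str(grp))
    share = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({share[0]:.1%})")
    ax.set_ylabel(f"PC2 ({share[1]:.1%})")
    ax.legend(fontsize=7)
    return ax


def plot_condition(meta, result, ax=None):
    """Log weight vs log length with per-year fitted lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.log(meta["length"].to_numpy(dtype=float))
    y = np.log(meta["weight"].to_numpy(dtype=float))
    years = meta["year"].to_numpy()
    est = dict(zip(result.interaction_fit["term"], result.interaction_fit["estimate"]))
    grid = np.linspace(x.min(), x.max(), 50)
    for i, year in enumerate(result.year_levels):
        m = years == year
        ax.scatter(x[m], y[m], s=10, alpha=0.5, label=str(year))
        a = est["intercept"] + (est["year2"] if i else 0.0)
        b = est["log_length"] + (est["year2:log_length"] if i else 0.0)
        ax.plot(grid, a + b * grid)
    ax.set_xlabel("log length (mm)")
    ax.set_ylabel("log weight (g)")
    ax.legend()
    return ax
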