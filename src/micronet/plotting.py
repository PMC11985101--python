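"""Optional plot helpers: composition stacked bars and the PCA biplot.

matplotlib is imported lazily so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chemlink import PcaResult


def stacked_composition_bars(comp: pd.DataFrame, path: str | Path | None = None):
    """Stacked bars of phylum fractions per ecosystem network."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = comp.pivot_table(index="ecosystem", columns="phylum",
                            values="fraction", fill_value=0.0)
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(wide)), 4))
    bottom = np.zeros(len(wide))
    for phylum in wide.columns:
        ax.bar(wide.index, wide[phylum], bottom=bottom, label=phylum)
        bottom += wide[phylum].to_numpy()
    ax.set_ylabel("fraction of network nodes")
    ax.legend(fontsize=7, ncol=2)
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def pca_biplot(result: PcaResult, path: str | Path | None = None):
    """Scores + loading arrows for the first two components."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    scores = result.scores
    ax.scatter(scores["PC1"], scores["PC2"], s=30)
    for name, row in scores.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=7)
    scale = float(np.abs(scores[["PC1", "PC2"]].to_numpy()).max())
    for var, row in result.loadings.iterrows():
        ax.arrow(0, 0, row["PC1"] * scale, row["PC2"] * scale,
                 color="crimson", alpha=0.6, head_width=0.02 * scale)
        ax.annotate(str(var), (row["PC1"] * scale * 1.08, row["PC2"] * scale * 1.08),
                    color="crimson", fontsize=7)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
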