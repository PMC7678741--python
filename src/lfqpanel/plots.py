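"""Basic figure exports: volcano plot and 3-D panel scatter."""

from __future__ import annotations

import numpy as np

from .containers import LFQMatrix
from .stats import UnivariateResult


def volcano_plot(results: list[UnivariateResult], alpha: float = 0.05,
                 highlight: set[str] | None = None, path=None):
    """Group difference (log2, A - C) vs -log10 p per protein.

    Significant proteins (p < alpha) are drawn in red; ``highlight``
    (e.g. SVM-selected panel members) in blue.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    highlight = highlight or set()
    fig, ax = plt.subplots(figsize=(5, 4))
    for r in results:
        if r.p_value is None:
            continue
        if r.protein_id in highlight:
            color = "tab:blue"
        elif r.p_value < alpha:
            color = "tab:red"
        else:
            color = "0.7"
        ax.scatter(r.difference, r.neg_log10_p, s=8, color=color)
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, color="0.4")
    ax.set_xlabel("difference, log2 LFQ (A - C)")
    ax.set_ylabel("-log10 p")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def panel_scatter_3d(matrix: LFQMatrix, protein_ids, path=None):
    """3-D scatter of the samples in the space of a protein trio."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(protein_ids) != 3:
        raise ValueError("panel_scatter_3d needs exactly three proteins")
    rows = [matrix.row_index(p) for p in protein_ids]
    labels = matrix.labels_array()
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    for group, color in (("C", "tab:orange"), ("A", "tab:green")):
        cols = np.flatnonzero(labels == group)
        ax.scatter(
            matrix.intensities[rows[0], cols],
            matrix.intensities[rows[1], cols],
            matrix.intensities[rows[2], cols],
            label=group, color=color, s=18,
        )
    ax.set_xlabel(protein_ids[0])
    ax.set_ylabel(protein_ids[1])
    ax.set_zlabel(protein_ids[2])
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
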