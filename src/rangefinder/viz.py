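"""Optional heatmap rendering of enrichment diagrams (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .sweetspot import EnrichmentDiagram


def plot_diagram(diagram: EnrichmentDiagram, path=None, ax=None):
    """Draw a dose x time diagram with the red-to-grey adaptive color key.

    Red marks the lowest adjusted p-values (the sweet-spot band), grey the
    top of the active scale.  Returns the matplotlib Axes.
    """
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    doses = sorted({d for d, _ in diagram.p_adj})
    times = sorted({t for _, t in diagram.p_adj})
    mat = np.full((len(doses), len(times)), np.nan)
    for (d, t), c in diagram.color_value.items():
        mat[doses.index(d), times.index(t)] = c
    cmap = LinearSegmentedColormap.from_list("red_grey", ["#d62728", "#bdbdbd"])
    cmap.set_bad("white")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(times), 1 + 0.5 * len(doses)))
    ax.imshow(mat, cmap=cmap, vmin=0, vmax=1, aspect="auto", origin="lower")
    for (d, t), sweet in diagram.sweet_mask.items():
        if sweet:
            ax.plot(times.index(t), doses.index(d), "k*", markersize=8)
    ax.set_xticks(range(len(times)), [f"{t/60:g}" for t in times])
    ax.set_yticks(range(len(doses)), [f"{d:g}" for d in doses])
    ax.set_xlabel("recovery time (h)")
    ax.set_ylabel("dose")
    ax.set_title(f"{diagram.set_name} (pmin = {diagram.pmin:.3g})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
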