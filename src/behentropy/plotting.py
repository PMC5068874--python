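"""Transition-matrix heat-maps.

The matrix CSV is the authoritative artifact; the rendered image is a
convenience. The color scale always spans [0, 1] so heat-maps of different
dams are directly comparable.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402


def plot_transition_heatmap(
    probs, labels, ax=None, cmap: str = "viridis", annotate: bool = True
):
    """Render a row-stochastic transition matrix as a heat-map.

    Rows are the current behavior, columns its successor; NaN rows (no
    outgoing transitions observed) render as hatched gray.
    """
    P = np.asarray(probs, dtype=float)
    k = P.shape[0]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.1 * k + 1.5, 1.1 * k))
    masked = np.ma.masked_invalid(P)
    cmap_obj = plt.get_cmap(cmap).copy()
    cmap_obj.set_bad(color="0.85")
    im = ax.imshow(masked, vmin=0.0, vmax=1.0, cmap=cmap_obj)
    ax.set_xticks(range(k), labels=labels, rotation=45, ha="right")
    ax.set_yticks(range(k), labels=labels)
    ax.set_xlabel("next behavior")
    ax.set_ylabel("current behavior")
    if annotate:
        for i in range(k):
            for j in range(k):
                if i == j or np.isnan(P[i, j]):
                    continue
                ax.text(
                    j, i, f"{P[i, j]:.2f}", ha="center", va="center",
                    fontsize=8,
                    color="white" if P[i, j] > 0.5 else "black",
                )
    ax.figure.colorbar(im, ax=ax, label="P(next | current)")
    return ax
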