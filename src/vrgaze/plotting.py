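"""Minimal rendering helpers: equirectangular heatmaps and recurrence plots."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_heatmap", "plot_recurrence"]


def plot_heatmap(heatmap, ax=None, cmap="jet", **imshow_kw):
    """Render a Heatmap on an equirectangular axis (lon -180..180, lat -90..90)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(heatmap.grid, extent=(-180, 180, -90, 90), cmap=cmap,
                   aspect="auto", **imshow_kw)
    ax.set_xlabel("longitude (deg)")
    ax.set_ylabel("latitude (deg)")
    return im


def plot_recurrence(r, ax=None, **scatter_kw):
    """Dot plot of a binary recurrence matrix (encoding index vs recognition)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    i, j = np.nonzero(np.asarray(r, dtype=bool))
    ax.scatter(j + 1, i + 1, s=scatter_kw.pop("s", 12), **scatter_kw)
    n = r.shape[0]
    ax.set_xlim(0.5, n + 0.5)
    ax.set_ylim(0.5, n + 0.5)
    ax.set_xlabel("recognition fixation")
    ax.set_ylabel("encoding fixation")
    return ax
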