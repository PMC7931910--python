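"""PNG export of portraits and correlation maps (red = high, blue = low)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_grid_png"]


def save_grid_png(grid: np.ndarray, path, title: str | None = None,
                  symmetric: bool = True) -> None:
    """Render one SOM grid (portrait, summary or correlation map) to PNG.

    Uses the diverging red-to-blue scale of transcriptome portraits
    (maximum expression in red, minimum in blue); ``symmetric`` centers
    the scale at zero.
    """
    grid = np.asarray(grid, dtype=float)
    vmax = np.abs(grid).max() if symmetric else grid.max()
    vmin = -vmax if symmetric else grid.min()
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    im = ax.imshow(grid, cmap="RdBu_r", vmin=vmin, vmax=vmax,
                   interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
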