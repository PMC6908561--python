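"""Static polar-map (bullseye) rendering of sector grids and ratio maps."""

from __future__ import annotations

import numpy as np

from .quantify import RatioMap
from .sectorization import N_SECTORS, SectorGrid


def plot_polar_map(data, path, title: str = "", cmap: str = "viridis") -> None:
    """Save a bullseye plot: apex at the centre, base at the periphery.

    ``data`` is a :class:`SectorGrid`, a :class:`RatioMap` or a plain
    (n_slices, 12) array; slice label 1 (most basal) maps to the
    outermost ring. The plot is rotated so 0 degrees (anterior) points
    up and angles increase clockwise on screen, matching the angular
    convention's anterior -> lateral -> inferior -> septal order.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(data, SectorGrid):
        values = data.values
    elif isinstance(data, RatioMap):
        values = data.values
    else:
        values = np.asarray(data, dtype=float)
    n_slices = values.shape[0]

    theta = np.radians(np.arange(N_SECTORS + 1) * 30.0)
    # ring 0 at the apex (innermost) = highest slice label
    r = np.arange(n_slices + 1)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    mesh = ax.pcolormesh(theta, r, values[::-1], cmap=cmap, shading="flat")
    ax.set_yticks([])
    ax.set_xticks(np.radians([0, 90, 180, 270]))
    ax.set_xticklabels(["anterior", "lateral", "inferior", "septal"])
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
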