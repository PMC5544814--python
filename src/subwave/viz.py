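"""Debug rendering of scenario geometry and meshes (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .geometry import REGIONS, ScenarioGeometry
from .mesh import Mesh

__all__ = ["plot_scenario", "plot_mesh"]

_COLORS = {
    "air": "#f5f5f5",
    "metal": "#707070",
    "port": "#c0d8f0",
    "water_bag": "#70b0e0",
    "skull": "#d8cfa0",
    "csf": "#80d0d0",
    "csf_interior": "#60c0c0",
    "brain": "#e8b0b0",
    "bleeding": "#b01010",
}


def plot_scenario(geometry: ScenarioGeometry, n: int = 600, ax=None):
    """Raster render of the region map; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    rb = geometry.config.boundary_radius
    xs = np.linspace(-rb, rb, n)
    X, Y = np.meshgrid(xs, xs)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    img = geometry.classify(pts).reshape(n, n).astype(float)
    img[np.hypot(X, Y) > rb] = np.nan
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    cmap = ListedColormap([_COLORS[r] for r in REGIONS])
    ax.imshow(
        img, origin="lower", extent=[-rb, rb, -rb, rb],
        cmap=cmap, vmin=-0.5, vmax=len(REGIONS) - 0.5, interpolation="nearest",
    )
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    return ax


def plot_mesh(mesh: Mesh, ax=None):
    """Triangle mesh colored by material label; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.tripcolor(
        mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles,
        facecolors=mesh.labels.astype(float), edgecolors="k", linewidth=0.1,
    )
    ax.set_aspect("equal")
    return ax
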