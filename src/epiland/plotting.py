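"""Optional thin plotting layer (requires matplotlib).

The surfaces are data products first; these helpers exist for quick visual
inspection, not publication rendering.
"""

from __future__ import annotations

import numpy as np


def plot_surface(surface, ax=None, levels: int = 30, cmap: str = "viridis"):
    """Filled contour of the elevation field with attractors marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    z = np.ma.masked_invalid(surface.z)
    cs = ax.contourf(surface.x, surface.y, z, levels=levels, cmap=cmap)
    for lab, (x, y) in surface.attractor_locations.items():
        ax.plot(x, y, "w*", markersize=10)
        ax.annotate(str(lab), (x, y), color="w", textcoords="offset points",
                    xytext=(6, 6))
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.figure.colorbar(cs, ax=ax, label="quasi-potential elevation")
    return ax


def plot_population(overlay, ax=None, **scatter_kw):
    """Scatter a jittered cell population (as returned by jitter_overlay)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scatter_kw.setdefault("s", 12)
    ax.scatter(overlay["x"], overlay["y"], c=overlay["basin"], **scatter_kw)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    return ax
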