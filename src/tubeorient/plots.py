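"""Optional plots: KDE surface with octile overlay, density curve, histograms."""

from __future__ import annotations

import numpy as np

from .distribution import OrientationDistribution, octile_curves

__all__ = ["plot_kde", "plot_density_profile"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_kde(dist: OrientationDistribution, ax=None, octiles: bool = True):
    """Heatmap of the (depth, angle) density with octile curves overlaid."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.pcolormesh(
        dist.depth_grid, dist.angle_grid, dist.density.T, shading="auto", cmap="viridis"
    )
    if octiles:
        curves = octile_curves(dist)
        for k, curve in enumerate(curves):
            # break the line where it wraps across ±90°
            c = curve.copy()
            jump = np.abs(np.diff(c)) > 90
            c[1:][jump] = np.nan
            ax.plot(dist.depth_grid, c, color="w", lw=0.8, alpha=0.8)
    ax.set_xlabel("normalized depth $z_n$")
    ax.set_ylabel(r"orientation $\alpha$ (deg)")
    ax.set_ylim(-90, 90)
    return ax


def plot_density_profile(density, ax=None):
    """Cell density (per 10^4 µm²) against normalized depth."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(density["z_n"], density["density_per_1e4um2"], lw=1.2)
    ax.set_xlabel("normalized depth $z_n$")
    ax.set_ylabel("cells per $10^4\\,\\mu m^2$")
    ax.set_ylim(bottom=0)
    return ax
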