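"""Depth-resolved orientation distributions and dispersion statistics.

The unit record is an orientation sample (normalized depth z_n, axial angle
α). A product-kernel Gaussian KDE estimates the joint density over
(z_n, α): the depth dimension is linear on [0, 1] with per-sample edge
renormalization, the angle dimension is wrapped with period 180° by
summing kernel replicas at α + 180k. From the gridded density come the
per-depth octile curves (the seven interior k/8 quantiles of the
conditional angle distribution, centered at the conditional axial mean so
the curves stay continuous across ±90°), the per-depth axial circular SD
trace, and the between-stack dispersion table (percentiles of per-stack
SDs at chosen normalized depths). The cell-density profile divides the
per-slice nucleus count inside the ROI by the ROI area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .axial import axial_circular_sd, axial_mean_resultant, wrap_axial
from .roi import AcquisitionGeometry, RoiSpec

__all__ = [
    "KdeParams",
    "OrientationDistribution",
    "kde2d_circular",
    "octile_curves",
    "circular_sd",
    "dispersion_table",
    "cell_density_profile",
]

OCTILES = np.arange(1, 8) / 8.0


@dataclass(frozen=True)
class KdeParams:
    """Bandwidths and grid of the 2D orientation KDE.

    ``bandwidth_depth`` is in normalized-depth units, ``bandwidth_angle``
    in degrees. Defaults trade noise against detail at the sample sizes a
    typical stack yields (a few thousand orientation samples).
    """

    bandwidth_depth: float = 0.08
    bandwidth_angle: float = 6.0
    grid_depth: int = 101
    grid_angle: int = 181

    def __post_init__(self):
        if self.bandwidth_depth <= 0 or self.bandwidth_angle <= 0:
            raise ValueError("bandwidths must be positive")
        if self.grid_depth < 16 or self.grid_angle < 16:
            raise ValueError("grids need at least 16 points")


@dataclass
class OrientationDistribution:
    """Gridded joint density over (normalized depth, angle).

    ``density[i, j]`` is probability per unit normalized depth per degree
    at ``(depth_grid[i], angle_grid[j])``; it integrates to 1 over
    [0, 1] x (-90, 90]. ``sigma_trace`` is the per-depth axial circular SD
    of the conditional angle distribution.
    """

    depth_grid: np.ndarray
    angle_grid: np.ndarray
    density: np.ndarray
    params: KdeParams
    n_samples: int
    sigma_trace: np.ndarray = field(default=None, repr=False)
    mean_trace: np.ndarray = field(default=None, repr=False)

    def conditional(self, i: int) -> np.ndarray:
        """Conditional angle density at depth grid point ``i`` (integrates to 1)."""
        col = self.density[i]
        mass = np.trapezoid(col, self.angle_grid)
        if mass <= 0:
            raise ValueError(f"no probability mass at depth index {i}")
        return col / mass

    def depth_marginal(self) -> np.ndarray:
        return np.trapezoid(self.density, self.angle_grid, axis=1)


def _pooling_weights(stack_ids: Optional[np.ndarray], n: int) -> np.ndarray:
    """Per-sample weights; with stack ids, each stack contributes equal mass."""
    if stack_ids is None:
        return np.full(n, 1.0 / n)
    ids = np.asarray(stack_ids)
    uniq, counts = np.unique(ids, return_counts=True)
    per_stack = dict(zip(uniq, 1.0 / (len(uniq) * counts)))
    return np.array([per_stack[i] for i in ids])


def kde2d_circular(
    z_n,
    alpha_deg,
    params: Optional[KdeParams] = None,
    stack_ids=None,
) -> OrientationDistribution:
    """Product-kernel Gaussian KDE over (normalized depth, axial angle).

    Depth kernels are renormalized over [0, 1] so no mass leaks past the
    wall boundaries; angle kernels are wrapped with period 180° (replicas
    at ±180°, ±360° — truncation is negligible for bandwidths up to 20°).
    With ``stack_ids`` given, every stack contributes equal total mass to
    the pooled estimate.
    """
    params = params or KdeParams()
    z = np.asarray(z_n, dtype=float).ravel()
    a = wrap_axial(np.asarray(alpha_deg, dtype=float).ravel())
    if z.size != a.size:
        raise ValueError("z_n and alpha_deg must have equal length")
    if z.size == 0:
        raise ValueError("no samples")
    if z.size < 2:
        raise ValueError("need at least 2 samples")
    if z.size < 50:
        warnings.warn(
            f"only {z.size} samples: bandwidth selection is unreliable",
            stacklevel=2,
        )
    w = _pooling_weights(stack_ids, z.size)

    zg = np.linspace(0.0, 1.0, params.grid_depth)
    ag = np.linspace(-90.0, 90.0, params.grid_angle)
    hz = params.bandwidth_depth
    ha = params.bandwidth_angle

    # depth kernels with edge renormalization per sample
    gz = np.exp(-0.5 * ((zg[:, None] - z[None, :]) / hz) ** 2) / (
        hz * np.sqrt(2 * np.pi)
    )
    mass_z = stats.norm.cdf((1.0 - z) / hz) - stats.norm.cdf((0.0 - z) / hz)
    gz = gz / mass_z[None, :]

    # wrapped angle kernels
    ga = np.zeros((params.grid_angle, z.size))
    for k in (-2, -1, 0, 1, 2):
        d = ag[:, None] - (a[None, :] + 180.0 * k)
        ga += np.exp(-0.5 * (d / ha) ** 2)
    ga /= ha * np.sqrt(2 * np.pi)

    dens = gz @ (w[:, None] * ga.T)
    total = np.trapezoid(np.trapezoid(dens, ag, axis=1), zg)
    if total > 0:
        dens /= total

    dist = OrientationDistribution(
        depth_grid=zg,
        angle_grid=ag,
        density=dens,
        params=params,
        n_samples=z.size,
    )
    _fill_traces(dist)
    return dist


def _fill_traces(dist: OrientationDistribution) -> None:
    """Per-depth conditional axial mean and circular SD from the grid."""
    nd = len(dist.depth_grid)
    sigma = np.full(nd, np.nan)
    mean = np.full(nd, np.nan)
    # avoid double-counting the duplicated ±90 edge in circular averages
    ang = dist.angle_grid[:-1]
    phi = np.deg2rad(2.0 * ang)
    marg = dist.depth_marginal()
    floor = 1e-4 * marg.max() if marg.max() > 0 else np.inf
    for i in range(nd):
        if marg[i] < floor:
            continue
        wcol = dist.density[i, :-1]
        tot = wcol.sum()
        if tot <= 0:
            continue
        c = np.sum(wcol * np.cos(phi)) / tot
        s = np.sum(wcol * np.sin(phi)) / tot
        rbar = np.hypot(c, s)
        mean[i] = wrap_axial(np.rad2deg(np.arctan2(s, c)) / 2.0)
        sigma[i] = (
            np.inf if rbar < 1e-12 else np.rad2deg(np.sqrt(-2.0 * np.log(rbar))) / 2.0
        )
    dist.sigma_trace = sigma
    dist.mean_trace = mean


def octile_curves(dist: OrientationDistribution) -> np.ndarray:
    """The seven interior k/8 quantile curves of the conditional angle law.

    At each depth the conditional density is re-centered at its axial
    circular mean before the CDF is formed, so the quantiles are taken on
    an interval without a wrap discontinuity and the returned curves are
    continuous across ±90°. Output shape (7, n_depth), wrapped back to
    (-90, 90]; NaN where a depth carries (numerically) no mass.
    """
    nd = len(dist.depth_grid)
    out = np.full((7, nd), np.nan)
    marg = dist.depth_marginal()
    floor = 1e-4 * marg.max() if marg.max() > 0 else np.inf
    ang = dist.angle_grid
    for i in range(nd):
        if marg[i] < floor or not np.isfinite(dist.mean_trace[i]):
            continue
        mu = dist.mean_trace[i]
        cond = dist.conditional(i)
        # offsets from the conditional mean, order the grid by offset
        off = np.atleast_1d(wrap_axial(ang - mu))
        order = np.argsort(off, kind="stable")
        oo = off[order]
        dd = cond[order]
        cdf = np.concatenate([[0.0], np.cumsum((dd[1:] + dd[:-1]) / 2.0 * np.diff(oo))])
        if cdf[-1] <= 0:
            continue
        cdf /= cdf[-1]
        q = np.interp(OCTILES, cdf, oo)
        out[:, i] = wrap_axial(mu + q)
    return out


def circular_sd(angles_deg, weights=None) -> float:
    """Axial circular SD (degrees) of a set of orientation angles.

    Angles are doubled, the mean resultant length gives
    sqrt(-2 ln R̄)/2 back on the axial scale; perfectly uniform input
    (R̄ = 0) returns inf.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 angles")
    return axial_circular_sd(a, weights)


def dispersion_table(
    samples: pd.DataFrame,
    depths: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    window_halfwidth: float = 0.1,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Between-stack variability of orientation dispersion.

    For each stack and normalized depth, the axial circular SD of the
    samples with |z_n - depth| <= window; then the 25th/50th/75th
    percentiles (linear interpolation between order statistics) of those
    per-stack SDs, per depth. Stacks with too few samples in a window are
    excluded from that row. Columns: depth, p25, p50, p75, iqr, n_stacks.
    """
    if samples["stack_id"].nunique() < 2:
        raise ValueError("dispersion table needs at least 2 stacks")
    rows = []
    for depth in depths:
        sds = []
        for _, grp in samples.groupby("stack_id"):
            sel = grp[np.abs(grp["z_n"] - depth) <= window_halfwidth]
            if len(sel) < min_samples:
                continue
            sd = circular_sd(sel["alpha_deg"].to_numpy())
            if np.isfinite(sd):
                sds.append(sd)
        if sds:
            p25, p50, p75 = np.percentile(sds, [25, 50, 75])
        else:
            p25 = p50 = p75 = np.nan
        rows.append((depth, p25, p50, p75, p75 - p25, len(sds)))
    return pd.DataFrame(
        rows, columns=["depth", "p25", "p50", "p75", "iqr", "n_stacks"]
    )


def per_stack_sd(
    samples: pd.DataFrame, depth: float, window_halfwidth: float = 0.1
) -> Dict[str, float]:
    """Axial circular SD per stack in one normalized-depth window."""
    out = {}
    for sid, grp in samples.groupby("stack_id"):
        sel = grp[np.abs(grp["z_n"] - depth) <= window_halfwidth]
        if len(sel) >= 2:
            out[sid] = circular_sd(sel["alpha_deg"].to_numpy())
    return out


def cell_density_profile(
    counts_per_slice: Mapping[int, int],
    rois: Iterable[RoiSpec],
    geometry: AcquisitionGeometry,
    lm_thickness_um: Optional[float] = None,
) -> pd.DataFrame:
    """Cells per 10^4 µm² of ROI area, per slice.

    ``counts_per_slice`` are nucleus counts after area filtering and ROI
    application but before the anisotropy filter (the count of detected
    nuclei, not just the elongated ones). Slices with an invalid ROI are
    omitted. Columns: slice_index, depth_um, z_n, count, roi_area_um2,
    density_per_1e4um2.
    """
    lm = lm_thickness_um or geometry.lm_thickness_um
    rows = []
    for roi in rois:
        if not roi.valid:
            continue
        count = int(counts_per_slice.get(roi.slice_index, 0))
        z_n = np.nan if not lm else min(max(roi.depth_um / lm, 0.0), 1.0)
        rows.append(
            (
                roi.slice_index,
                roi.depth_um,
                z_n,
                count,
                roi.area_um2,
                count / roi.area_um2 * 1e4,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "slice_index",
            "depth_um",
            "z_n",
            "count",
            "roi_area_um2",
            "density_per_1e4um2",
        ],
    )
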