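"""Cluster orientation from the second-moment (inertia) tensor.

Each retained cluster's pixel coordinates define a 2x2 second central
moment matrix (uniform weight per pixel, in µm²). Its eigenvalues
λ1 >= λ2 measure elongation: the ratio λ1/λ2 must exceed a threshold
(default 1.5) to exclude round nuclei, and the eigenvector of λ1 gives the
in-plane orientation. The angle α is measured against the longitudinal
axis of the tube (image x / column direction), positive toward +y
(increasing row index), reduced to the axial representative (-90, 90].
"""

from __future__ import annotations

import math
from typing import Iterable, List

import numpy as np
import pandas as pd

from .axial import wrap_axial
from .cellness import NucleusCluster

__all__ = [
    "moment_tensor",
    "anisotropy_ok",
    "principal_angle",
    "principal_angle_closed_form",
    "collect_samples",
]

SAMPLE_COLUMNS = [
    "stack_id",
    "slice_index",
    "z_um",
    "z_n",
    "alpha_deg",
    "ratio",
    "area_um2",
    "x_um",
    "y_um",
]


def moment_tensor(cluster: NucleusCluster) -> np.ndarray:
    """Second central moment matrix of the cluster's pixels, in (x, y) order.

    Population covariance (divide by n) of the pixel positions in µm.
    Caches the tensor and its ordered eigenvalues on the cluster. Raises on
    single-pixel clusters (rank-0 tensor, orientation meaningless).
    """
    coords = cluster.pixel_coords
    if len(coords) < 2:
        raise ValueError("moment tensor requires at least 2 pixels")
    xy = np.column_stack(
        [coords[:, 1].astype(float), coords[:, 0].astype(float)]
    ) * cluster.pixel_size_um
    centered = xy - xy.mean(axis=0)
    m = centered.T @ centered / len(coords)
    m = 0.5 * (m + m.T)
    evals = np.linalg.eigvalsh(m)  # ascending
    cluster.moment_tensor = m
    cluster.eigvals = (float(evals[1]), float(evals[0]))
    return m


def anisotropy_ok(cluster: NucleusCluster, min_ratio: float = 1.5) -> bool:
    """True iff λ1/λ2 exceeds ``min_ratio`` (λ2 = 0 with λ1 > 0 counts as pass)."""
    if cluster.eigvals is None:
        moment_tensor(cluster)
    l1, l2 = cluster.eigvals
    if l2 <= 0:
        return l1 > 0
    return l1 / l2 > min_ratio


def principal_angle(cluster: NucleusCluster) -> float:
    """Orientation of the cluster's long axis vs. the longitudinal (x) axis.

    Returns α in (-90, 90] degrees from the eigenvector of the largest
    moment-tensor eigenvalue. Raises when λ1 = λ2 (isotropic cluster,
    orientation undefined).
    """
    if cluster.moment_tensor is None:
        moment_tensor(cluster)
    m = cluster.moment_tensor
    evals, evecs = np.linalg.eigh(m)
    if evals[1] - evals[0] <= 1e-15 * max(abs(evals[1]), 1e-30):
        raise ValueError("isotropic cluster: principal angle undefined")
    v = evecs[:, 1]  # eigenvector of the largest eigenvalue, (x, y)
    alpha = wrap_axial(math.degrees(math.atan2(v[1], v[0])))
    cluster.angle_deg = alpha
    return alpha


def principal_angle_closed_form(cluster: NucleusCluster) -> float:
    """Half-angle closed form for the 2x2 eigen-problem (independent check).

    alpha = 0.5 * atan2(2 cov_xy, cov_xx - cov_yy), the textbook principal
    axis of a 2D covariance; used as the oracle against the
    eigen-decomposition route.
    """
    if cluster.moment_tensor is None:
        moment_tensor(cluster)
    m = cluster.moment_tensor
    return wrap_axial(
        math.degrees(0.5 * math.atan2(2.0 * m[0, 1], m[0, 0] - m[1, 1]))
    )


def collect_samples(
    clusters: Iterable[NucleusCluster],
    stack_id: str,
    slice_spacing_um: float,
    lm_thickness_um: float,
    geometry=None,
) -> pd.DataFrame:
    """Build the orientation-sample table for one stack.

    One row per cluster that survived the ROI, area, and anisotropy
    filters: depth below the outer surface, normalized depth z_n = z /
    muscle-layer thickness clipped to [0, 1], angle α, eigen-ratio, area,
    and the centroid position (x along the tube axis; y lateral from the
    apex line when a geometry is given, else from row 0).
    """
    if lm_thickness_um <= 0:
        raise ValueError("lm_thickness_um must be positive")
    rows = []
    for cl in clusters:
        if cl.angle_deg is None:
            principal_angle(cl)
        l1, l2 = cl.eigvals
        ratio = float(np.inf) if l2 <= 0 else l1 / l2
        z = cl.slice_index * slice_spacing_um
        x_um = cl.centroid_px[1] * cl.pixel_size_um
        if geometry is not None:
            y_um = geometry.lateral_offset_um(cl.centroid_px[0])
        else:
            y_um = cl.centroid_px[0] * cl.pixel_size_um
        rows.append(
            (
                stack_id,
                cl.slice_index,
                z,
                min(max(z / lm_thickness_um, 0.0), 1.0),
                cl.angle_deg,
                ratio,
                cl.area_um2,
                x_um,
                y_um,
            )
        )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
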