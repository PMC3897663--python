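"""Depth-dependent region of interest under a cylindrical-wall model.

Flat optical sections of a curved tube mix tissue from different wall
depths: a point at lateral offset ``y`` from the apex line of a cylinder of
outer radius ``R``, imaged in the plane at nominal depth ``z`` below the
topmost outer surface, actually sits at wall depth

    z_wall(y) = R - sqrt((R - z)^2 + y^2)  <=  z.

Two constraints define the usable band around the apex line:

* crosstalk: keep only points whose wall depth is within ``delta_max`` of
  the nominal depth, giving half-width
  ``w_c = sqrt((R - z + delta_max)^2 - (R - z)^2)``;
* filling: keep only points inside the tissue (the plane exits the outer
  surface at ``w_f = sqrt(z (2R - z))``), so cell densities can be formed
  as count / area.

The effective ROI is the band ``|y| <= min(w_c, w_f, field half-width)``
running parallel to the tube's longitudinal (x) axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "AcquisitionGeometry",
    "RoiSpec",
    "crosstalk_halfwidth",
    "filling_halfwidth",
    "effective_roi",
    "apply_roi",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of one acquired stack.

    Slices are ordered from the adventitial (outer) side inward; slice 0 is
    the shallowest plane, tangent to the outer surface. The longitudinal
    axis of the tube is the image x (column) direction; the lateral axis is
    the image y (row) direction.
    """

    outer_radius_um: float
    wall_thickness_um: float
    pixel_size_um: float
    slice_spacing_um: float
    field_size_px: tuple  # (ny rows, nx cols)
    n_slices: int
    apex_offset_px: float = 0.0
    lm_thickness_um: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.wall_thickness_um < self.outer_radius_um):
            raise ValueError("need 0 < wall thickness < outer radius")
        if self.pixel_size_um <= 0 or self.slice_spacing_um <= 0:
            raise ValueError("pixel size and slice spacing must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def field_halfwidth_um(self) -> float:
        ny = self.field_size_px[0]
        return ny * self.pixel_size_um / 2.0

    @property
    def field_length_um(self) -> float:
        nx = self.field_size_px[1]
        return nx * self.pixel_size_um

    def slice_depth_um(self, slice_index: int) -> float:
        return slice_index * self.slice_spacing_um

    def lateral_offset_um(self, row: float) -> float:
        """Signed lateral offset (µm) of a row coordinate from the apex line."""
        ny = self.field_size_px[0]
        center = (ny - 1) / 2.0 + self.apex_offset_px
        return (row - center) * self.pixel_size_um


@dataclass(frozen=True)
class RoiSpec:
    slice_index: int
    depth_um: float
    crosstalk_halfwidth_um: float
    filling_halfwidth_um: float
    halfwidth_um: float
    area_um2: float
    valid: bool


def crosstalk_halfwidth(z: float, R: float, delta_max: float) -> float:
    """Lateral offset at which wall depth deviates by ``delta_max`` from ``z``."""
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    if z < 0 or z > R:
        raise ValueError("need 0 <= z <= R")
    a = R - z
    return math.sqrt((a + delta_max) ** 2 - a**2)


def filling_halfwidth(z: float, R: float) -> float:
    """Lateral offset at which the plane at depth ``z`` exits the outer surface."""
    if z < 0 or z > R:
        raise ValueError("need 0 <= z <= R")
    return math.sqrt(z * (2.0 * R - z))


def effective_roi(
    geometry: AcquisitionGeometry, slice_index: int, delta_max: float = 2.0
) -> RoiSpec:
    """Effective ROI band for one slice: min of the two constraints and the field."""
    z = geometry.slice_depth_um(slice_index)
    R = geometry.outer_radius_um
    if z > R:
        # plane beyond the cylinder axis region of validity; no usable band
        return RoiSpec(slice_index, z, 0.0, 0.0, 0.0, 0.0, False)
    w_c = crosstalk_halfwidth(z, R, delta_max)
    w_f = filling_halfwidth(z, R)
    w = min(w_c, w_f, geometry.field_halfwidth_um)
    valid = w > 0
    area = 2.0 * w * geometry.field_length_um if valid else 0.0
    return RoiSpec(slice_index, z, w_c, w_f, w, area, valid)


def apply_roi(clusters, roi: RoiSpec, geometry: AcquisitionGeometry):
    """Retain clusters whose centroid lies inside the ROI band (closed bounds).

    Sets each cluster's ``in_roi`` flag; returns the retained subset.
    Raises if a cluster does not belong to ``roi.slice_index``.
    """
    kept = []
    for cl in clusters:
        if cl.slice_index != roi.slice_index:
            raise ValueError(
                f"cluster from slice {cl.slice_index} passed to ROI of "
                f"slice {roi.slice_index}"
            )
        off = geometry.lateral_offset_um(cl.centroid_px[0])
        # closed boundary, robust to rounding in the offset arithmetic
        tol = 1e-9 * max(1.0, roi.halfwidth_um)
        inside = bool(roi.valid and abs(off) <= roi.halfwidth_um + tol)
        cl.in_roi = inside
        if inside:
            kept.append(cl)
    return kept
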