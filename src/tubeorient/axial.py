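"""Axial (180-degree periodic) circular statistics.

Nuclear orientations are *axial* data: an orientation alpha and alpha + 180
degrees are the same physical orientation. The standard treatment (Fisher,
Mardia) doubles the angles, applies ordinary circular statistics on the
doubled scale, and halves the results. All public functions here work in
degrees with the axial representative kept in (-90, 90].
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

__all__ = [
    "wrap_axial",
    "axial_mean_resultant",
    "axial_mean",
    "axial_circular_sd",
    "kappa_for_axial_sd",
    "axial_sd_for_kappa",
    "axial_difference",
]


def wrap_axial(angle_deg):
    """Reduce angles (degrees) to the axial representative in (-90, 90]."""
    a = np.asarray(angle_deg, dtype=float)
    w = ((a + 90.0) % 180.0) - 90.0  # in [-90, 90)
    w = np.where(w == -90.0, 90.0, w)
    if np.isscalar(angle_deg) or w.ndim == 0:
        return float(w)
    return w


def axial_mean_resultant(angles_deg, weights=None):
    """Mean resultant length and mean direction of axial data.

    Returns ``(R_bar, mean_deg)`` where ``R_bar`` is the mean resultant
    length on the doubled scale and ``mean_deg`` the axial mean in
    (-90, 90].
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("no angles given")
    phi = np.deg2rad(2.0 * a)
    if weights is None:
        c = np.mean(np.cos(phi))
        s = np.mean(np.sin(phi))
    else:
        w = np.asarray(weights, dtype=float)
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("weights must have positive sum")
        c = np.sum(w * np.cos(phi)) / wsum
        s = np.sum(w * np.sin(phi)) / wsum
    rbar = float(np.hypot(c, s))
    mean = wrap_axial(np.rad2deg(np.arctan2(s, c)) / 2.0)
    return rbar, mean


def axial_mean(angles_deg, weights=None):
    """Axial circular mean in (-90, 90] degrees."""
    return axial_mean_resultant(angles_deg, weights)[1]


def axial_circular_sd(angles_deg, weights=None):
    """Axial circular standard deviation in degrees.

    Angles are doubled, the circular SD ``sqrt(-2 ln R_bar)`` is evaluated on
    the doubled scale, then halved and converted to degrees. Perfectly
    uniform data (``R_bar`` = 0) has undefined dispersion and returns
    ``numpy.inf``.
    """
    rbar, _ = axial_mean_resultant(angles_deg, weights)
    if rbar < 1e-12:
        return float(np.inf)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(rbar))) / 2.0)


def axial_sd_for_kappa(kappa):
    """Axial circular SD (degrees) of a von Mises law with given concentration.

    The von Mises distribution lives on the doubled-angle scale; its mean
    resultant length is ``I1(kappa)/I0(kappa)``.
    """
    if kappa <= 0:
        return float(np.inf)
    rbar = special.i1e(kappa) / special.i0e(kappa)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(rbar))) / 2.0)


def kappa_for_axial_sd(sd_deg):
    """Von Mises concentration whose axial circular SD equals ``sd_deg``.

    Returns ``inf`` for sd 0 (degenerate point mass) and 0 for infinite sd
    (axial-uniform). The inversion solves ``I1(k)/I0(k) = exp(-s^2/2)`` with
    ``s`` the doubled-scale SD in radians.
    """
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    if sd_deg == 0:
        return float(np.inf)
    if not np.isfinite(sd_deg):
        return 0.0
    s = np.deg2rad(2.0 * sd_deg)
    rbar = np.exp(-0.5 * s * s)
    if rbar < 1e-10:
        return 0.0

    def f(k):
        return special.i1e(k) / special.i0e(k) - rbar

    hi = max(10.0, 2.0 / (1.0 - rbar))
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12))


def axial_difference(a_deg, b_deg):
    """Smallest axial separation |a - b| in degrees, in [0, 90]."""
    d = abs(wrap_axial(a_deg) - wrap_axial(b_deg)) % 180.0
    return float(min(d, 180.0 - d))
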