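"""Orientation KDE, octiles, circular SD, dispersion table, density profile."""

import numpy as np
import pandas as pd
import pytest

import tubeorient as to
from tubeorient.axial import wrap_axial
from tubeorient.distribution import (
    KdeParams,
    cell_density_profile,
    circular_sd,
    dispersion_table,
    kde2d_circular,
    octile_curves,
)
from tubeorient.roi import AcquisitionGeometry, effective_roi


def _integral(dist):
    return np.trapezoid(
        np.trapezoid(dist.density, dist.angle_grid, axis=1), dist.depth_grid
    )


def test_kde_mass_is_one_and_nonnegative(rng):
    z = rng.uniform(0, 1, 500)
    a = rng.normal(0, 20, 500)
    dist = kde2d_circular(z, wrap_axial(a))
    assert (dist.density >= 0).all()
    assert _integral(dist) == pytest.approx(1.0, abs=1e-3)


def test_kde_mass_robust_to_edge_heavy_samples(rng):
    # all samples at the depth boundary: renormalization keeps mass = 1
    z = np.zeros(200)
    a = rng.normal(0, 10, 200)
    dist = kde2d_circular(z, wrap_axial(a))
    assert _integral(dist) == pytest.approx(1.0, abs=1e-3)


def test_kde_ridge_at_zero_for_longitudinal_samples(rng):
    z = rng.uniform(0, 1, 2000)
    a = rng.normal(0, 3, 2000)
    dist = kde2d_circular(z, wrap_axial(a))
    marg = np.trapezoid(dist.density, dist.depth_grid, axis=0)
    assert abs(dist.angle_grid[np.argmax(marg)]) <= 2.0


def test_kde_wraps_across_axial_boundary(rng):
    z = rng.uniform(0, 1, 500)
    a = np.full(500, 89.0)
    dist = kde2d_circular(z, a)
    j_neg = np.argmin(np.abs(dist.angle_grid + 89.0))
    assert dist.density[:, j_neg].max() > 0.01 * dist.density.max()
    # densities at the two representations of the same angle agree
    assert np.allclose(dist.density[:, 0], dist.density[:, -1], rtol=1e-9)


def test_kde_invariant_under_180_degree_shift(rng):
    z = rng.uniform(0, 1, 300)
    a = wrap_axial(rng.normal(20, 25, 300))
    d1 = kde2d_circular(z, a)
    d2 = kde2d_circular(z, wrap_axial(a + 180.0))
    assert np.allclose(d1.density, d2.density, rtol=1e-10, atol=1e-14)


def test_kde_warns_on_tiny_sample(rng):
    with pytest.warns(UserWarning, match="samples"):
        kde2d_circular(np.array([0.1, 0.9]), np.array([0.0, 10.0]))
    with pytest.raises(ValueError):
        kde2d_circular(np.array([]), np.array([]))


def test_kde_angle_marginal_matches_closed_form_axial_von_mises(rng):
    """ISE against the true axial von Mises density at sigma = 25 degrees."""
    from scipy.special import i0

    sd = 25.0
    n = 10_000
    a = to.sample_axial_angle(0.0, sd, rng, size=n)
    z = rng.uniform(0, 1, n)
    dist = kde2d_circular(z, a, KdeParams(bandwidth_angle=5.0))
    est = np.trapezoid(dist.density, dist.depth_grid, axis=0)
    kappa = to.kappa_for_axial_sd(sd)
    phi = np.deg2rad(2.0 * dist.angle_grid)
    true = np.exp(kappa * np.cos(phi)) / (2 * np.pi * i0(kappa)) * 2 * np.pi / 180.0
    ise = np.trapezoid((est - true) ** 2, dist.angle_grid)
    assert ise < 1e-4


def test_octiles_symmetric_unimodal_median_is_zero(rng):
    z = rng.uniform(0, 1, 5000)
    a = wrap_axial(rng.normal(0, 15, 5000))
    dist = kde2d_circular(z, a)
    curves = octile_curves(dist)
    assert curves.shape == (7, len(dist.depth_grid))
    med = curves[3]
    assert np.nanmax(np.abs(med)) < 3.0
    # octile ordering: non-crossing in centered coordinates
    for i in range(len(dist.depth_grid)):
        col = curves[:, i]
        if np.isnan(col).any():
            continue
        centered = wrap_axial(col - dist.mean_trace[i])
        assert np.all(np.diff(centered) > 0)


def test_octiles_of_uniform_conditional(rng):
    z = rng.uniform(0, 1, 20000)
    a = to.sample_axial_angle(0.0, np.inf, rng, size=20000)
    dist = kde2d_circular(z, a)
    curves = octile_curves(dist)
    mid = len(dist.depth_grid) // 2
    col = np.sort(wrap_axial(curves[:, mid] - dist.mean_trace[mid]))
    expected = np.array([-67.5, -45.0, -22.5, 0.0, 22.5, 45.0, 67.5])
    assert np.allclose(col, expected, atol=6.0)


def test_circular_sd_basic_cases():
    assert circular_sd([12.0, 12.0, 12.0]) == pytest.approx(0.0, abs=1e-7)
    assert np.isinf(circular_sd([45.0, -45.0, 45.0, -45.0]))
    with pytest.raises(ValueError):
        circular_sd([1.0])


def test_circular_sd_recovers_wrapped_normal(rng):
    # independent sampling route: wrapped normal on the doubled scale
    sd = 25.0
    phi = rng.normal(0.0, np.deg2rad(2 * sd), size=100_000)
    a = wrap_axial(np.rad2deg(phi) / 2.0)
    assert circular_sd(a) == pytest.approx(sd, abs=0.5)


def test_dispersion_table_hand_percentiles():
    rng = np.random.default_rng(5)
    frames = []
    for sid, sd in [("a", 20.0), ("b", 30.0), ("c", 40.0)]:
        a = to.sample_axial_angle(0.0, sd, rng, size=4000)
        frames.append(
            pd.DataFrame(
                {"stack_id": sid, "z_n": rng.uniform(0, 1, 4000), "alpha_deg": a}
            )
        )
    samples = pd.concat(frames, ignore_index=True)
    table = dispersion_table(samples, depths=(0.5,), window_halfwidth=0.5)
    row = table.iloc[0]
    # per-stack SDs ~ (20, 30, 40): linear-interpolation percentiles (25,30,35)
    assert row.p25 == pytest.approx(25.0, abs=1.5)
    assert row.p50 == pytest.approx(30.0, abs=1.5)
    assert row.p75 == pytest.approx(35.0, abs=1.5)
    assert row.p25 <= row.p50 <= row.p75


def test_dispersion_table_identical_stacks_equal_percentiles(rng):
    a = to.sample_axial_angle(0.0, 25.0, rng, size=2000)
    z = rng.uniform(0, 1, 2000)
    frames = [
        pd.DataFrame({"stack_id": s, "z_n": z, "alpha_deg": a}) for s in "abc"
    ]
    table = dispersion_table(pd.concat(frames, ignore_index=True), depths=(0.5,),
                             window_halfwidth=0.5)
    row = table.iloc[0]
    assert row.p25 == pytest.approx(row.p75)
    assert row.iqr == pytest.approx(0.0, abs=1e-9)


def test_dispersion_table_needs_two_stacks(rng):
    df = pd.DataFrame(
        {"stack_id": "only", "z_n": rng.uniform(0, 1, 100),
         "alpha_deg": rng.uniform(-90, 90, 100)}
    )
    with pytest.raises(ValueError):
        dispersion_table(df)


def test_cell_density_profile_arithmetic():
    g = AcquisitionGeometry(150.0, 55.0, 0.5, 0.5, (512, 512), 40,
                            lm_thickness_um=55.0)
    rois = [effective_roi(g, k, 2.0) for k in range(5)]
    counts = {k: 10 for k in range(5)}
    prof = cell_density_profile(counts, rois, g)
    # slice 0 has an invalid ROI and is omitted
    assert 0 not in prof.slice_index.values
    for _, row in prof.iterrows():
        assert row.density_per_1e4um2 == pytest.approx(10 / row.roi_area_um2 * 1e4)


def test_cell_density_profile_empty_slice_zero():
    g = AcquisitionGeometry(150.0, 55.0, 0.5, 0.5, (512, 512), 40,
                            lm_thickness_um=55.0)
    rois = [effective_roi(g, 3, 2.0)]
    prof = cell_density_profile({}, rois, g)
    assert prof.density_per_1e4um2.iloc[0] == 0.0
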