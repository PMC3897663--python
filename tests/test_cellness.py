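"""Cellness filtering, binarization, clustering, and area filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tubeorient.cellness import (
    CellnessParams,
    binarize,
    cellness_filter,
    extract_clusters,
    filter_by_area,
)

PX = 0.5
PARAMS = CellnessParams()


def gaussian_blob(shape=(96, 96), center=(48, 48), sx=6.0, sy=2.0, theta=0.0, amp=100.0):
    """Anisotropic Gaussian blob; sx along x (cols) before rotation by theta."""
    rr, cc = np.mgrid[: shape[0], : shape[1]].astype(float)
    dy, dx = rr - center[0], cc - center[1]
    th = np.deg2rad(theta)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def test_constant_image_gives_zero_map():
    img = np.full((64, 64), 37.0)
    assert not cellness_filter(img, PARAMS, PX).any()


def test_offset_invariance():
    img = gaussian_blob()
    a = cellness_filter(img, PARAMS, PX)
    b = cellness_filter(img + 250.0, PARAMS, PX)
    assert np.allclose(a, b, atol=1e-10)


def test_blob_argmax_at_center():
    img = gaussian_blob(center=(40, 55))
    cmap = cellness_filter(img, PARAMS, PX)
    peak = np.unravel_index(np.argmax(cmap), cmap.shape)
    assert abs(peak[0] - 40) <= 1 and abs(peak[1] - 55) <= 1


def test_dark_structure_suppressed():
    img = 100.0 - gaussian_blob()  # dark elongated structure on bright bg
    cmap = cellness_filter(img, PARAMS, PX)
    # the valley core (within one short-axis sigma) has h2 > 0: zeroed
    assert cmap[47:50, 40:57].max() == 0.0


def test_non_finite_input_raises():
    img = np.ones((32, 32))
    img[3, 3] = np.nan
    with pytest.raises(ValueError):
        cellness_filter(img, PARAMS, PX)


def test_ninety_degree_rotation_equivariance():
    img = gaussian_blob(center=(30, 60), theta=25.0)
    a = cellness_filter(np.rot90(img), PARAMS, PX)
    b = np.rot90(cellness_filter(img, PARAMS, PX))
    assert np.allclose(a, b, atol=1e-10)


def test_matches_skimage_frangi_ridge_location():
    """Independent cross-check against scikit-image's Frangi filter.

    Same single-scale bright-ridge setup on both sides; the two responses
    must agree on where the structure is (high correlation on the
    normalized maps), though internal normalization details differ.
    """
    from skimage.filters import frangi

    img = gaussian_blob(center=(48, 40), sx=10, sy=2.5, theta=30.0)
    ours = cellness_filter(img, PARAMS, PX)
    theirs = frangi(
        img, sigmas=[PARAMS.sigma_kernel_um / PX], beta=PARAMS.beta,
        black_ridges=False,
    )
    theirs = theirs / theirs.max()
    corr = np.corrcoef(ours.ravel(), theirs.ravel())[0, 1]
    assert corr > 0.95
    assert np.unravel_index(np.argmax(ours), ours.shape) == np.unravel_index(
        np.argmax(theirs), theirs.shape
    )


def test_binarize_selects_above_threshold():
    m = np.array([[0.2, 0.8], [0.8, 0.2]])
    mask = binarize(m, 0.5)
    assert mask.tolist() == [[False, True], [True, False]]
    assert not binarize(np.zeros((4, 4)), 0.3).any()


@given(
    hnp.arrays(float, (16, 16), elements=st.floats(0, 1)),
    st.floats(0.05, 0.95),
    st.floats(0.05, 0.95),
)
def test_mask_size_non_increasing_in_threshold(m, t1, t2):
    lo, hi = min(t1, t2), max(t1, t2)
    assert binarize(m, hi).sum() <= binarize(m, lo).sum()


def test_connectivity_of_diagonal_pixels():
    mask = np.zeros((5, 5), bool)
    mask[1, 1] = mask[2, 2] = True
    assert len(extract_clusters(mask, PX, connectivity=8)) == 1
    assert len(extract_clusters(mask, PX, connectivity=4)) == 2


def test_cluster_area_of_solid_square():
    mask = np.zeros((7, 7), bool)
    mask[2:5, 2:5] = True
    (cl,) = extract_clusters(mask, PX)
    assert cl.area_um2 == pytest.approx(9 * 0.25)
    assert cl.centroid_px == pytest.approx((3.0, 3.0))


@given(hnp.arrays(bool, (24, 24)))
def test_cluster_areas_conserve_foreground(mask):
    clusters = extract_clusters(mask, PX)
    assert sum(c.n_pixels for c in clusters) == int(mask.sum())


def test_filter_by_area_bounds():
    mask = np.zeros((40, 80), bool)
    mask[2, 2:6] = True  # 4 px  = 1 µm²
    mask[10:18, 10:20] = True  # 80 px = 20 µm²
    mask[25:39, 30:75] = True  # 630 px ~ 157 µm²
    clusters = extract_clusters(mask, PX)
    kept = filter_by_area(clusters, 5.0, 100.0)
    assert len(kept) == 1
    assert kept[0].area_um2 == pytest.approx(20.0)
    assert len(filter_by_area(clusters, 0.0, np.inf)) == 3


def test_area_filter_keeps_nuclei_rejects_clutter(clean_spec):
    """On a noiseless synthetic slice, area bounds keep nuclei, drop specks."""
    import dataclasses

    import tubeorient as to

    spec = dataclasses.replace(clean_spec, clutter_count_per_slice=6)
    stack, truth = to.generate_stack(spec)
    k = 40  # a mid-depth slice
    cmap = cellness_filter(stack.data[k], PARAMS, spec.pixel_size_um)
    clusters = extract_clusters(binarize(cmap, PARAMS.threshold), spec.pixel_size_um,
                                slice_index=k)
    kept = filter_by_area(clusters, PARAMS.area_min_um2, PARAMS.area_max_um2)
    # no kept cluster coincides with a clutter-only location: clutter blobs
    # are far below the lower area bound after filtering
    assert all(c.area_um2 >= PARAMS.area_min_um2 for c in kept)
    z = k * spec.pixel_size_um
    px = spec.pixel_size_um
    ny, nx = spec.field_size_px
    gt = truth.nuclei
    infield = gt[
        (gt.x_um >= 0)
        & (gt.x_um <= nx * px)
        & (gt.y_um.abs() <= ny * px / 2.0)
    ]
    near = infield[np.abs(infield.z_um - z) <= spec.nucleus_depth_axis_um / 2.0]
    assert len(kept) > 0.5 * len(near)  # detects the bulk of nearby nuclei


def test_detected_count_tracks_ground_truth_on_clean_stack(clean_spec):
    """Per-slice retained clusters track the nuclei intersecting each slice.

    A nucleus is taken to intersect a slice when the plane lies within half
    a depth axis of its center. Counts are pooled over mid-wall slices
    (single-slice counts are Poisson-noisy).
    """
    import tubeorient as to

    stack, truth = to.generate_stack(clean_spec)
    px = clean_spec.pixel_size_um
    half = clean_spec.nucleus_depth_axis_um / 2.0
    # only nuclei whose center lies inside the imaged field render fully
    ny, nx = clean_spec.field_size_px
    gt = truth.nuclei
    gt = gt[
        (gt.x_um >= 0)
        & (gt.x_um <= nx * px)
        & (gt.y_um.abs() <= ny * px / 2.0)
    ]
    detected, expected = 0, 0
    for k in range(20, 50, 3):
        cmap = cellness_filter(stack.data[k], PARAMS, px)
        clusters = extract_clusters(binarize(cmap, PARAMS.threshold), px, slice_index=k)
        kept = filter_by_area(clusters, PARAMS.area_min_um2, PARAMS.area_max_um2)
        detected += len(kept)
        z = k * px
        expected += int((np.abs(gt.z_um - z) <= half).sum())
    assert detected == pytest.approx(expected, rel=0.10)
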