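"""Unit and oracle tests for the shared imaging primitives."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from c9quant.imaging_core import (
    BinaryMask,
    ChannelImage,
    boundary_distance,
    circularity,
    filter_by_circularity,
    label_regions,
    local_maxima,
    percent_positive_area,
    skeleton_length,
    skeletonize_mask,
    threshold_global,
    tophat_subtract,
)

PX = 0.1


def img(a, px=PX, name=""):
    return ChannelImage(np.asarray(a, float), px, name)


def mask(a, px=PX):
    return BinaryMask(np.asarray(a, bool), px)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def brute_otsu(pixels):
    """Exhaustive inter-class-variance scan over all candidate thresholds."""
    values = np.unique(pixels)
    best_t, best_var = values[0], -1.0
    for t in values[:-1]:
        lo, hi = pixels[pixels <= t], pixels[pixels > t]
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def test_otsu_matches_exhaustive_scan_on_bimodal_image():
    rng = np.random.default_rng(0)
    pixels = np.full(100, 10.0)
    pixels[rng.choice(100, 10, replace=False)] = 100.0
    res = threshold_global(img(pixels.reshape(10, 10)), "otsu")
    assert res.mask.pixels.sum() == 10
    assert (img(pixels.reshape(10, 10)).pixels[res.mask.pixels] == 100).all()
    t_oracle = brute_otsu(pixels)
    assert t_oracle <= res.threshold < 100


def test_constant_image_otsu_degenerate_flag():
    with pytest.warns(UserWarning):
        res = threshold_global(img(np.zeros((8, 8))), "otsu")
    assert res.degenerate
    assert not res.mask.pixels.any()


def test_fixed_threshold_cut():
    pixels = np.array([[10.0, 100.0], [10.0, 100.0]])
    res = threshold_global(img(pixels), "fixed:50")
    assert res.mask.pixels.tolist() == [[False, True], [False, True]]
    assert not res.degenerate


def test_quantile_threshold():
    pixels = np.arange(100.0).reshape(10, 10)
    res = threshold_global(img(pixels), "quantile:0.9")
    assert res.mask.pixels.sum() == 10  # strictly above the 90th percentile


# ---------------------------------------------------------------------------
# labeling and circularity
# ---------------------------------------------------------------------------


def test_label_two_squares_geometry():
    m = np.zeros((12, 12), bool)
    m[1:4, 1:4] = True
    m[7:10, 7:10] = True
    regs = label_regions(mask(m))
    assert regs.n_regions == 2
    for r in regs.regions:
        assert r.area_um2 == pytest.approx(9 * PX**2)


def test_label_empty_mask():
    assert label_regions(mask(np.zeros((5, 5), bool))).n_regions == 0


def test_connectivity_4_vs_8_on_diagonal_touch():
    m = np.zeros((4, 4), bool)
    m[0, 0] = m[1, 1] = True
    assert label_regions(mask(m), connectivity=4).n_regions == 2
    assert label_regions(mask(m), connectivity=8).n_regions == 1


def test_circularity_analytic_shapes():
    # disc: isoperimetric identity; square: 4*pi*s^2/(4s)^2 = pi/4
    assert circularity(np.pi * 4.0**2, 2 * np.pi * 4.0) == pytest.approx(1.0)
    assert circularity(25.0, 20.0) == pytest.approx(np.pi / 4)
    with pytest.raises(ValueError):
        circularity(0.0, 5.0)


def boundary_chain_length(m):
    """Brute-force boundary-length oracle: trace the 8-connected contour of
    a single filled region and sum unit / sqrt(2) chain steps."""
    from scipy import ndimage

    boundary = m & ~ndimage.binary_erosion(m)
    pts = np.argwhere(boundary)
    # order boundary pixels by angle around the centroid (valid for convex
    # rasterized shapes such as discs)
    center = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 0] - center[0], pts[:, 1] - center[1])
    ordered = pts[np.argsort(ang)]
    diffs = np.abs(np.diff(np.vstack([ordered, ordered[:1]]), axis=0))
    steps = np.where(diffs.max(axis=1) <= 1, np.hypot(diffs[:, 0], diffs[:, 1]), 0.0)
    return steps.sum()


def test_rasterized_disc_circularity_near_one():
    from skimage.draw import disk as sk_disk

    m = np.zeros((64, 64), bool)
    rr, cc = sk_disk((32, 32), 20)
    m[rr, cc] = True
    regs = label_regions(mask(m, px=1.0))
    circ = regs.regions[0].circularity_raw
    assert abs(circ - 1.0) <= 0.1
    # independent oracle: contour-chain perimeter on the same raster
    perim_oracle = boundary_chain_length(m)
    circ_oracle = 4 * np.pi * m.sum() / perim_oracle**2
    assert abs(circ - circ_oracle) <= 0.1


def test_single_pixel_region_circularity_is_one():
    m = np.zeros((3, 3), bool)
    m[1, 1] = True
    regs = label_regions(mask(m))
    assert regs.regions[0].circularity == 1.0


def test_filter_by_circularity_disc_vs_line():
    from skimage.draw import disk as sk_disk

    m = np.zeros((64, 64), bool)
    rr, cc = sk_disk((20, 20), 8)
    m[rr, cc] = True
    m[50, 10:50] = True  # 1x40 line
    regs = label_regions(mask(m))
    circs = sorted(r.circularity for r in regs.regions)
    assert circs[0] < 0.5 < 0.6 <= circs[1] + 1e-9
    kept = filter_by_circularity(regs, 0.6)
    assert kept.pixels.sum() == len(rr)
    assert not kept.pixels[50, 10:50].any()


def test_filter_by_circularity_boundary_cases():
    m = np.zeros((10, 10), bool)
    m[2:5, 2:5] = True
    regs = label_regions(mask(m))
    assert filter_by_circularity(regs, 0.0).pixels.sum() == m.sum()  # identity
    assert filter_by_circularity(regs, 1.0 + 0.05).pixels.sum() == 0


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------


def test_skeletonize_empty_and_thin_line():
    empty = skeletonize_mask(mask(np.zeros((5, 5), bool)))
    assert not empty.pixels.any()
    m = np.zeros((5, 20), bool)
    m[2, 2:18] = True
    skel = skeletonize_mask(mask(m))
    assert (skel.pixels == m).all()  # already one pixel wide


def test_skeletonize_wide_bar_yields_single_spanning_path():
    m = np.zeros((15, 70), bool)
    m[5:10, 5:65] = True  # 5-px-wide bar, 60 px long
    skel = skeletonize_mask(mask(m))
    assert skel.pixels.sum() <= m.sum()
    assert (skel.pixels & ~m).sum() == 0  # contractive
    # brute-force path search: one component, spans the bar's long axis
    pts = set(map(tuple, np.argwhere(skel.pixels)))
    cols = [c for _, c in pts]
    assert max(cols) - min(cols) >= 50
    start = min(pts, key=lambda p: p[1])
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                q = (r + dr, c + dc)
                if q in pts and q not in seen:
                    seen.add(q)
                    stack.append(q)
    assert seen == pts  # single 8-connected path
    # one pixel wide: interior columns contain exactly one skeleton pixel
    per_col = skel.pixels[:, min(cols) + 2 : max(cols) - 1].sum(axis=0)
    assert (per_col == 1).all()


@pytest.mark.parametrize(
    "builder,expected",
    [
        (lambda m: m.__setitem__((2, slice(0, 50)), True), 49 * PX),
        (lambda m: [m.__setitem__((i, i), True) for i in range(50)],
         49 * np.sqrt(2) * PX),
        (lambda m: None, 0.0),
    ],
    ids=["horizontal", "diagonal", "empty"],
)
def test_skeleton_length_edge_model(builder, expected):
    m = np.zeros((60, 60), bool)
    builder(m)
    assert skeleton_length(mask(m)) == pytest.approx(expected)


def test_skeleton_length_rotation_and_flip_invariance():
    rng = np.random.default_rng(3)
    m = np.zeros((40, 40), bool)
    r, c = 20, 5
    m[r, c] = True
    for _ in range(60):
        dr, dc = rng.choice([(-1, 0), (0, 1), (-1, 1), (1, 1)])
        r, c = np.clip(r + dr, 0, 39), np.clip(c + dc, 0, 39)
        m[r, c] = True
    base = skeleton_length(mask(m))
    for variant in (np.rot90(m), np.rot90(m, 2), np.fliplr(m), np.flipud(m)):
        assert skeleton_length(mask(variant.copy())) == pytest.approx(base)


# ---------------------------------------------------------------------------
# percent positive area
# ---------------------------------------------------------------------------


def test_percent_positive_area_basic_and_errors():
    m = np.zeros((10, 10), bool)
    m[:5, :5] = True
    assert percent_positive_area(mask(m)) == pytest.approx(25.0)
    assert percent_positive_area(mask(np.zeros((10, 10), bool))) == 0.0
    assert percent_positive_area(mask(m), mask(m)) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        percent_positive_area(mask(m), mask(np.zeros((10, 10), bool)))


# ---------------------------------------------------------------------------
# local maxima
# ---------------------------------------------------------------------------


def test_two_isolated_peaks_detected():
    a = np.zeros((30, 30))
    a[5, 5] = 100.0
    a[20, 22] = 100.0
    pts = local_maxima(img(a), min_distance_um=0.3, min_prominence=50)
    assert len(pts) == 2
    assert {tuple(p) for p in pts.points} == {(5.0, 5.0), (20.0, 22.0)}


def test_flat_image_has_no_maxima():
    assert len(local_maxima(img(np.ones((20, 20))), 0.3, 0.0)) == 0


def test_plateau_yields_single_centroid_point():
    a = np.zeros((20, 20))
    a[8:11, 8:11] = 50.0  # 3x3 plateau
    pts = local_maxima(img(a), 0.2, 10)
    assert len(pts) == 1
    assert tuple(pts.points[0]) == (9.0, 9.0)


def test_planted_peaks_all_recovered_no_spurious():
    rng = np.random.default_rng(11)
    a = rng.normal(10.0, 1.0, (200, 200)).clip(0)
    planted = []
    while len(planted) < 40:
        r, c = rng.integers(10, 190, 2)
        if all(np.hypot(r - pr, c - pc) > 12 for pr, pc in planted):
            planted.append((int(r), int(c)))
            a[r, c] += 25.0  # SNR 25 over sigma-1 noise
    pts = local_maxima(img(a), min_distance_um=0.5, min_prominence=15.0)
    assert len(pts) == 40
    d = cdist(pts.points, np.asarray(planted, float))
    assert (d.min(axis=1) <= 1.0).all()


# ---------------------------------------------------------------------------
# top-hat
# ---------------------------------------------------------------------------


def test_tophat_constant_image_zero():
    out = tophat_subtract(img(np.full((30, 30), 7.0)), radius_um=0.5)
    assert np.allclose(out.pixels, 0.0)


def test_tophat_single_bright_pixel():
    a = np.full((31, 31), 20.0)
    a[15, 15] = 100.0
    out = tophat_subtract(img(a), radius_um=0.5)
    assert out.pixels[15, 15] == pytest.approx(80.0)
    other = out.pixels.copy()
    other[15, 15] = 0
    assert np.abs(other).max() == pytest.approx(0.0)


def test_tophat_matches_explicit_erosion_dilation_oracle():
    from scipy import ndimage
    from skimage.morphology import disk

    rng = np.random.default_rng(5)
    base = np.linspace(0, 40, 64)[None, :] * np.ones((64, 1))  # gradient bg
    a = base.copy()
    spots = [(10, 10), (30, 45), (50, 20)]
    for r, c in spots:
        a[r - 1 : r + 2, c - 1 : c + 2] += 60.0
    out = tophat_subtract(img(a, px=1.0), radius_um=5.0)
    fp = disk(5)
    opened = ndimage.grey_dilation(
        ndimage.grey_erosion(a, footprint=fp), footprint=fp
    )
    oracle = np.clip(a - opened, 0, None)
    assert np.allclose(out.pixels, oracle)
    # spot contrasts preserved, background suppressed
    for r, c in spots:
        assert out.pixels[r, c] == pytest.approx(60.0, rel=0.05)
    bg_residual = out.pixels.copy()
    for r, c in spots:
        bg_residual[r - 2 : r + 3, c - 2 : c + 3] = 0
    # border columns are distorted by structuring-element overhang
    assert bg_residual[6:-6, 6:-6].max() < 0.05 * 40


def test_tophat_subpixel_radius_rejected():
    with pytest.raises(ValueError):
        tophat_subtract(img(np.ones((10, 10)), px=1.0), radius_um=0.4)


def test_tophat_bounded_by_input_and_zero():
    rng = np.random.default_rng(8)
    a = rng.uniform(0, 50, (40, 40))
    out = tophat_subtract(img(a, px=1.0), radius_um=3.0)
    assert (out.pixels <= a + 1e-12).all()
    assert (out.pixels >= 0).all()


# ---------------------------------------------------------------------------
# boundary distance
# ---------------------------------------------------------------------------


def brute_force_distance(m, px):
    """O(n^2) exhaustive min-over-background Euclidean distances."""
    fg = np.argwhere(m)
    bg = np.argwhere(~m)
    out = np.zeros(m.shape)
    d = cdist(fg, bg).min(axis=1)
    out[fg[:, 0], fg[:, 1]] = d * px
    return out


def test_boundary_distance_disc_center():
    from skimage.draw import disk as sk_disk

    m = np.zeros((64, 64), bool)
    rr, cc = sk_disk((32, 32), 20)
    m[rr, cc] = True
    dist = boundary_distance(mask(m))
    assert dist[32, 32] == pytest.approx(20 * PX, abs=PX)
    from scipy import ndimage

    edge = m & ~ndimage.binary_erosion(m)
    assert (dist[edge] <= np.sqrt(2) * PX + 1e-12).all()


@pytest.mark.parametrize("seed", range(6))
def test_boundary_distance_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    m = rng.random((64, 64)) < 0.4
    if not m.any() or m.all():
        m[0, 0] = True
        m[1, 1] = False
    dist = boundary_distance(mask(m))
    assert np.allclose(dist, brute_force_distance(m, PX), atol=1e-9 * PX)


def test_boundary_distance_rejects_uniform_masks():
    with pytest.raises(ValueError):
        boundary_distance(mask(np.ones((5, 5), bool)))
    with pytest.raises(ValueError):
        boundary_distance(mask(np.zeros((5, 5), bool)))


# ---------------------------------------------------------------------------
# shape/contract properties
# ---------------------------------------------------------------------------


def test_mask_producing_operations_preserve_shape():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 100, (33, 47))
    image = img(a)
    res = threshold_global(image, "otsu")
    assert res.mask.shape == image.shape
    regs = label_regions(res.mask)
    assert filter_by_circularity(regs, 0.5).shape == image.shape
    assert skeletonize_mask(res.mask).shape == image.shape
    assert tophat_subtract(image, 1.0).shape == image.shape


def test_contractive_operations():
    rng = np.random.default_rng(4)
    m = rng.random((40, 40)) < 0.3
    bm = mask(m)
    regs = label_regions(bm)
    filtered = filter_by_circularity(regs, 0.7)
    assert not (filtered.pixels & ~m).any()
    skel = skeletonize_mask(bm)
    assert not (skel.pixels & ~m).any()
    assert skel.pixels.sum() <= m.sum()
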