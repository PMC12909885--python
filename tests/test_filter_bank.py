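"""Filter-bank oracles: hand-computed grayscale and Sobel values, Canny
topology, Harris against a fully independent loop-based detector, CKPF and
kernel-isolation properties."""

import numpy as np
import pytest
from scipy.ndimage import label

from nutnet.augmentation import apply_rotation
from nutnet.filter_bank import (FilterConfig, HarrisParams, KERNELS,
                                apply_filters, canny_edges, detect_corners,
                                kernel_isolate, render_ckpf, run_filtration,
                                sobel_magnitude, to_grayscale)
from nutnet.fixtures import FixtureSpec, generate_fixture_dataset, make_toy_matrix


# -------------------------------------------------------- independent oracle

def _gaussian_kernel(sigma, truncate=4.0):
    r = int(truncate * sigma + 0.5)
    xs = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (xs / sigma) ** 2)
    return k / k.sum()


def _correlate_reflect(img, kernel2d):
    """Plain-loop 2-D cross-correlation with reflect borders."""
    kh, kw = kernel2d.shape
    rh, rw = kh // 2, kw // 2
    padded = np.pad(img, ((rh, rh), (rw, rw)), mode="reflect")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = (padded[i:i + kh, j:j + kw] * kernel2d).sum()
    return out


def brute_force_harris_keypoints(img, params=HarrisParams()):
    """Independent Harris detector: explicit loops, sampled Gaussian
    window, exhaustive threshold + 3x3 max scan."""
    sx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ix = _correlate_reflect(img, sx)
    iy = _correlate_reflect(img, sx.T)
    g1 = _gaussian_kernel(params.window_sigma)
    g2d = np.outer(g1, g1)
    sxx = _correlate_reflect(ix * ix, g2d)
    syy = _correlate_reflect(iy * iy, g2d)
    sxy = _correlate_reflect(ix * iy, g2d)
    r = (sxx * syy - sxy * sxy) - params.k * (sxx + syy) ** 2
    rmax = r.max()
    if rmax <= 0:
        return set()
    pts = set()
    h, w = r.shape
    for i in range(h):
        for j in range(w):
            if r[i, j] < params.rel_thresh * rmax:
                continue
            neigh = r[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if r[i, j] == neigh.max():
                pts.add((i, j))
    return pts


# --------------------------------------------------------------- grayscale

def test_grayscale_zero_input():
    black = np.zeros((2, 2, 3), dtype=np.uint8)
    for mode in ("paper", "standard"):
        np.testing.assert_array_equal(to_grayscale(black, mode), 0.0)


def test_grayscale_paper_white_value():
    """Two-stage weighting maps white to 0.2989*0.3 + 0.5870*0.59 +
    0.1140*0.11 = 0.44854, not 1.0."""
    white = np.full((1, 1, 3), 255, dtype=np.uint8)
    assert to_grayscale(white, "paper")[0, 0] == pytest.approx(0.44854, abs=1e-9)
    assert to_grayscale(white, "standard")[0, 0] == pytest.approx(0.9999, abs=1e-3)


def test_grayscale_paper_pure_red():
    red = np.zeros((1, 1, 3), dtype=np.uint8)
    red[..., 0] = 255
    assert to_grayscale(red, "paper")[0, 0] == pytest.approx(0.089670, abs=1e-9)


def test_grayscale_rejects_bad_shapes():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4)), "paper")
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4, 3)), "bogus")


# ------------------------------------------------------------------- sobel

def test_sobel_constant_is_zero():
    out = sobel_magnitude(make_toy_matrix("constant", 5))
    np.testing.assert_array_equal(out, 0.0)


def test_sobel_step_edge_center_response():
    """Hand convolution of the 3x3 step toy: |Gx| at center = 4, Gy = 0."""
    toy = make_toy_matrix("step_edge", 3)
    out, scale = sobel_magnitude(toy, return_scale=True)
    assert out[1, 1] * scale == pytest.approx(4.0)


def test_sobel_mirror_equivariance():
    g = np.random.default_rng(1).random((12, 12))
    np.testing.assert_allclose(sobel_magnitude(g[:, ::-1]),
                               sobel_magnitude(g)[:, ::-1], atol=1e-12)


def test_sobel_rejects_tiny_images():
    with pytest.raises(ValueError):
        sobel_magnitude(np.zeros((2, 2)))


def test_sobel_range():
    g = np.random.default_rng(2).random((16, 16))
    out = sobel_magnitude(g)
    assert out.min() >= 0 and out.max() <= 1


# ------------------------------------------------------------------- canny

def test_canny_constant_empty():
    assert canny_edges(make_toy_matrix("constant", 9)).sum() == 0


def test_canny_square_closed_contour():
    """Edges of a centered filled square form one 8-connected component
    whose complement has exactly two regions (inside and outside)."""
    img = np.zeros((64, 64))
    img[22:42, 22:42] = 1.0
    e = canny_edges(img)
    assert e.sum() > 0
    _, n_edge = label(e, structure=np.ones((3, 3)))
    assert n_edge == 1
    _, n_bg = label(~e)
    assert n_bg == 2


def test_canny_monotone_in_thresholds():
    g = np.random.default_rng(3).random((32, 32))
    loose = canny_edges(g, 0.05, 0.15)
    tight = canny_edges(g, 0.2, 0.6)
    assert not (tight & ~loose).any()


def test_canny_threshold_ordering_enforced():
    g = np.zeros((8, 8))
    with pytest.raises(ValueError):
        canny_edges(g, 0.5, 0.2)


# ------------------------------------------------------------------ harris

@pytest.mark.parametrize("kind", ["constant", "step_edge", "square", "l_shape"])
def test_harris_equals_brute_force_on_toys(kind):
    toy = make_toy_matrix(kind, 9)
    ours = set(detect_corners(toy).coords())
    oracle = brute_force_harris_keypoints(toy)
    assert ours == oracle


def test_harris_constant_no_keypoints():
    assert len(detect_corners(np.full((16, 16), 0.5))) == 0


def test_harris_square_four_corners():
    """A 20x20 filled square in 64x64 yields exactly 4 keypoints, each
    within 2 px of a geometric corner (verified against the brute-force
    oracle)."""
    img = np.zeros((64, 64))
    img[22:42, 22:42] = 1.0
    kps = detect_corners(img)
    assert len(kps) == 4
    corners = [(22, 22), (22, 41), (41, 22), (41, 41)]
    for r, c, _ in kps.points:
        assert min(abs(r - cr) + abs(c - cc) for cr, cc in corners) <= 2
    assert set(kps.coords()) == brute_force_harris_keypoints(img)


def test_harris_l_shape_six_corners():
    """An L-shaped region large enough for the sigma=1 window shows its
    six geometric corners."""
    img = np.zeros((64, 64))
    img[10:54, 10:26] = 1.0
    img[38:54, 10:54] = 1.0
    kps = detect_corners(img)
    assert len(kps) == 6
    geometric = [(10, 10), (10, 25), (38, 25), (38, 53), (53, 10), (53, 53)]
    for r, c, _ in kps.points:
        assert min(abs(r - gr) + abs(c - gc) for gr, gc in geometric) <= 2


def test_harris_rotation_coherence():
    """Corners of a rectangle rotated 90 degrees map to the rotated
    positions exactly."""
    img = np.zeros((64, 64))
    img[10:30, 20:50] = 1.0
    a = set(detect_corners(img).coords())
    b = set(detect_corners(apply_rotation(img, 90, "nearest")).coords())
    w = img.shape[1]
    assert b == {(w - 1 - c, r) for r, c in a}


def test_harris_responses_above_threshold_and_nms():
    img = np.zeros((64, 64))
    img[22:42, 22:42] = 1.0
    kps = detect_corners(img)
    rmax = max(p[2] for p in kps.points)
    for r, c, resp in kps.points:
        assert resp >= kps.params.rel_thresh * rmax
    coords = kps.coords()
    for i, (r1, c1) in enumerate(coords):
        for r2, c2 in coords[i + 1:]:
            assert max(abs(r1 - r2), abs(c1 - c2)) > 1


# -------------------------------------------------------------------- ckpf

def test_ckpf_no_keypoints_uniform_attenuation():
    g = np.random.default_rng(4).random((16, 16))
    from nutnet.filter_bank import KeypointSet
    out = render_ckpf(g, KeypointSet([], HarrisParams()), alpha=0.3)
    np.testing.assert_allclose(out, 0.3 * g)


def test_ckpf_identity_configuration():
    img = np.zeros((64, 64))
    img[22:42, 22:42] = 0.8
    kps = detect_corners(img)
    out = render_ckpf(img, kps, alpha=1.0, boost=0.0)
    np.testing.assert_allclose(out, img)


def test_ckpf_corners_brighter_than_background():
    img = np.zeros((64, 64))
    img[22:42, 22:42] = 0.8
    kps = detect_corners(img)
    out = render_ckpf(img, kps, alpha=0.3, radius=3, boost=0.5)
    yy, xx = np.mgrid[0:64, 0:64]
    disk = np.zeros((64, 64), dtype=bool)
    for r, c, _ in kps.points:
        disk |= (yy - r) ** 2 + (xx - c) ** 2 <= 9
    inside_sq = img > 0
    assert out[disk].mean() > out[inside_sq & ~disk].mean()
    assert out.min() >= 0 and out.max() <= 1


# --------------------------------------------------------- kernel isolation

def test_kernel_identity_unchanged():
    g = np.random.default_rng(5).random((8, 8))
    np.testing.assert_allclose(kernel_isolate(g, "identity"), g)


def test_kernel_highboost_constant_preserved():
    """Kernel weights sum to 1, so a constant image passes through."""
    assert KERNELS["laplacian_highboost"].sum() == 1
    g = make_toy_matrix("constant", 5)
    np.testing.assert_allclose(kernel_isolate(g, "laplacian_highboost"), g)


def test_kernel_highboost_step_edge_concentrates_on_edge():
    toy = make_toy_matrix("step_edge", 9)
    out = kernel_isolate(toy, "laplacian_highboost")
    edge_col = int(np.ceil(2 * 9 / 3))
    # hand convolution: the bright side of the edge overshoots to the clamp
    assert out[4, edge_col] == 1.0
    assert out[4, 0] == 0.0


def test_kernel_unknown_name():
    with pytest.raises(ValueError):
        kernel_isolate(np.zeros((4, 4)), "emboss")


# ----------------------------------------------------------- orchestration

def test_apply_filters_shapes_and_ranges():
    rng = np.random.default_rng(6)
    rgb = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
    fo = apply_filters(rgb)
    for arr in (fo.gray, fo.sobel, fo.ckpf, fo.kernel_isolated):
        assert arr.shape == (32, 32)
        assert arr.min() >= 0 and arr.max() <= 1
    assert fo.canny.shape == (32, 32) and fo.canny.dtype == bool


def test_run_filtration_counts_and_determinism(tmp_path):
    m = generate_fixture_dataset(FixtureSpec(2, 2, 32, seed=9), tmp_path / "d")
    cfg = FilterConfig()
    m1 = run_filtration(m, cfg, tmp_path / "f1")
    assert m1.count(provenance="filtered") == 4 * 5
    m2 = run_filtration(m, cfg, tmp_path / "f2")
    for r1, r2 in zip(m1.select(provenance="filtered"),
                      m2.select(provenance="filtered")):
        assert open(r1.path, "rb").read() == open(r2.path, "rb").read()


def test_run_filtration_ckpf_only(tmp_path):
    m = generate_fixture_dataset(FixtureSpec(2, 2, 32, seed=9), tmp_path / "d")
    cfg = FilterConfig(renderings=("ckpf",))
    out = run_filtration(m, cfg, tmp_path / "f")
    assert out.count(provenance="filtered") == 4
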