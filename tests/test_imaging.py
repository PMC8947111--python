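"""Pixel-operator tests: degenerate inputs, formula oracles, morphological
properties, and exhaustive-search agreement for both threshold families."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import draw

from myometrics import imaging
from myometrics.imaging import (
    N_BINS,
    ThresholdSpec,
    binary_close_fill,
    correct_illumination,
    disk_footprint,
    enhance_line_structures,
    enhance_speckles,
    enhance_tubeness,
    grayscale_closing,
    li_threshold,
    median_filter,
    otsu3_thresholds,
    rescale_full_range,
    sharpen_membranes,
    threshold_image,
)

# ---------------------------------------------------------------------------
# independent exhaustive oracles (plain loops over every bin boundary)
# ---------------------------------------------------------------------------


def otsu3_oracle(hist):
    """Between-class variance maximized by explicit search over all pairs."""
    n = hist.sum()
    g = np.arange(len(hist))
    mu = (hist * g).sum() / n
    best, best_pair = -1.0, None
    for t1 in range(len(hist) - 2):
        for t2 in range(t1 + 1, len(hist) - 1):
            masks = (g <= t1, (g > t1) & (g <= t2), g > t2)
            var = 0.0
            ok = True
            for m in masks:
                w = hist[m].sum()
                if w == 0:
                    ok = False
                    break
                mk = (hist[m] * g[m]).sum() / w
                var += (w / n) * (mk - mu) ** 2
            if ok and var > best + 1e-12:
                best, best_pair = var, (t1, t2)
    return best_pair


def li_oracle(hist):
    """Cross-entropy minimized by explicit search over all boundaries."""
    g = np.arange(len(hist), dtype=float)
    best, best_t = np.inf, None
    for t in range(len(hist) - 1):
        nb = hist[: t + 1].sum()
        nf = hist[t + 1 :].sum()
        if nb == 0 or nf == 0:
            continue
        sb = (hist[: t + 1] * g[: t + 1]).sum()
        sf = (hist[t + 1 :] * g[t + 1 :]).sum()
        ce = 0.0
        if sb > 0:
            ce -= sb * np.log(sb / nb)
        if sf > 0:
            ce -= sf * np.log(sf / nf)
        if ce < best - 1e-12:
            best, best_t = ce, t
    return best_t


def test_rescale_affine_and_degenerate():
    img = np.array([[0.2, 0.4], [0.6, 0.3]])
    out = rescale_full_range(img)
    assert out.min() == 0.0 and out.max() == 1.0
    assert np.isclose(out[0, 1], 0.5)  # 0.4 is midway between 0.2 and 0.6
    spanned = np.array([[0.0, 0.5], [1.0, 0.25]])
    assert np.array_equal(rescale_full_range(spanned), spanned)
    assert np.array_equal(rescale_full_range(np.full((3, 3), 0.7)), np.zeros((3, 3)))


def test_sharpen_formula_oracle(rng):
    img = rng.random((24, 24))
    out = sharpen_membranes(img, 1.5)
    expected = np.clip(img + (img - ndi.gaussian_filter(img, 1.5, mode="reflect")), 0, 1)
    assert np.allclose(out, expected)
    const = np.full((16, 16), 0.4)
    assert np.allclose(sharpen_membranes(const, 2.0), const)
    line = np.zeros((21, 21))
    line[10, :] = 0.5
    assert sharpen_membranes(line, 1.0)[10, 10] > 0.5
    with pytest.raises(ValueError):
        sharpen_membranes(img, 0.0)


def test_line_enhancement_prefers_lines_over_blobs():
    line = np.zeros((64, 64))
    line[30:32, 8:56] = 0.8
    blob = np.zeros((64, 64))
    rr, cc = draw.disk((32, 32), 6)
    blob[rr, cc] = 0.8
    r_line = enhance_line_structures(line, 2)
    r_blob = enhance_line_structures(blob, 2)
    assert r_line[line > 0].mean() > r_blob[blob > 0].mean()
    assert enhance_line_structures(np.zeros((32, 32)), 2).max() == 0.0


def test_line_enhancement_rot90_equivariant(rng):
    img = rng.random((60, 60))
    a = np.rot90(enhance_line_structures(img, 2))
    b = enhance_line_structures(np.rot90(img), 2)
    inner = (slice(12, -12), slice(12, -12))
    assert np.allclose(a[inner], b[inner])


def test_tubeness_ridge_and_offset_invariance():
    assert enhance_tubeness(np.zeros((32, 32)), 1.0).max() == 0.0
    ridge = np.zeros((64, 64))
    ridge[:, 30] = 1.0
    resp = enhance_tubeness(ridge, 1.0)
    assert resp[:, 30].mean() > 0.9
    assert resp[:, 10].max() < 1e-6
    shifted = enhance_tubeness(np.clip(0.5 * ridge + 0.3, 0, 1), 1.0)
    assert np.allclose(shifted, enhance_tubeness(0.5 * ridge, 1.0), atol=1e-10)


def test_speckle_enhancement_size_selectivity():
    assert np.array_equal(enhance_speckles(np.full((32, 32), 0.6), 10), np.zeros((32, 32)))
    big = np.zeros((64, 64))
    rr, cc = draw.disk((32, 32), 15)
    big[rr, cc] = 0.9
    assert enhance_speckles(big, 10)[28:36, 28:36].max() < 0.05
    dot = np.zeros((64, 64))
    rr, cc = draw.disk((32, 32), 2)
    dot[rr, cc] = 0.9
    assert enhance_speckles(dot, 10)[32, 32] > 0.85


def test_median_filter_oracle(rng):
    img = rng.random((16, 16))
    out = median_filter(img, 2)
    fp = disk_footprint(2)
    pad = np.pad(img, 2, mode="symmetric")
    expected = np.empty_like(img)
    for i in range(16):
        for j in range(16):
            patch = pad[i : i + 5, j : j + 5]
            expected[i, j] = np.median(patch[fp])
    assert np.allclose(out, expected)
    flat = np.full((10, 10), 0.3)
    flat[5, 5] = 1.0
    assert median_filter(flat, 1)[5, 5] == 0.3
    assert np.array_equal(median_filter(np.full((8, 8), 0.4), 2), np.full((8, 8), 0.4))


def test_median_commutes_with_affine_map(rng):
    img = rng.random((20, 20))
    a, b = 0.6, 0.2
    assert np.allclose(median_filter(a * img + b, 2), a * median_filter(img, 2) + b)


def test_grayscale_closing_properties(rng):
    line = np.zeros((21, 40))
    line[9:12, :] = 0.8  # membrane-like 3-px line
    line[9:12, 20] = 0.0  # 1-px gap
    closed = grayscale_closing(line, 2)
    assert closed[10, 20] >= 0.8 - 1e-9  # gap core raised to line level
    img = rng.random((24, 24))
    once = grayscale_closing(img, 2)
    assert np.all(once >= img - 1e-12)  # extensive
    assert np.allclose(grayscale_closing(once, 2), once)  # idempotent
    const = np.full((12, 12), 0.5)
    assert np.allclose(grayscale_closing(const, 2), const)


def test_otsu3_point_mass_example():
    vals = np.concatenate([np.full(40, 0.1), np.full(30, 0.5), np.full(30, 0.9)])
    img = vals.reshape(10, 10)
    mid_bg = threshold_image(img, ThresholdSpec("otsu3", "background"))
    assert mid_bg.sum() == 30  # only the 0.9 pixels
    assert np.all(mid_bg[img > 0.8] == 1)
    mid_fg = threshold_image(img, ThresholdSpec("otsu3", "foreground"))
    assert mid_fg.sum() == 60  # 0.5 and 0.9 pixels


@pytest.mark.parametrize("method", ["otsu3", "li"])
def test_thresholds_match_exhaustive_oracle(method, rng):
    for _ in range(20):
        img = rng.integers(0, 256, (32, 32)) / (N_BINS - 1)
        hist = np.bincount(np.round(img * (N_BINS - 1)).astype(int).ravel(), minlength=N_BINS)
        if method == "otsu3":
            assert otsu3_thresholds(hist.astype(float)) == otsu3_oracle(hist)
        else:
            assert li_threshold(hist.astype(float)) == li_oracle(hist)


def test_li_matches_skimage_on_bimodal(rng):
    """Independent cross-check: the exhaustive minimum cross-entropy
    threshold separates the same two modes as skimage's iterative Li."""
    from skimage.filters import threshold_li as sk_li

    img = np.concatenate([rng.normal(0.2, 0.03, 600), rng.normal(0.8, 0.03, 400)])
    img = np.clip(img, 0, 1).reshape(25, 40)
    ours = threshold_image(img, ThresholdSpec("li", None))
    theirs = (img > sk_li(img)).astype(np.uint8)
    assert np.mean(ours == theirs) > 0.995


def test_degenerate_thresholds():
    const = np.full((16, 16), 0.5)
    with pytest.warns(UserWarning, match="degenerate"):
        assert threshold_image(const, ThresholdSpec("li", None)).sum() == 0
    binary = np.zeros((16, 16))
    binary[:8] = 1.0
    # exactly two gray levels: otsu3 degrades to a single threshold
    out = threshold_image(binary, ThresholdSpec("otsu3", "background"))
    assert np.array_equal(out, binary.astype(np.uint8))


def test_adaptive_equals_global_on_tiled_image(rng):
    tile = rng.integers(0, 256, (25, 25)) / (N_BINS - 1)
    big = np.tile(tile, (4, 4))
    for spec_g, spec_a in [
        (ThresholdSpec("li", None), ThresholdSpec("li", None, "adaptive", 25)),
        (
            ThresholdSpec("otsu3", "background"),
            ThresholdSpec("otsu3", "background", "adaptive", 25),
        ),
    ]:
        assert np.array_equal(threshold_image(big, spec_g), threshold_image(big, spec_a))


def test_adaptive_window_validation(rng):
    img = rng.random((32, 32))
    with pytest.raises(ValueError):
        threshold_image(img, ThresholdSpec("li", None, "adaptive", 64))
    with pytest.raises(ValueError):
        ThresholdSpec("li", None, "adaptive", None)
    with pytest.raises(ValueError):
        ThresholdSpec("li", "background")


def test_log_transform_separates_wide_dynamic_range(rng):
    img = np.full((40, 40), 1e-3)
    img[10:20, 10:20] = 0.05  # faint object, far below the bright one
    img[25:35, 25:35] = 0.9
    out = threshold_image(img, ThresholdSpec("li", None, log_transform=True))
    assert out[12:18, 12:18].all() and out[27:33, 27:33].all()
    assert out[:8, :8].sum() == 0


def test_binary_close_fill_hole_size_gate():
    ring = np.zeros((32, 32), dtype=np.uint8)
    rr, cc = draw.disk((16, 16), 8)
    ring[rr, cc] = 1
    rr, cc = draw.disk((16, 16), 2.7)  # ~20 px hole
    ring[rr, cc] = 0
    hole = (ring == 0).sum() - (binary_close_fill(np.ones_like(ring), 1, 0) == 0).sum()
    filled = binary_close_fill(ring, 1, 50)
    assert filled[16, 16] == 1
    kept_hole = binary_close_fill(ring, 1, 10)
    assert kept_hole[16, 16] == 0
    assert binary_close_fill(np.zeros((16, 16), np.uint8), 2, 100).sum() == 0
    assert np.all(filled >= ring)  # foreground never shrinks


def test_correct_illumination_flattens_ramp(rng):
    ramp = np.linspace(0.5, 1.0, 160)[None, :] * np.ones((160, 1))
    field = 0.6 * ramp
    flat = correct_illumination(field, 8)
    inner = flat[32:-32, 32:-32]
    assert inner.max() / inner.min() - 1 < 0.02
    uniform = np.full((64, 64), 0.35)
    out = correct_illumination(uniform, 10)
    assert np.allclose(out / out[0, 0], np.ones_like(out))  # unchanged up to scale
    with pytest.raises(ValueError):
        correct_illumination(uniform, 0)


def test_correct_illumination_floors_zero_background():
    img = np.zeros((32, 32))
    img[16, 16] = 1e-9
    with pytest.warns(UserWarning, match="floor"):
        out = correct_illumination(img, 2)
    assert np.all(np.isfinite(out))


@pytest.mark.parametrize(
    "op",
    [
        lambda x: rescale_full_range(x),
        lambda x: sharpen_membranes(x, 1.5),
        lambda x: enhance_line_structures(x, 2),
        lambda x: enhance_tubeness(x, 1.0),
        lambda x: enhance_speckles(x, 6),
        lambda x: median_filter(x, 2),
        lambda x: grayscale_closing(x, 2),
    ],
)
def test_filters_preserve_shape_and_range(op, rng):
    img = rng.random((31, 37))
    out = op(img)
    assert out.shape == img.shape
    assert out.min() >= 0.0 and out.max() <= 1.0
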