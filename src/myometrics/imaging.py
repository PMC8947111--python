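"""Pixel-level operators shared by all pipelines.

Intensity images are 2-D float arrays on [0, 1] (16-bit inputs are divided by
65535 on load, 8-bit by 255).  Every operator preserves the image shape and the
[0, 1] range.  Structuring elements are discrete disks: a pixel belongs to the
disk iff its center lies within ``radius`` of the origin.

Two thresholding families are provided, both computed by exhaustive search
over a fixed 256-bin histogram of [0, 1]:

* three-class Otsu (``otsu3``) — two thresholds ``t1 < t2`` maximizing the
  between-class variance of the three-way partition; the middle class can be
  assigned to either foreground or background,
* minimum cross-entropy (``li``) — the single threshold minimizing the
  cross-entropy between the image and its two-level reconstruction.

Both support a global scope or an adaptive scope in which per-window
thresholds are bilinearly interpolated between tile centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

N_BINS = 256
LOG_EPS = 1e-4  # offset for the optional log transform before thresholding

__all__ = [
    "ThresholdSpec",
    "rescale_full_range",
    "gaussian_blur",
    "sharpen_membranes",
    "enhance_line_structures",
    "enhance_tubeness",
    "enhance_speckles",
    "median_filter",
    "grayscale_closing",
    "threshold_image",
    "binary_close_fill",
    "correct_illumination",
    "otsu3_thresholds",
    "li_threshold",
    "disk_footprint",
]


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk: pixel included iff center distance <= radius."""
    radius = int(radius)
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def _check_image(img) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D intensity image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def rescale_full_range(img) -> np.ndarray:
    """Stretch intensities to span [0, 1] (monotone affine map).

    A constant image maps to all zeros, matching the convention that the
    negative signal is 0.
    """
    img = _check_image(img)
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def gaussian_blur(img, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndi.gaussian_filter(np.asarray(img, dtype=float), sigma, mode="reflect")


def sharpen_membranes(img, sigma: float) -> np.ndarray:
    """Unsharp mask: add the detail image (input minus Gaussian blur) back.

    output = clip(img + (img - blur(img, sigma)), 0, 1)
    """
    img = _check_image(img)
    detail = img - gaussian_blur(img, sigma)
    return np.clip(img + detail, 0.0, 1.0)


def _line_footprint(length: int, angle: float) -> np.ndarray:
    """Width-1 linear structuring element of ``length`` pixels at ``angle``.

    Offsets are rounded per sample so that the 12-orientation set maps onto
    itself under 90-degree rotation (exact rotational equivariance of the
    line-enhancement operator up to border effects).
    """
    half = (length - 1) / 2.0
    t = np.arange(length) - half
    rows = np.rint(t * np.sin(angle)).astype(int)
    cols = np.rint(t * np.cos(angle)).astype(int)
    r0, c0 = rows.min(), cols.min()
    fp = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    fp[rows - r0, cols - c0] = True
    return fp


def enhance_line_structures(img, line_width: int, n_angles: int = 12) -> np.ndarray:
    """Highlight elongated bright ridges.

    Orientation contrast of grayscale openings with width-1 linear elements
    of length ``5 * line_width`` at ``n_angles`` uniformly spaced
    orientations: ``max_angle(opening) - min_angle(opening)``.  A thin bright
    line survives the opening along its own orientation but vanishes under
    the perpendicular one, giving full response; an isotropic blob responds
    (or not) identically in every orientation, so the contrast cancels
    regardless of its size.
    """
    img = _check_image(img)
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    length = max(3, int(round(line_width)) * 5)
    hi = np.full_like(img, -np.inf)
    lo = np.full_like(img, np.inf)
    for k in range(n_angles):
        angle = np.pi * k / n_angles
        opened = ndi.grey_opening(img, footprint=_line_footprint(length, angle), mode="reflect")
        np.maximum(hi, opened, out=hi)
        np.minimum(lo, opened, out=lo)
    return np.clip(hi - lo, 0.0, 1.0)


def enhance_tubeness(img, sigma: float = 1.0) -> np.ndarray:
    """Hessian ridge measure for bright curvilinear structures.

    The most negative Hessian eigenvalue at scale ``sigma`` is negated,
    clipped at zero and rescaled to [0, 1].  Being a second-derivative
    measure, the response is invariant to constant offsets.
    """
    from skimage.feature import hessian_matrix, hessian_matrix_eigvals

    img = _check_image(img)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    H = hessian_matrix(
        img, sigma=sigma, mode="reflect", order="rc", use_gaussian_derivatives=True
    )
    eigvals = hessian_matrix_eigvals(H)  # sorted in decreasing order
    ridge = np.maximum(-eigvals[-1], 0.0)
    return rescale_full_range(ridge)


def enhance_speckles(img, feature_size: int) -> np.ndarray:
    """White top-hat: img minus grayscale opening with a disk of diameter
    ``feature_size``; structures larger than the feature size are suppressed."""
    img = _check_image(img)
    if feature_size < 1:
        raise ValueError("feature_size must be >= 1")
    radius = max(1, int(feature_size) // 2)
    if radius <= 8:
        opened = ndi.grey_opening(img, footprint=disk_footprint(radius), mode="reflect")
    else:
        # large disks: sequence-decomposed footprint (near-circular, far faster)
        from skimage import morphology as skmorph

        fp = skmorph.disk(radius, decomposition="sequence")
        opened = skmorph.opening(img, footprint=fp)
    return np.clip(img - opened, 0.0, 1.0)


def median_filter(img, radius: int) -> np.ndarray:
    """Disk-neighborhood median; removes salt-and-pepper noise."""
    img = _check_image(img)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndi.median_filter(img, footprint=disk_footprint(radius), mode="reflect")


def grayscale_closing(img, disk_radius: int) -> np.ndarray:
    """Grayscale closing (dilate then erode) with a disk element.

    Extensive (output >= input) and idempotent; used to bridge small
    intensity gaps in membrane signals.
    """
    img = _check_image(img)
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    closed = ndi.grey_closing(img, footprint=disk_footprint(disk_radius), mode="reflect")
    # reflect padding keeps closing extensive in the interior; enforce at borders
    return np.clip(np.maximum(closed, img), 0.0, 1.0)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdSpec:
    """Thresholding recipe.

    method
        ``"otsu3"`` (three-class Otsu) or ``"li"`` (minimum cross-entropy).
    middle_class_to
        For otsu3 only: assign the middle-intensity class to ``"foreground"``
        or ``"background"``.
    scope
        ``"global"`` or ``"adaptive"`` (per-window thresholds, bilinearly
        interpolated between tile centers).
    window_px
        Adaptive tile size in pixels.
    log_transform
        Threshold on log(intensity + 1e-4); useful for wide-dynamic-range
        stains.
    """

    method: str = "otsu3"
    middle_class_to: str | None = "background"
    scope: str = "global"
    window_px: int | None = None
    log_transform: bool = False

    def __post_init__(self):
        if self.method not in ("otsu3", "li"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "otsu3":
            if self.middle_class_to not in ("foreground", "background"):
                raise ValueError("middle_class_to must be 'foreground' or 'background'")
        elif self.middle_class_to is not None:
            raise ValueError("middle_class_to is only defined for otsu3")
        if self.scope not in ("global", "adaptive"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "adaptive" and (self.window_px is None or self.window_px <= 0):
            raise ValueError("adaptive scope requires window_px > 0")


def _histogram(q: np.ndarray) -> np.ndarray:
    return np.bincount(q.ravel(), minlength=N_BINS).astype(float)


def otsu3_thresholds(hist: np.ndarray) -> tuple[int, int] | None:
    """Exhaustive two-threshold Otsu on a 256-bin histogram.

    Returns bin indices ``(t1, t2)`` with ``t1 < t2`` maximizing the
    between-class variance of the partition {<=t1, (t1, t2], >t2}, or ``None``
    if fewer than 3 bins are occupied.  Ties resolve to the lexicographically
    smallest pair.
    """
    hist = np.asarray(hist, dtype=float)
    if np.count_nonzero(hist) < 3:
        return None
    g = np.arange(N_BINS, dtype=float)
    c = np.cumsum(hist)
    s = np.cumsum(hist * g)
    n, stot = c[-1], s[-1]
    t1 = np.arange(N_BINS)[:, None]
    t2 = np.arange(N_BINS)[None, :]
    w_a, s_a = c[t1], s[t1]
    w_b, s_b = c[t2] - c[t1], s[t2] - s[t1]
    w_c, s_c = n - c[t2], stot - s[t2]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = s_a**2 / w_a + s_b**2 / w_b + s_c**2 / w_c
    valid = (t1 < t2) & (w_a > 0) & (w_b > 0) & (w_c > 0)
    crit = np.where(valid, crit, -np.inf)
    if not np.isfinite(crit).any():
        return None
    flat = int(np.argmax(crit))  # first occurrence -> smallest (t1, t2)
    return flat // N_BINS, flat % N_BINS


def li_threshold(hist: np.ndarray) -> int | None:
    """Exhaustive minimum cross-entropy threshold on a 256-bin histogram.

    Minimizes ``-(Sb*log(mu_b) + Sf*log(mu_f))`` over all bin boundaries,
    where ``S`` is the summed intensity mass and ``mu`` the mean of each side.
    Returns the bin index, or ``None`` for a constant histogram.
    """
    hist = np.asarray(hist, dtype=float)
    if np.count_nonzero(hist) < 2:
        return None
    g = np.arange(N_BINS, dtype=float)
    c = np.cumsum(hist)
    s = np.cumsum(hist * g)
    n, stot = c[-1], s[-1]
    t = np.arange(N_BINS - 1)
    nb, sb = c[t], s[t]
    nf, sf = n - nb, stot - sb
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(nb > 0, sb / np.maximum(nb, 1), 0.0)
        mu_f = np.where(nf > 0, sf / np.maximum(nf, 1), 0.0)
        term_b = np.where(sb > 0, sb * np.log(np.maximum(mu_b, 1e-300)), 0.0)
        term_f = np.where(sf > 0, sf * np.log(np.maximum(mu_f, 1e-300)), 0.0)
    ce = -(term_b + term_f)
    ce = np.where((nb > 0) & (nf > 0), ce, np.inf)
    if not np.isfinite(ce).any():
        return None
    return int(np.argmin(ce))  # first occurrence -> lowest threshold


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * (N_BINS - 1)), 0, N_BINS - 1).astype(np.intp)


def _global_thresholds(q: np.ndarray, spec: ThresholdSpec):
    """Threshold bin(s) for a quantized region; None means degenerate."""
    hist = _histogram(q)
    if spec.method == "li":
        return li_threshold(hist)
    t = otsu3_thresholds(hist)
    if t is None and np.count_nonzero(hist) == 2:
        # exactly two populated bins: degrade to two-class Otsu (the middle
        # class is empty), so binary-valued inputs still threshold sensibly
        lo, hi = np.flatnonzero(hist)
        return (int(lo), int(lo))
    return t


def _adaptive_threshold_maps(work: np.ndarray, spec: ThresholdSpec):
    """Per-pixel threshold map(s): per-tile thresholds bilinearly interpolated
    between tile centers; degenerate tiles inherit the global threshold."""
    h, w = work.shape
    win = int(spec.window_px)
    q = _quantize(work)
    t_global = _global_thresholds(q, spec)
    rows = list(range(0, h, win))
    cols = list(range(0, w, win))
    n_maps = 2 if spec.method == "otsu3" else 1
    grids = [np.full((len(rows), len(cols)), np.nan) for _ in range(n_maps)]
    for i, r0 in enumerate(rows):
        for j, c0 in enumerate(cols):
            t = _global_thresholds(q[r0 : r0 + win, c0 : c0 + win], spec)
            if t is None:
                t = t_global
            if t is None:
                continue
            if n_maps == 2:
                grids[0][i, j], grids[1][i, j] = t
            else:
                grids[0][i, j] = t
    if np.isnan(grids[0]).all():
        return None
    # remaining NaNs: tiles degenerate with no global fallback value
    for grid in grids:
        if np.isnan(grid).any():
            fill = np.nanmean(grid)
            grid[np.isnan(grid)] = fill
    centers_r = np.array([min(r0 + win / 2 - 0.5, h - 1) for r0 in rows])
    centers_c = np.array([min(c0 + win / 2 - 0.5, w - 1) for c0 in cols])
    rr = np.clip(np.arange(h, dtype=float), centers_r[0], centers_r[-1])
    cc = np.clip(np.arange(w, dtype=float), centers_c[0], centers_c[-1])
    pts = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    maps = []
    for grid in grids:
        if grid.size == 1:
            maps.append(np.full((h, w), grid[0, 0]))
            continue
        if len(centers_r) == 1 or len(centers_c) == 1:
            axis_vals = centers_c if len(centers_r) == 1 else centers_r
            axis_pts = pts[:, 1] if len(centers_r) == 1 else pts[:, 0]
            maps.append(np.interp(axis_pts, axis_vals, grid.ravel()).reshape(h, w))
            continue
        interp = RegularGridInterpolator((centers_r, centers_c), grid, method="linear")
        maps.append(interp(pts).reshape(h, w))
    return maps


def threshold_image(img, spec: ThresholdSpec) -> np.ndarray:
    """Binarize an intensity image according to ``spec``.

    Returns a {0, 1} uint8 raster.  For otsu3, foreground is ``v > t2``
    (middle to background) or ``v > t1`` (middle to foreground).  Degenerate
    inputs (constant, or too few gray levels) yield an all-background image
    with a warning.
    """
    img = _check_image(img)
    work = np.log(img + LOG_EPS) if spec.log_transform else img
    if spec.log_transform:
        lo, hi = work.min(), work.max()
        work = np.zeros_like(work) if hi == lo else (work - lo) / (hi - lo)
    q = _quantize(work)

    # comparisons happen in quantized bin space (thresholds are bin indices,
    # fractional for interpolated adaptive maps), so sub-quantum intensity
    # dust cannot cross a threshold
    def select(t_lo, t_hi):
        if spec.method == "li" or spec.middle_class_to == "foreground":
            return q > t_lo
        return q > t_hi

    if spec.scope == "adaptive":
        if spec.window_px >= min(img.shape):
            raise ValueError("adaptive window_px must be smaller than the image")
        maps = _adaptive_threshold_maps(work, spec)
        if maps is None:
            warnings.warn("degenerate image: thresholding produced background only")
            return np.zeros(img.shape, dtype=np.uint8)
        if spec.method == "otsu3":
            fg = select(maps[0], maps[1])
        else:
            fg = select(maps[0], maps[0])
        return fg.astype(np.uint8)

    t = _global_thresholds(q, spec)
    if t is None:
        warnings.warn("degenerate image: thresholding produced background only")
        return np.zeros(img.shape, dtype=np.uint8)
    if spec.method == "otsu3":
        fg = select(t[0], t[1])
    else:
        fg = select(t, t)
    return fg.astype(np.uint8)


def binary_close_fill(binary, disk_radius: int, max_hole_area: float) -> np.ndarray:
    """Binary closing with a disk, then fill enclosed background components
    of area <= ``max_hole_area`` (small holes such as capillaries).  The
    foreground never shrinks."""
    binary = np.asarray(binary).astype(bool)
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    structure = disk_footprint(disk_radius)
    closed = ndi.binary_erosion(
        ndi.binary_dilation(binary, structure=structure), structure=structure, border_value=1
    )
    closed |= binary
    bg = measure.label(~closed, connectivity=1)  # 4-connected background holes
    if bg.max() > 0:
        border = np.unique(
            np.concatenate([bg[0, :], bg[-1, :], bg[:, 0], bg[:, -1]])
        )
        areas = np.bincount(bg.ravel())
        fill_ids = [
            k
            for k in range(1, bg.max() + 1)
            if k not in border and areas[k] <= max_hole_area
        ]
        if fill_ids:
            closed |= np.isin(bg, fill_ids)
    return closed.astype(np.uint8)


def correct_illumination(img, smoothing_sigma: float) -> np.ndarray:
    """Flat-field correction: divide each channel by a heavily smoothed
    estimate of its illumination function, then rescale so the maximum is
    <= 1.  Works on 2-D grayscale or (h, w, 3) RGB arrays."""
    img = np.asarray(img, dtype=float)
    if smoothing_sigma <= 0:
        raise ValueError("smoothing_sigma must be positive")
    single = img.ndim == 2
    stack = img[..., None] if single else img
    out = np.empty_like(stack)
    for k in range(stack.shape[-1]):
        chan = stack[..., k]
        bg = ndi.gaussian_filter(chan, smoothing_sigma, mode="reflect")
        if np.any(bg <= 0):
            warnings.warn("illumination estimate contains zeros; flooring")
            bg = np.maximum(bg, 1e-6)
        flat = chan / bg
        # normalize by a high percentile rather than the absolute peak so a
        # few halo pixels at object borders cannot compress the whole range,
        # then clip so the output maximum stays <= 1
        ref = np.percentile(flat, 99.5)
        if ref > 1:
            flat = flat / ref
        out[..., k] = np.clip(flat, 0.0, 1.0)
    return out[..., 0] if single else out
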