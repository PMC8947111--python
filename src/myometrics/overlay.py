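"""Quality-check overlays: object outlines painted over the source image.

Default palette follows the pipelines' conventions: kept fibers red,
discarded objects yellow, nuclei yellow, shrunken fibers cyan, central
nucleus points magenta.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation

from .io import write_image

COLORS = {
    "red": (1.0, 0.0, 0.0),
    "yellow": (1.0, 1.0, 0.0),
    "cyan": (0.0, 1.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
    "purple": (0.6, 0.2, 0.8),
}


def render_overlay(base, layers) -> np.ndarray:
    """Paint label-map outlines on a grayscale or RGB base image.

    ``layers`` is an iterable of ``(labels, color)`` pairs where color is a
    name from :data:`COLORS` or an RGB triple.  Point-like objects (single
    pixels) are dilated so they stay visible.
    """
    base = np.asarray(base, dtype=float)
    rgb = np.stack([base] * 3, axis=-1) if base.ndim == 2 else base.copy()
    for labels, color in layers:
        labels = np.asarray(labels)
        if labels.max() == 0:
            continue
        color = COLORS.get(color, color)
        outline = segmentation.find_boundaries(labels, mode="inner")
        if np.count_nonzero(labels) <= labels.max() * 2:  # point-like layer
            outline = ndi.binary_dilation(labels > 0, structure=morphology.disk(2))
        rgb[outline] = color
    return np.clip(rgb, 0.0, 1.0)


def save_overlay(path, base, layers) -> None:
    write_image(path, render_overlay(base, layers))
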