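"""Basal-lamina (laminin) channel pipeline: membrane enhancement, threshold,
inversion and fiber segmentation with morphometry.

The chain enhances fiber boundaries (unsharp mask option, oriented line
openings, Hessian tubeness), bridges membrane gaps, binarizes with a
three-class Otsu threshold (middle class to background), fills small holes,
inverts so fiber interiors become foreground, splits touching fibers by
seeded watershed, and filters implausible objects on area, form factor and
solidity.  Measurements are reported in pixels, and in μm/μm² when a
calibration is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import imaging
from .imaging import ThresholdSpec
from .io import GrayImage
from .objects import DeclumpSpec, filter_objects, identify_primary_objects, measure_objects

log = logging.getLogger(__name__)

__all__ = ["FiberPipelineConfig", "FiberSegmentation", "segment_fibers", "fiber_size_distribution"]


@dataclass(frozen=True)
class FiberPipelineConfig:
    """Defaults reproduce the published fiber-segmentation parameters:
    3-class global Otsu with middle class to background (adaptive 500-px
    window variant available), 18–2000 px diameter gate, border discard, and
    filter minima of 40 px² area, 0.32 form factor, 0.75 solidity."""

    unsharp_sigma: float = 2.0
    closing_radius: int = 2
    median_radius: int = 2
    threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec("otsu3", "background", "global")
    )
    variant_adaptive: bool = False
    adaptive_window_px: int = 500
    diameter_range: tuple[float, float] = (18.0, 2000.0)
    min_area_px: float = 40.0
    min_form_factor: float = 0.32
    min_solidity: float = 0.75
    line_width: int = 2
    tubeness_sigma: float = 1.0
    enhancement_gain: float = 2.0
    enhance_input: str = "rescaled"  # or "sharpened"
    enable_enhancement: bool = True
    morph_radius: int = 2
    max_hole_area_px: float = 300.0
    declump_smoothing_sigma: float = 2.0
    um_per_px: float | None = None


@dataclass
class FiberSegmentation:
    kept: np.ndarray
    discarded: np.ndarray
    records: pd.DataFrame
    enhanced: np.ndarray | None = None  # pre-threshold image, for overlays


def _record_columns(calibrated: bool) -> list[str]:
    cols = [
        "label",
        "area_px",
        "perimeter_px",
        "form_factor",
        "solidity",
        "convex_area_px",
        "mfd_px",
        "centroid_row",
        "centroid_col",
        "touches_border",
    ]
    if calibrated:
        cols += ["csa_um2", "mfd_um"]
    return cols + ["cnf_class", "n_nuclei"]


def segment_fibers(laminin, cfg: FiberPipelineConfig | None = None) -> FiberSegmentation:
    """Run the full laminin chain and measure the kept fibers.

    ``laminin`` may be a :class:`GrayImage` (its calibration is used unless
    the config overrides it) or a bare array.  Without a calibration the
    records carry pixel units only and a warning is emitted.
    """
    cfg = cfg or FiberPipelineConfig()
    um_per_px = cfg.um_per_px
    if isinstance(laminin, GrayImage):
        um_per_px = um_per_px if um_per_px is not None else laminin.um_per_px
        img = laminin.pixels
    else:
        img = np.asarray(laminin, dtype=float)
    if um_per_px is None:
        warnings.warn("no μm/pixel calibration: fiber records carry pixel units only")

    x = imaging.rescale_full_range(img)
    base = imaging.sharpen_membranes(x, cfg.unsharp_sigma) if cfg.enhance_input == "sharpened" else x
    if cfg.enable_enhancement:
        lines = np.clip(
            imaging.enhance_line_structures(base, cfg.line_width) * cfg.enhancement_gain, 0, 1
        )
        tubes = np.clip(
            imaging.enhance_tubeness(base, cfg.tubeness_sigma) * cfg.enhancement_gain, 0, 1
        )
        y = 0.5 * (lines + tubes)
    else:
        y = base
    y = imaging.grayscale_closing(y, cfg.closing_radius)
    y = imaging.median_filter(y, cfg.median_radius)

    tspec = cfg.threshold
    if cfg.variant_adaptive:
        window = min(cfg.adaptive_window_px, min(img.shape) - 1)
        tspec = replace(tspec, scope="adaptive", window_px=window)
    binary = imaging.threshold_image(y, tspec)
    binary = imaging.binary_close_fill(binary, cfg.morph_radius, cfg.max_hole_area_px)
    inverted = (1 - binary).astype(float)

    declump = DeclumpSpec(
        seed_method="intensity",
        divide_method="shape",
        smoothing_sigma=cfg.declump_smoothing_sigma,
        min_seed_distance=cfg.diameter_range[0] / 2.0,
    )
    labels = identify_primary_objects(
        inverted,
        ThresholdSpec("li", None, "global"),
        declump,
        cfg.diameter_range,
        discard_border=True,
    )
    log.info("fiber candidates after identification: %d", labels.max())

    table = measure_objects(labels, um_per_px)
    kept, discarded = filter_objects(
        labels, table, cfg.min_area_px, cfg.min_form_factor, cfg.min_solidity
    )
    records = measure_objects(kept, um_per_px)
    records["cnf_class"] = "unset"
    records["n_nuclei"] = np.nan
    records = records.reindex(columns=_record_columns(um_per_px is not None))
    log.info("fibers kept: %d, discarded: %d", kept.max(), discarded.max())
    return FiberSegmentation(kept=kept, discarded=discarded, records=records, enhanced=y)


def fiber_size_distribution(records: pd.DataFrame, bin_width_um: float = 5.0) -> pd.DataFrame:
    """Histogram of minimum Feret diameters in contiguous bins starting at 0.

    Uses ``mfd_um`` when present, else ``mfd_px``.  Relative frequencies sum
    to 1; an empty record set yields an empty histogram.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    cols = ["bin_left", "bin_right", "count", "frequency"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    values = records["mfd_um"] if "mfd_um" in records else records["mfd_px"]
    values = values.to_numpy(dtype=float)
    n_bins = int(np.floor(values.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )
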