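"""Object identification, measurement and relation operators.

A *label map* is a 2-D non-negative integer raster: 0 is background, ``k > 0``
is object ``k``.  Objects are 8-connected; background holes are 4-connected.
Every operation that produces a label map returns contiguously renumbered
labels (1..n, ordered by original label).

Shape conventions:

* perimeter uses the Crofton formula (4 directions), which keeps the form
  factor of digital disks close to 1;
* solidity uses the rasterized convex image (pixels whose centers fall in
  the hull), so convex digital shapes score ~1;
* the minimum Feret diameter is the smallest width between two parallel
  supporting lines, computed on the corner-point convex hull by rotating
  calipers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure, segmentation

from .imaging import ThresholdSpec, disk_footprint, threshold_image

_CORNERS = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])

__all__ = [
    "DeclumpSpec",
    "ParentChildRelation",
    "identify_primary_objects",
    "measure_objects",
    "min_feret_diameter",
    "filter_objects",
    "filter_decisions",
    "resize_labels",
    "shrink_to_point",
    "mask_objects_by_overlap",
    "relate_objects",
    "classify_parents_by_children",
    "remove_labels",
]


@dataclass(frozen=True)
class DeclumpSpec:
    """How to split touching objects.

    seed_method / divide_method
        ``"intensity"`` — seeds are local maxima of the smoothed image and/or
        dividing lines follow the inverted smoothed intensity (for objects
        brighter in the middle);
        ``"shape"`` — seeds/divides come from the Euclidean distance
        transform (for objects split at indentations).
    smoothing_sigma
        Gaussian smoothing applied before intensity-based seeding.
    min_seed_distance
        Minimum spacing between watershed seeds, in pixels.
    """

    seed_method: str = "intensity"
    divide_method: str = "shape"
    smoothing_sigma: float = 2.0
    min_seed_distance: float = 5.0

    def __post_init__(self):
        if self.seed_method not in ("intensity", "shape"):
            raise ValueError(f"unknown seed_method {self.seed_method!r}")
        if self.divide_method not in ("intensity", "shape"):
            raise ValueError(f"unknown divide_method {self.divide_method!r}")
        if self.min_seed_distance <= 0:
            raise ValueError("min_seed_distance must be > 0")


@dataclass
class ParentChildRelation:
    """Assignment of child objects to at most one parent each."""

    child_to_parent: dict[int, int | None] = field(default_factory=dict)
    children_per_parent: dict[int, int] = field(default_factory=dict)

    @property
    def n_unassigned(self) -> int:
        return sum(1 for p in self.child_to_parent.values() if p is None)


def _relabel(labels: np.ndarray) -> np.ndarray:
    return segmentation.relabel_sequential(labels)[0]


def _boundary_reduce(coords: np.ndarray) -> np.ndarray:
    """Keep only boundary pixels of a pixel set; convex hulls and Feret
    widths of the corner points are unchanged."""
    r0, c0 = coords.min(axis=0)
    mask = np.zeros(coords.max(axis=0) - (r0, c0) + 1, dtype=bool)
    mask[coords[:, 0] - r0, coords[:, 1] - c0] = True
    interior = ndi.binary_erosion(mask)
    return np.argwhere(mask & ~interior) + (r0, c0)


def _declump(img: np.ndarray, binary: np.ndarray, spec: DeclumpSpec) -> np.ndarray:
    """Seeded watershed split of a foreground mask.

    Seeds are plateau-connected local maxima of the seed surface within a
    disk footprint of radius ``min_seed_distance`` — one seed per plateau, so
    constant-intensity objects are not oversegmented.
    """
    edt = None
    if "shape" in (spec.seed_method, spec.divide_method):
        edt = ndi.distance_transform_edt(binary)
    if spec.seed_method == "intensity":
        surface = ndi.gaussian_filter(img, spec.smoothing_sigma)
    else:
        surface = edt
    surface = np.where(binary, surface, -np.inf)
    fp = disk_footprint(max(1, int(round(spec.min_seed_distance))))
    maxf = ndi.maximum_filter(surface, footprint=fp, mode="constant", cval=-np.inf)
    peaks = (surface >= maxf) & binary
    markers = measure.label(peaks, connectivity=2)
    divide = -ndi.gaussian_filter(img, spec.smoothing_sigma) if spec.divide_method == "intensity" else -edt
    return segmentation.watershed(divide, markers=markers, mask=binary)


def _merge_undersized_fragments(labels: np.ndarray, dmin: float) -> np.ndarray:
    """Merge watershed fragments below the minimum diameter into their
    largest touching neighbor.

    Declumping must not manufacture objects smaller than the smallest object
    being looked for; micro-peaks along a ridge of constant intensity (e.g.
    a ring-shaped marker object) otherwise shatter one object into sub-gate
    arcs.  Isolated undersized objects are left for the diameter gate.
    """
    labels = labels.copy()
    structure = np.ones((3, 3), dtype=bool)
    for _ in range(8):  # chains of fragments merge over a few passes
        areas = np.bincount(labels.ravel())
        eq_diam = 2.0 * np.sqrt(areas / np.pi)
        small = [
            lab
            for lab in np.argsort(areas)
            if lab > 0 and areas[lab] > 0 and eq_diam[lab] < dmin
        ]
        changed = False
        for lab in small:
            mask = labels == lab
            ring = ndi.binary_dilation(mask, structure=structure) & ~mask
            neighbors = np.unique(labels[ring])
            neighbors = neighbors[neighbors > 0]
            if neighbors.size:
                target = neighbors[np.argmax(areas[neighbors])]
                labels[mask] = target
                areas[target] += areas[lab]
                areas[lab] = 0
                changed = True
        if not changed:
            break
    return labels


def identify_primary_objects(
    img,
    spec: ThresholdSpec,
    declump: DeclumpSpec | None,
    diameter_range: tuple[float, float],
    discard_border: bool = True,
) -> np.ndarray:
    """Threshold an image and split the foreground into objects.

    Objects whose equivalent circular diameter ``2*sqrt(area/pi)`` falls
    outside ``diameter_range`` are removed, as are border-touching objects
    when ``discard_border``.  With ``declump=None`` the result is plain
    8-connected component labeling of the thresholded mask.
    """
    dmin, dmax = diameter_range
    if not dmin < dmax:
        raise ValueError("diameter_range must satisfy min < max")
    img = np.asarray(img, dtype=float)
    binary = threshold_image(img, spec).astype(bool)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    if declump is None:
        labels = measure.label(binary, connectivity=2)
    else:
        labels = _declump(img, binary, declump)
        labels = _merge_undersized_fragments(labels, dmin)
    areas = np.bincount(labels.ravel())
    eq_diam = 2.0 * np.sqrt(areas / np.pi)
    bad = np.flatnonzero((eq_diam < dmin) | (eq_diam > dmax))
    bad = bad[bad > 0]
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    if discard_border:
        labels = segmentation.clear_border(labels)
    return _relabel(labels).astype(np.int32)


def min_feret_diameter(coords: np.ndarray) -> float:
    """Minimum Feret diameter of a pixel set, in pixels.

    Rotating calipers on the convex hull of the pixel corner points: the
    minimum width of a convex polygon is attained with one hull edge flush
    against a supporting line, so it suffices to take, for every hull edge,
    the farthest vertex distance from that edge, and minimize over edges.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("expected an (N, 2) array of pixel coordinates")
    if coords.shape[0] > 400:
        coords = _boundary_reduce(coords.astype(int)).astype(float)
    pts = (coords[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 2)
    hull = ConvexHull(pts)
    v = pts[hull.vertices]
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    # distance of every vertex from every edge line; width = max over vertices
    d = np.abs((v[None, :, :] - v[:, None, :]) @ normals[:, :, None]).squeeze(-1)
    return float(d.max(axis=1).min())


def _perimeter(mask: np.ndarray) -> float:
    # Crofton formula with 4 projection directions: nearly unbiased on smooth
    # digital shapes (a digital disk's form factor stays within ~1% of 1,
    # where chain-code or marching-squares lengths bias it ~5-10% low)
    return float(measure.perimeter_crofton(mask, directions=4))


def measure_objects(labels, um_per_px: float | None = None) -> pd.DataFrame:
    """Per-object shape table.

    Columns: label, area_px, perimeter_px, form_factor (4*pi*A/P^2), solidity
    (area / corner-point convex-hull area), convex_area_px, mfd_px, centroid
    and border flag; plus ``csa_um2`` and ``mfd_um`` when a calibration is
    given.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    rows = []
    for prop in measure.regionprops(labels):
        coords = prop.coords
        area = float(prop.area)
        perim = _perimeter(prop.image)
        convex_area = float(prop.area_convex)
        mr, mc = prop.bbox[0], prop.bbox[1]
        Mr, Mc = prop.bbox[2], prop.bbox[3]
        rows.append(
            {
                "label": int(prop.label),
                "area_px": area,
                "perimeter_px": perim,
                "form_factor": 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan,
                "solidity": min(area / convex_area, 1.0),
                "convex_area_px": convex_area,
                "mfd_px": min_feret_diameter(coords),
                "centroid_row": float(prop.centroid[0]),
                "centroid_col": float(prop.centroid[1]),
                "touches_border": bool(mr == 0 or mc == 0 or Mr == h or Mc == w),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
    if um_per_px is not None:
        table["csa_um2"] = table["area_px"] * um_per_px**2
        table["mfd_um"] = table["mfd_px"] * um_per_px
    return table


def filter_decisions(
    table: pd.DataFrame,
    min_area_px: float = 40.0,
    min_form_factor: float = 0.32,
    min_solidity: float = 0.75,
) -> pd.Series:
    """Keep decision per object: area, form factor and solidity must all meet
    their minimum (inclusive) thresholds."""
    return (
        (table["area_px"] >= min_area_px)
        & (table["form_factor"] >= min_form_factor)
        & (table["solidity"] >= min_solidity)
    )


def filter_objects(
    labels,
    table: pd.DataFrame,
    min_area_px: float = 40.0,
    min_form_factor: float = 0.32,
    min_solidity: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition objects into (kept, discarded) label maps by the three shape
    criteria; the discarded map supports outline overlays."""
    labels = np.asarray(labels)
    keep = filter_decisions(table, min_area_px, min_form_factor, min_solidity)
    kept_ids = table.loc[keep, "label"].to_numpy()
    kept = np.where(np.isin(labels, kept_ids), labels, 0)
    discarded = np.where(np.isin(labels, kept_ids) | (labels == 0), 0, labels)
    return _relabel(kept).astype(np.int32), _relabel(discarded).astype(np.int32)


def remove_labels(labels, ids) -> np.ndarray:
    """Programmatic edit hook: drop the given object ids and renumber."""
    labels = np.asarray(labels)
    out = np.where(np.isin(labels, np.asarray(list(ids))), 0, labels)
    return _relabel(out).astype(np.int32)


def resize_labels(labels, delta_px: int) -> np.ndarray:
    """Shrink (negative delta) or expand (positive delta) every object.

    Shrinking erodes each object independently with a disk of radius
    ``|delta|`` (labels never merge; objects may vanish).  Expansion assigns
    each background pixel within ``delta`` of an object to its nearest
    object, never overwriting another object.
    """
    labels = np.asarray(labels)
    if delta_px == 0:
        raise ValueError("delta_px must be nonzero")
    if delta_px > 0:
        out = segmentation.expand_labels(labels, distance=delta_px)
        return _relabel(out).astype(np.int32)
    r = -delta_px
    out = np.zeros_like(labels)
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = np.pad(labels[sl] == lab, 1)  # everything beyond is background
        # erosion by the discrete disk == keep pixels farther than r from the
        # complement (neighboring labels and the image border count as such)
        edt = ndi.distance_transform_edt(mask)
        out[sl][(edt > r)[1:-1, 1:-1]] = lab
    return _relabel(out).astype(np.int32)


def shrink_to_point(labels) -> np.ndarray:
    """Reduce each object to a single pixel: its centroid if inside the
    object, otherwise the object pixel nearest the centroid."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    for prop in measure.regionprops(labels):
        r = int(round(prop.centroid[0]))
        c = int(round(prop.centroid[1]))
        if not (
            0 <= r < labels.shape[0]
            and 0 <= c < labels.shape[1]
            and labels[r, c] == prop.label
        ):
            d2 = ((prop.coords - np.asarray(prop.centroid)) ** 2).sum(axis=1)
            r, c = prop.coords[int(np.argmin(d2))]
        out[r, c] = prop.label
    return _relabel(out).astype(np.int32)


def mask_objects_by_overlap(
    children, mask, min_overlap_fraction: float
) -> np.ndarray:
    """Keep a child object (entire, unclipped) iff the fraction of its pixels
    lying on any mask object is >= ``min_overlap_fraction``."""
    children = np.asarray(children)
    mask = np.asarray(mask)
    if children.shape != mask.shape:
        raise ValueError("children and mask must share dimensions")
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    n = children.max()
    if n == 0:
        return np.zeros_like(children, dtype=np.int32)
    areas = np.bincount(children.ravel(), minlength=n + 1)
    inside = np.bincount(children[mask > 0].ravel(), minlength=n + 1)
    with np.errstate(invalid="ignore"):
        frac = np.where(areas > 0, inside / np.maximum(areas, 1), 0.0)
    keep = np.flatnonzero(frac >= min_overlap_fraction)
    keep = keep[keep > 0]
    out = np.where(np.isin(children, keep), children, 0)
    return _relabel(out).astype(np.int32)


def relate_objects(children, parents) -> ParentChildRelation:
    """Assign each child to the parent owning the most of its pixels.

    Children with no parent overlap map to ``None``; ties break to the lowest
    parent label.  ``children_per_parent`` includes zero counts for every
    parent.
    """
    children = np.asarray(children)
    parents = np.asarray(parents)
    if children.shape != parents.shape:
        raise ValueError("children and parents must share dimensions")
    n_children = int(children.max())
    n_parents = int(parents.max())
    rel = ParentChildRelation(
        child_to_parent={},
        children_per_parent={p: 0 for p in range(1, n_parents + 1)},
    )
    if n_children == 0:
        return rel
    sel = children > 0
    pairs = children[sel].astype(np.int64) * (n_parents + 1) + parents[sel]
    counts = np.bincount(pairs, minlength=(n_children + 1) * (n_parents + 1))
    counts = counts.reshape(n_children + 1, n_parents + 1)
    for child in range(1, n_children + 1):
        overlap = counts[child, 1:]
        if overlap.sum() == 0:
            rel.child_to_parent[child] = None
            continue
        parent = int(np.argmax(overlap)) + 1  # first max -> lowest label
        rel.child_to_parent[child] = parent
        rel.children_per_parent[parent] += 1
    return rel


def classify_parents_by_children(rel: ParentChildRelation) -> dict[int, str]:
    """CNF iff a parent has at least one child nucleus, else PNF."""
    return {
        parent: ("CNF" if count >= 1 else "PNF")
        for parent, count in rel.children_per_parent.items()
    }
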