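"""Ground-truthed synthetic image generator.

Emulates the image structure the pipelines assume, so every stage is testable
without real micrographs:

* a polygonal fiber mosaic (Voronoi cells of Poisson-disc-sampled seeds)
  whose boundaries carry a bright, partially interrupted, noisy membrane
  signal (the basal-lamina channel);
* small bright nuclei placed centrally in some fibers, 2–3 px inside the
  boundary of others (so a 5-px fiber shrink must classify them peripheral),
  and interstitially along the membrane network;
* diffuse irregular membrane-marker blobs around a designated subset of
  interstitial nuclei (the macrophage channel);
* RGB brightfield images of yellow tissue on a white background with red
  collagen ribbons of known area fraction, rendered through the forward
  stain-transmittance model so color unmixing is well-posed.

All outputs are deterministic functions of the spec, including its RNG seed.
Truth minimum Feret diameters are computed by a dense angle sweep,
independent of the rotating-calipers implementation in :mod:`.objects`, so
the two can cross-validate each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import color as skcolor
from skimage import morphology, segmentation

from .io import GrayImage, RgbImage

_CORNERS = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])

__all__ = [
    "MosaicSpec",
    "GroundTruth",
    "SiriusTruth",
    "generate_muscle_image_set",
    "generate_sirius_image",
    "render_nuclei",
    "feret_width_sweep",
]


def _boundary_coords(coords: np.ndarray) -> np.ndarray:
    """Reduce a pixel set to its boundary pixels (projection extremes are
    unchanged, since interior pixel corners cannot be extreme)."""
    coords = np.asarray(coords)
    r0, c0 = coords.min(axis=0)
    mask = np.zeros(coords.max(axis=0) - (r0, c0) + 1, dtype=bool)
    mask[coords[:, 0] - r0, coords[:, 1] - c0] = True
    interior = ndi.binary_erosion(mask)
    return np.argwhere(mask & ~interior) + (r0, c0)


def feret_width_sweep(coords: np.ndarray, n_angles: int = 3600, refine: int = 2) -> float:
    """Minimum width over a dense angle sweep with local refinement.

    Projects the pixel corner points onto ``n_angles`` uniformly spaced
    directions, then re-sweeps a shrinking bracket around the best direction
    (the width profile has a linear kink at its minimum, so pure uniform
    sampling converges only linearly).  Used for ground-truth MFD values;
    kept deliberately independent of the rotating-calipers code path.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] > 400:
        coords = _boundary_coords(coords.astype(int)).astype(float)
    pts = (coords[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 2)

    def widths(angles):
        dirs = np.stack([np.sin(angles), np.cos(angles)], axis=1)
        proj = pts @ dirs.T
        return proj.max(axis=0) - proj.min(axis=0)

    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    w = widths(angles)
    best = int(np.argmin(w))
    lo, hi = angles[best] - np.pi / n_angles, angles[best] + np.pi / n_angles
    for _ in range(refine):
        angles = np.linspace(lo, hi, n_angles)
        w = widths(angles)
        best = int(np.argmin(w))
        step = (hi - lo) / (n_angles - 1)
        lo, hi = angles[best] - step, angles[best] + step
    return float(w.min())


@dataclass(frozen=True)
class MosaicSpec:
    """Study conditions for one synthetic muscle image set.

    Geometry defaults give ~30 fibers of 50–150 px diameter in a 512x512
    field — inside the fiber pipeline's 18–2000 px diameter gate — with
    nuclei of ~8 px diameter, inside the nucleus pipeline's 6–20 px gate.
    """

    shape: tuple[int, int] = (512, 512)
    n_fiber_seeds: int = 30
    min_seed_spacing: float = 60.0
    membrane_width_px: int = 4
    membrane_intensity: float = 0.8
    gap_fraction: float = 0.1
    noise_sd: float = 0.05
    nucleus_radius_px: int = 4
    nucleus_intensity: float = 0.9
    cnf_fraction: float = 0.3
    pnf_fraction: float = 0.3
    n_extra_interstitial_nuclei: int = 12
    macrophage_count: int = 5
    macrophage_blob_radius_px: int = 8
    macrophage_ring: bool = False
    marker_intensity: float = 0.7
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("gap_fraction", "cnf_fraction", "pnf_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cnf_fraction + self.pnf_fraction > 1.0 + 1e-12:
            raise ValueError("cnf_fraction + pnf_fraction must be <= 1")


@dataclass
class GroundTruth:
    """Pixel-consistent truth for one generated image set."""

    cell_labels: np.ndarray  # full Voronoi cells (membrane included)
    fiber_labels: np.ndarray  # fiber interiors (membrane excluded)
    fiber_table: pd.DataFrame  # label, area, MFD, class, border flag
    nucleus_labels: np.ndarray
    nucleus_table: pd.DataFrame  # label, row, col, role
    macrophage_mask: np.ndarray = field(default=None)


@dataclass
class SiriusTruth:
    tissue_mask: np.ndarray
    red_mask: np.ndarray
    red_fraction: float


def _poisson_disc(rng, shape, n, min_spacing, max_tries=40000):
    pts = []
    for _ in range(max_tries):
        cand = rng.uniform((0, 0), shape)
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_spacing**2 for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise RuntimeError(
        f"could not place {n} fiber seeds with spacing {min_spacing} in {shape}; "
        "reduce n_fiber_seeds or min_seed_spacing"
    )


def render_nuclei(
    centers, shape, radius: float, intensity: float = 0.9
) -> np.ndarray:
    """Render super-Gaussian nucleus profiles ``I = A*exp(-(d/R)^4)``.

    The quartic profile keeps an approximately flat core out to ~0.9 R, so
    thresholded nuclei recover the nominal radius.
    """
    img = np.zeros(shape, dtype=float)
    r_ext = int(np.ceil(radius * 2.2))
    yy, xx = np.mgrid[-r_ext : r_ext + 1, -r_ext : r_ext + 1]
    d = np.hypot(yy, xx)
    profile = intensity * np.exp(-((d / radius) ** 4))
    for r0, c0 in centers:
        r0, c0 = int(round(r0)), int(round(c0))
        rlo, rhi = max(0, r0 - r_ext), min(shape[0], r0 + r_ext + 1)
        clo, chi = max(0, c0 - r_ext), min(shape[1], c0 + r_ext + 1)
        patch = profile[
            rlo - (r0 - r_ext) : rhi - (r0 - r_ext),
            clo - (c0 - r_ext) : chi - (c0 - r_ext),
        ]
        np.maximum(img[rlo:rhi, clo:chi], patch, out=img[rlo:rhi, clo:chi])
    return img


def _nucleus_label_map(centers, shape, radius) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for k, (r0, c0) in enumerate(centers, start=1):
        disc = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2
        labels[disc & (labels == 0)] = k
    return labels


def _far_from_all(point, others, min_dist) -> bool:
    return all(
        (point[0] - o[0]) ** 2 + (point[1] - o[1]) ** 2 >= min_dist**2 for o in others
    )


def generate_muscle_image_set(spec: MosaicSpec):
    """Generate (laminin, dapi, marker, truth) for one synthetic field.

    Returns :class:`GrayImage` channels and a :class:`GroundTruth` whose
    label maps and tables are pixel-consistent with the emitted images.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape

    seeds = _poisson_disc(rng, spec.shape, spec.n_fiber_seeds, spec.min_seed_spacing)
    rr, cc = np.mgrid[0:h, 0:w]
    _, idx = cKDTree(seeds).query(np.column_stack([rr.ravel(), cc.ravel()]))
    cell_labels = (idx + 1).reshape(h, w).astype(np.int32)

    boundary = segmentation.find_boundaries(cell_labels, mode="thick")
    pad = max(0, int(round((spec.membrane_width_px - 2) / 2)))
    membrane = (
        ndi.binary_dilation(boundary, structure=morphology.disk(pad)) if pad else boundary
    )

    fiber_labels = np.where(membrane, 0, cell_labels).astype(np.int32)

    # per-fiber truth geometry
    border_ids = set(
        np.unique(
            np.concatenate(
                [cell_labels[0, :], cell_labels[-1, :], cell_labels[:, 0], cell_labels[:, -1]]
            )
        ).tolist()
    )
    rows = []
    interiors: dict[int, np.ndarray] = {}
    for lab in range(1, spec.n_fiber_seeds + 1):
        coords = np.argwhere(fiber_labels == lab)
        if coords.shape[0] == 0:
            continue
        interiors[lab] = coords
        rows.append(
            {
                "label": lab,
                "area_px": float(coords.shape[0]),
                "mfd_px": feret_width_sweep(coords),
                "touches_border": lab in border_ids,
                "nucleus_role": "none",
                "cnf_class": "none",
            }
        )
    fiber_table = pd.DataFrame(rows).set_index("label", drop=False)

    # laminin channel: membrane with gaps and noise
    membrane_gapped = membrane.copy()
    mem_idx = np.flatnonzero(membrane.ravel())
    n_gap = int(round(spec.gap_fraction * mem_idx.size))
    if n_gap:
        drop = rng.choice(mem_idx, size=n_gap, replace=False)
        membrane_gapped.ravel()[drop] = False
    laminin = spec.membrane_intensity * membrane_gapped.astype(float)
    if spec.noise_sd > 0:
        laminin = laminin + rng.normal(0.0, spec.noise_sd, size=laminin.shape)
    laminin = np.clip(laminin, 0.0, 1.0)

    # nucleus placement
    interior_ids = [
        lab for lab in interiors if lab not in border_ids
    ]
    order = rng.permutation(interior_ids)
    n_cnf = int(round(spec.cnf_fraction * len(interior_ids)))
    n_pnf = int(round(spec.pnf_fraction * len(interior_ids)))
    centers: list[tuple[float, float]] = []
    roles: list[str] = []
    min_sep = 2 * spec.nucleus_radius_px + 3

    for lab in order[:n_cnf]:
        com = ndi.center_of_mass(fiber_labels == lab)
        pt = (float(np.round(com[0])), float(np.round(com[1])))
        if fiber_labels[int(pt[0]), int(pt[1])] != lab:
            coords = interiors[lab]
            d2 = ((coords - np.asarray(com)) ** 2).sum(axis=1)
            pt = tuple(coords[int(np.argmin(d2))].astype(float))
        centers.append(pt)
        roles.append("central")
        fiber_table.loc[lab, ["nucleus_role", "cnf_class"]] = ("central", "CNF")

    for lab in order[n_cnf : n_cnf + n_pnf]:
        cell_mask = cell_labels == lab
        edt = ndi.distance_transform_edt(cell_mask)
        band = np.argwhere((edt >= 2.0) & (edt <= 3.0))
        if band.shape[0] == 0:
            raise RuntimeError(f"fiber {lab} too small for peripheral nucleus band")
        cand_order = rng.permutation(band.shape[0])
        placed = False
        for ci in cand_order[: min(200, band.shape[0])]:
            pt = tuple(band[ci].astype(float))
            if _far_from_all(pt, centers, min_sep):
                centers.append(pt)
                roles.append("peripheral")
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place peripheral nucleus in fiber {lab} with spacing {min_sep}"
            )
        fiber_table.loc[lab, "nucleus_role"] = "peripheral"

    # fibers without a central nucleus are peripherally nucleated by definition
    fiber_table.loc[
        (~fiber_table["touches_border"]) & (fiber_table["cnf_class"] == "none"),
        "cnf_class",
    ] = "PNF"

    # interstitial nuclei on the membrane network (macrophage hosts first,
    # with wider margins so their blobs stay clear of borders and neighbors)
    edge_dist = np.minimum.reduce([rr, cc, h - 1 - rr, w - 1 - cc])
    blob_r = spec.macrophage_blob_radius_px
    macro_margin = blob_r + spec.nucleus_radius_px + 6
    macro_sep = 2 * blob_r + spec.nucleus_radius_px + 6
    boundary_pts = np.argwhere(boundary)

    # marker blobs (main disc + satellites) reach ~1.7 blob radii; other
    # nuclei must stay outside that even after their own 2-px expansion
    blob_clearance = int(np.ceil(1.7 * blob_r)) + spec.nucleus_radius_px + 6

    def place_on_boundary(count, margin, sep, role):
        pool = boundary_pts[edge_dist[boundary_pts[:, 0], boundary_pts[:, 1]] >= margin]
        cand_order = rng.permutation(pool.shape[0])
        macro_centers = [p for p, r in zip(centers, roles) if r == "macrophage"]
        placed = 0
        for ci in cand_order:
            if placed == count:
                break
            pt = tuple(pool[ci].astype(float))
            if _far_from_all(pt, centers, sep) and (
                role == "macrophage" or _far_from_all(pt, macro_centers, blob_clearance)
            ):
                centers.append(pt)
                roles.append(role)
                placed += 1
        if placed < count:
            raise RuntimeError(
                f"could only place {placed}/{count} {role} nuclei with "
                f"margin {margin} and spacing {sep}"
            )

    place_on_boundary(spec.macrophage_count, macro_margin, macro_sep, "macrophage")
    place_on_boundary(
        spec.n_extra_interstitial_nuclei, 12, min_sep, "interstitial"
    )

    dapi = np.clip(
        render_nuclei(centers, spec.shape, spec.nucleus_radius_px, spec.nucleus_intensity),
        0.0,
        1.0,
    )
    nucleus_labels = _nucleus_label_map(centers, spec.shape, spec.nucleus_radius_px)
    nucleus_table = pd.DataFrame(
        {
            "label": np.arange(1, len(centers) + 1),
            "row": [c[0] for c in centers],
            "col": [c[1] for c in centers],
            "role": roles,
        }
    )

    # marker channel: irregular blobs (or rings) at macrophage nuclei
    macro_mask = np.zeros(spec.shape, dtype=bool)
    for pt, role in zip(centers, roles):
        if role != "macrophage":
            continue
        r0, c0 = pt
        if spec.macrophage_ring:
            # clear of the nucleus even after segmentation overshoot (~1 px),
            # yet within reach of the 2-px expansion
            inner = spec.nucleus_radius_px + 2
            outer = inner + max(3, blob_r - 2)
            d = np.hypot(rr - r0, cc - c0)
            macro_mask |= (d >= inner) & (d <= outer)
        else:
            d = np.hypot(rr - r0, cc - c0)
            blob = d <= blob_r
            for _ in range(3):
                dr, dc = rng.uniform(-0.7 * blob_r, 0.7 * blob_r, size=2)
                blob |= np.hypot(rr - r0 - dr, cc - c0 - dc) <= 0.6 * blob_r
            macro_mask |= blob
    marker = np.clip(spec.marker_intensity * macro_mask.astype(float), 0.0, 1.0)

    truth = GroundTruth(
        cell_labels=cell_labels,
        fiber_labels=fiber_labels,
        fiber_table=fiber_table.reset_index(drop=True),
        nucleus_labels=nucleus_labels,
        nucleus_table=nucleus_table,
        macrophage_mask=macro_mask,
    )
    return (
        GrayImage(laminin),
        GrayImage(dapi),
        GrayImage(marker),
        truth,
    )


# ---------------------------------------------------------------------------
# Sirius-red brightfield generator
# ---------------------------------------------------------------------------


def generate_sirius_image(
    shape: tuple[int, int] = (512, 512),
    true_fraction: float = 0.15,
    ribbon_width: int = 6,
    rng_seed: int = 0,
    illumination_gradient: float = 0.0,
    full_field: bool = False,
):
    """Yellow tissue on white background with red collagen ribbons whose
    pixel fraction of the tissue equals ``true_fraction`` (to within one
    pixel).

    Colors come from the forward stain model: per-pixel transmittance
    ``10**-(c @ M)`` where M rows are the FastRed/FastBlue/DAB absorbance
    vectors, so unmixing the image against the same vectors is well-posed.
    Ribbons carry two red-density levels (strong and medium), mimicking the
    bright-plus-faint collagen signal the three-class threshold is meant to
    separate.  ``illumination_gradient`` g applies a horizontal gain ramp
    from (1-g) to 1 for testing flat-field correction; with ``full_field``
    the tissue covers the entire raster (a section larger than the field of
    view), the regime in which smoothing-based illumination estimation is
    well-posed.
    """
    if not 0.0 <= true_fraction <= 0.6:
        raise ValueError("true_fraction must be in [0, 0.6]")
    rng = np.random.default_rng(rng_seed)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]

    # irregular tissue section (or whole-field tissue)
    if full_field:
        tissue = np.ones(shape, dtype=bool)
        rng.uniform(0, 2 * np.pi)  # keep the stream aligned with the default path
    else:
        cy, cx = h / 2, w / 2
        theta = np.arctan2(rr - cy, cc - cx)
        phase = rng.uniform(0, 2 * np.pi)
        radius = 0.44 * min(h, w) * (1 + 0.07 * np.sin(5 * theta + phase))
        tissue = np.hypot(rr - cy, cc - cx) <= radius
    tissue_px = int(tissue.sum())
    target_px = int(round(true_fraction * tissue_px))

    red_mask = np.zeros(shape, dtype=bool)
    if target_px > 0:
        n_seeds = 16
        for _ in range(6):
            seeds = rng.uniform((0, 0), shape, size=(n_seeds, 2))
            _, idx = cKDTree(seeds).query(np.column_stack([rr.ravel(), cc.ravel()]))
            cells = idx.reshape(h, w)
            ribbons = segmentation.find_boundaries(cells, mode="thick")
            ribbons = ndi.binary_dilation(
                ribbons, structure=morphology.disk(max(1, ribbon_width // 2))
            )
            red_mask = ribbons & tissue
            if red_mask.sum() >= target_px:
                break
            n_seeds *= 2
        excess = int(red_mask.sum()) - target_px
        if excess < 0:
            raise RuntimeError("could not reach requested collagen fraction")
        if excess > 0:
            drop = rng.choice(np.flatnonzero(red_mask.ravel()), size=excess, replace=False)
            red_mask.ravel()[drop] = False

    # density fields (stain "concentrations")
    block = 32
    coarse = rng.random((h // block + 1, w // block + 1)) < 0.5
    strong = coarse[rr // block, cc // block]
    c_red = np.where(red_mask, np.where(strong, 1.0, 0.55), 0.0)
    c_blue = np.where(tissue, 0.02, 0.0)
    c_dab = np.where(tissue & ~red_mask, 0.5, 0.0) + np.where(red_mask, 0.05, 0.0)

    M = skcolor.rgb_from_rbd  # rows: FastRed, FastBlue, DAB absorbance
    od = np.stack([c_red, c_blue, c_dab], axis=-1) @ M
    rgb = np.power(10.0, -od)
    if illumination_gradient > 0:
        gain = (1.0 - illumination_gradient) + illumination_gradient * (cc / (w - 1))
        rgb = rgb * gain[..., None]
    rgb = np.clip(rgb, 0.0, 1.0)

    frac = float(red_mask.sum()) / tissue_px if tissue_px else 0.0
    return RgbImage(rgb), SiriusTruth(tissue_mask=tissue, red_mask=red_mask, red_fraction=frac)
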