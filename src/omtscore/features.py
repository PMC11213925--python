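"""Per-tile morpho-spatial feature extraction.

Each retained tile is summarised by a 168-element vector:

* **104 morphological features** — 13 shape descriptors per nucleus
  (eccentricity, convex area, contour area, extent, perimeter, solidity,
  orientation, radius, major/minor axis, equivalent diameter, bounding-box
  area and aspect ratio), aggregated per nuclear type (epithelial vs other)
  with four tile-level statistics (mean, min, max, population std):
  2 x 13 x 4 = 104.
* **64 spatial features** — for each directed (reference class, neighbour
  class) pair over {epithelial, other} and each radius in {100, 200, 300,
  400} px (50-200 um at 0.50 mpp), the count of neighbour-class nuclei
  within the radius of each reference nucleus, aggregated with the same four
  statistics: 4 x 4 x 4 = 64.

Basal-epithelial nuclei are merged into the epithelial feature class.  Shape
statistics are reported in microns (px x mpp); empty classes yield zeros so
vectors stay finite.  Nuclear ellipse parameters (eccentricity, orientation,
major/minor axis) come from the ellipse with the same normalised second
central moments as the polygon region, computed analytically from exact
polygon moment integrals.  Orientation is the angle of the major axis from
the +x axis, in (-pi/2, pi/2].
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from .io import DEFAULT_MPP, NucleusClass, NucleusRecord

SHAPE_FEATURE_NAMES = [
    "eccentricity",
    "convex_area",
    "contour_area",
    "extent",
    "perimeter",
    "solidity",
    "orientation",
    "radius",
    "major_axis",
    "minor_axis",
    "equivalent_diameter",
    "bbox_area",
    "bbox_aspect_ratio",
]

STAT_NAMES = ["mean", "min", "max", "std"]
RADII_PX = [100, 200, 300, 400]
#: directed (reference class, neighbour class) pairs, canonical order
SPATIAL_PAIRS = [("epi", "epi"), ("epi", "other"), ("other", "epi"), ("other", "other")]

N_MORPHOLOGICAL = 2 * len(SHAPE_FEATURE_NAMES) * len(STAT_NAMES)  # 104
N_SPATIAL = len(SPATIAL_PAIRS) * len(RADII_PX) * len(STAT_NAMES)  # 64
N_FEATURES = N_MORPHOLOGICAL + N_SPATIAL  # 168


def feature_names() -> list[str]:
    """The 168 canonical feature column names, in vector order."""
    names = [
        f"morph_{cls}_{shape}_{stat}"
        for cls in ("epithelial", "other")
        for shape in SHAPE_FEATURE_NAMES
        for stat in STAT_NAMES
    ]
    names += [
        f"spat_{ref}_{nbr}_r{r}_{stat}"
        for ref, nbr in SPATIAL_PAIRS
        for r in RADII_PX
        for stat in STAT_NAMES
    ]
    return names


@dataclass(frozen=True)
class ShapeDescriptor:
    """The 13 per-nucleus shape scalars (lengths um, areas um^2)."""

    eccentricity: float
    convex_area: float
    contour_area: float
    extent: float
    perimeter: float
    solidity: float
    orientation: float
    radius: float
    major_axis: float
    minor_axis: float
    equivalent_diameter: float
    bbox_area: float
    bbox_aspect_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


def _polygon_moments(v: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Exact area, centroid and second central moments of a simple polygon.

    Returns (area, cx, cy, mu20, mu02, mu11) where mu are the per-area
    normalised central second moments (x-variance, y-variance, covariance).
    """
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    if area < 0:  # clockwise winding: flip
        return _polygon_moments(v[::-1])
    if area == 0:
        raise ValueError("degenerate polygon with zero area")
    cx = ((x + x1) * cross).sum() / (6 * area)
    cy = ((y + y1) * cross).sum() / (6 * area)
    ixx = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0  # integral of y^2
    iyy = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0  # integral of x^2
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mu20 = iyy / area - cx * cx
    mu02 = ixx / area - cy * cy
    mu11 = ixy / area - cx * cy
    return area, cx, cy, mu20, mu02, mu11


def shape_features(
    contour: Sequence[tuple[float, float]], mpp: float = DEFAULT_MPP
) -> ShapeDescriptor:
    """Compute the 13 shape descriptors for one nuclear contour polygon.

    ``contour`` is in pixel coordinates; outputs are in microns via ``mpp``.
    """
    v = np.asarray(contour, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise ValueError("contour needs >=3 (x, y) vertices")
    # all descriptors are translation-invariant; a local frame keeps the
    # second-moment integrals well conditioned far from the slide origin
    v = v - v.mean(axis=0)
    area_px, cx, cy, mu20, mu02, mu11 = _polygon_moments(v)
    area_px = abs(area_px)

    # moment-matched ellipse
    common = np.sqrt(4 * mu11 ** 2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2.0
    # det / lam1 avoids the cancellation in (trace - discriminant) / 2
    det = mu20 * mu02 - mu11 ** 2
    lam2 = min(max(det / lam1, 0.0), lam1) if lam1 > 0 else 0.0
    major_px = 4.0 * np.sqrt(lam1)
    minor_px = 4.0 * np.sqrt(lam2)
    eccentricity = float(np.sqrt(1.0 - lam2 / lam1)) if lam1 > 0 else 0.0
    orientation = float(0.5 * np.arctan2(2 * mu11, mu20 - mu02))

    hull_area_px = Polygon(v).convex_hull.area
    edges = np.diff(np.vstack([v, v[:1]]), axis=0)
    perimeter_px = float(np.linalg.norm(edges, axis=1).sum())
    xmin, ymin = v.min(axis=0)
    xmax, ymax = v.max(axis=0)
    bw, bh = xmax - xmin, ymax - ymin
    bbox_area_px = bw * bh
    radius_px = float(np.linalg.norm(v - [cx, cy], axis=1).mean())

    a2 = mpp * mpp  # px^2 -> um^2
    return ShapeDescriptor(
        eccentricity=min(eccentricity, np.nextafter(1.0, 0.0)),
        convex_area=hull_area_px * a2,
        contour_area=area_px * a2,
        extent=float(area_px / bbox_area_px) if bbox_area_px > 0 else 1.0,
        perimeter=perimeter_px * mpp,
        solidity=float(area_px / hull_area_px),
        orientation=orientation,
        radius=radius_px * mpp,
        major_axis=float(major_px) * mpp,
        minor_axis=float(minor_px) * mpp,
        equivalent_diameter=float(np.sqrt(4 * area_px / np.pi)) * mpp,
        bbox_area=bbox_area_px * a2,
        bbox_aspect_ratio=float(bw / bh) if bh > 0 else 1.0,
    )


def feature_class_index(model_class: NucleusClass) -> int:
    """0 for the epithelial feature class (incl. basal), 1 for other."""
    return 1 if model_class is NucleusClass.OTHER else 0


def shape_descriptor_matrix(
    nuclei: Sequence[NucleusRecord], mpp: float = DEFAULT_MPP
) -> np.ndarray:
    """(n, 13) matrix of shape descriptors, row order = input order."""
    if not nuclei:
        return np.zeros((0, len(SHAPE_FEATURE_NAMES)))
    return np.vstack([shape_features(n.contour, mpp).as_array() for n in nuclei])


def _stats(values: np.ndarray) -> np.ndarray:
    """[mean, min, max, population std] per column; zeros when empty."""
    if values.shape[0] == 0:
        return np.zeros(4 * values.shape[1])
    out = np.stack(
        [values.mean(axis=0), values.min(axis=0), values.max(axis=0), values.std(axis=0)],
        axis=1,
    )  # (n_cols, 4) so columns vary fastest over stats
    return out.ravel()


def morphological_stats(descriptors: np.ndarray, class_idx: np.ndarray) -> np.ndarray:
    """104-vector of per-class shape statistics from a descriptor matrix."""
    return np.concatenate(
        [_stats(descriptors[class_idx == c]) for c in (0, 1)]
    )


def tile_morphological_features(
    nuclei_in_tile: Sequence[NucleusRecord], mpp: float = DEFAULT_MPP
) -> np.ndarray:
    """The 104 morphological features of a tile (zeros if no nuclei)."""
    desc = shape_descriptor_matrix(nuclei_in_tile, mpp)
    cls = np.array([feature_class_index(n.model_class) for n in nuclei_in_tile], dtype=int)
    return morphological_stats(desc, cls)


def neighbor_counts(
    centroids: np.ndarray, class_idx: np.ndarray, radii: Sequence[float] = RADII_PX
) -> np.ndarray:
    """Per-nucleus neighbour counts by neighbour class and radius.

    Returns an (n, 2, n_radii) integer array: entry ``[i, c, r]`` is the
    number of class-``c`` nuclei (0 = epithelial, 1 = other) whose centroid
    lies within ``radii[r]`` px of nucleus ``i`` (Euclidean, boundary
    inclusive, excluding ``i`` itself).  Counts are confined to the supplied
    (within-tile) nuclei.
    """
    n = centroids.shape[0]
    counts = np.zeros((n, 2, len(radii)), dtype=int)
    if n == 0:
        return counts
    d = cdist(centroids, centroids)
    np.fill_diagonal(d, np.inf)  # a nucleus is never its own neighbour
    for c in (0, 1):
        dc = d[:, class_idx == c]
        for ri, r in enumerate(radii):
            counts[:, c, ri] = (dc <= r).sum(axis=1)
    return counts


def neighbor_counts_for_nuclei(
    nuclei_in_tile: Sequence[NucleusRecord], radii: Sequence[float] = RADII_PX
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper returning (counts, class_idx) for record lists."""
    cents = np.array([n.centroid for n in nuclei_in_tile], dtype=float).reshape(-1, 2)
    cls = np.array(
        [feature_class_index(n.model_class) for n in nuclei_in_tile], dtype=int
    )
    return neighbor_counts(cents, cls, radii), cls


def tile_spatial_features(counts: np.ndarray, class_idx: np.ndarray) -> np.ndarray:
    """The 64 spatial features from per-nucleus neighbour counts.

    For each directed pair the four statistics are taken over the reference
    nuclei of that pair's reference class; empty reference class gives zeros.
    """
    blocks = []
    for ref_name, nbr_name in SPATIAL_PAIRS:
        ref = 0 if ref_name == "epi" else 1
        nbr = 0 if nbr_name == "epi" else 1
        vals = counts[class_idx == ref, nbr, :].astype(float)  # (n_ref, n_radii)
        blocks.append(_stats(vals))
    return np.concatenate(blocks)


def tile_feature_vector(
    nuclei_in_tile: Sequence[NucleusRecord], mpp: float = DEFAULT_MPP
) -> np.ndarray:
    """The full 168-element tile feature vector (morphological ++ spatial)."""
    morph = tile_morphological_features(nuclei_in_tile, mpp)
    counts, cls = neighbor_counts_for_nuclei(nuclei_in_tile)
    spat = tile_spatial_features(counts, cls)
    vec = np.concatenate([morph, spat])
    assert vec.shape == (N_FEATURES,)
    return vec
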