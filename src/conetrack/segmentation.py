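"""Growth-cone segmentation and per-frame landmark geometry.

The growth cone is segmented from the diffuse cytoplasmic fluorescence of
the +TIP marker: Sobel edge detection followed by morphological cleanup
(dilation, hole filling, erosion), keeping the largest connected
component. From the mask we derive the boundary polygon, the midline
(ridge of the interior distance transform, extracted as the longest path
of the skeleton), the front arc (boundary on the tip side of the 1:1.7
midline division rule) and scalar morphology via the second-moment
equivalent ellipse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "GrowthConeGeometry",
    "NoGrowthConeError",
    "segment_growth_cone",
    "morphology_features",
    "compute_midline",
    "compute_front",
    "analyze_frame",
]

#: Fraction of midline arc length, measured from the tip, at which the
#: front/rear division point sits (the 1:1.7 front:rear partition).
FRONT_FRACTION = 1.0 / (1.0 + 1.7)


class NoGrowthConeError(ValueError):
    """Raised when no connected component above the minimum area is found."""


@dataclass
class SegmentationParams:
    """Settings of the Sobel + morphology segmentation chain.

    ``median_size`` (px, 1 disables) despeckles comet spots before edge
    detection; ``smooth_sigma`` (px) pre-smooths the frame; the Sobel
    edge band is thresholded by Otsu in log-gradient space, dilated,
    hole-filled and eroded with a disk of ``morph_radius`` to locate the
    cone; the final boundary is then refined at half the interior
    fluorescence level (``refine_level`` × the median intensity above
    the Otsu intensity threshold), which localizes the blurred edge
    without systematic bias. ``min_area_um2`` rejects debris-sized
    components; ``front_fraction`` is the tip-side share of midline arc
    length used by the front rule; ``entry_edge`` names the image edge
    from which the neurite enters (defines the proximal midline end).
    """

    median_size: int = 3
    smooth_sigma: float = 1.5
    morph_radius: int = 2
    refine_level: float = 0.5
    min_area_um2: float = 5.0
    front_fraction: float = FRONT_FRACTION
    entry_edge: str = "left"  # left | right | top | bottom
    midline_smooth_window: int = 5

    def __post_init__(self) -> None:
        if self.entry_edge not in ("left", "right", "top", "bottom"):
            raise ValueError(f"invalid entry_edge {self.entry_edge!r}")
        if not 0.0 <= self.front_fraction < 1.0:
            raise ValueError("front_fraction must be in [0, 1)")


@dataclass
class GrowthConeGeometry:
    """Per-frame growth-cone landmarks and morphology scalars.

    Polylines are (n, 2) arrays of (x, y) in μm; the midline is ordered
    proximal → tip; the front is a contiguous boundary sub-arc.
    """

    frame: int
    mask: np.ndarray
    boundary_um: np.ndarray
    midline_um: np.ndarray
    front_um: np.ndarray
    tip_um: np.ndarray
    area_um2: float
    perimeter_um: float
    length_um: float
    width_um: float
    eccentricity: float
    centroid_um: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def scalar_row(self) -> dict:
        return {
            "frame": self.frame,
            "area_um2": self.area_um2,
            "perimeter_um": self.perimeter_um,
            "length_um": self.length_um,
            "width_um": self.width_um,
            "eccentricity": self.eccentricity,
            "centroid_x_um": float(self.centroid_um[0]),
            "centroid_y_um": float(self.centroid_um[1]),
            "tip_x_um": float(self.tip_um[0]),
            "tip_y_um": float(self.tip_um[1]),
        }


def segment_growth_cone(
    frame: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Segment the growth cone from cytoplasmic background fluorescence.

    Sobel gradient magnitude → Otsu threshold → dilation → hole filling
    → erosion → keep the largest connected component.

    Raises
    ------
    NoGrowthConeError
        If no component reaches ``params.min_area_um2``.
    """
    params = params or SegmentationParams()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a single-channel 2-D image")
    if params.median_size > 1:
        img = ndimage.median_filter(img, size=params.median_size)
    img_s = (ndimage.gaussian_filter(img, params.smooth_sigma)
             if params.smooth_sigma > 0 else img)
    grad = filters.sobel(img_s)
    pos = grad[grad > 1e-9]
    if pos.size == 0 or img_s.max() <= img_s.min():
        raise NoGrowthConeError("no growth cone found: flat image")
    # Otsu in log-gradient space: robust to the dynamic-range gap between
    # cone-edge gradients and the much stronger comet-spot gradients
    edges = grad > np.exp(filters.threshold_otsu(np.log(pos)))
    selem = morphology.disk(params.morph_radius) if params.morph_radius else None
    work = morphology.dilation(edges, selem) if selem is not None else edges
    work = ndimage.binary_fill_holes(work)
    if selem is not None:
        work = morphology.erosion(work, selem)
    labels, n = ndimage.label(work)
    if n == 0:
        raise NoGrowthConeError("no growth cone found: empty segmentation")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               np.arange(1, n + 1))
    rough = labels == int(np.argmax(sizes)) + 1
    # boundary refinement: threshold at half the interior fluorescence
    # level, the unbiased localization of a blurred step edge
    t_int = filters.threshold_otsu(img_s)
    interior = img_s[img_s > t_int]
    if interior.size:
        level = params.refine_level * float(np.median(interior))
        refined = ndimage.binary_fill_holes(img_s > level)
        labels, n = ndimage.label(refined)
        if n:
            overlaps = ndimage.sum_labels(rough.astype(float), labels,
                                          np.arange(1, n + 1))
            if overlaps.max() > 0:
                rough = labels == int(np.argmax(overlaps)) + 1
    if rough.sum() * pixel_size**2 < params.min_area_um2:
        raise NoGrowthConeError(
            "no growth cone found: largest component below minimum area")
    return rough


def morphology_features(mask: np.ndarray, pixel_size: float) -> dict:
    """Morphology scalars of a binary mask, in μm units.

    Length and width are the major and minor axes of the second-moment
    equivalent ellipse; eccentricity comes from the same ellipse.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    cy, cx = props.centroid
    return {
        "area_um2": float(props.area) * pixel_size**2,
        "perimeter_um": float(props.perimeter) * pixel_size,
        "length_um": float(props.axis_major_length) * pixel_size,
        "width_um": float(props.axis_minor_length) * pixel_size,
        "eccentricity": float(props.eccentricity),
        "centroid_um": np.array([cx, cy]) * pixel_size,
    }


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton, edge weight = step length."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in pixels:
                    g.add_edge((r, c), nb, weight=math.hypot(dr, dc))
    if not g.nodes and pixels:
        g.add_nodes_from(pixels)
    return g


def _longest_skeleton_path(g: nx.Graph) -> list[tuple[int, int]]:
    """Maximum-arc-length endpoint-to-endpoint path of the skeleton graph.

    Two passes of Dijkstra from the farthest endpoints (the weighted
    double-sweep heuristic, exact on trees; skeletons are tree-like after
    skimage skeletonization).
    """
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if not comps:
        raise ValueError("empty skeleton")
    sub = g.subgraph(comps[0])
    endpoints = [n for n in sub.nodes if sub.degree(n) <= 1] or list(sub.nodes)
    start = endpoints[0]
    dist = nx.single_source_dijkstra_path_length(sub, start)
    far1 = max(dist, key=dist.get)
    dist2, paths = nx.single_source_dijkstra(sub, far1)
    far2 = max(dist2, key=dist2.get)
    return paths[far2]


def _smooth_polyline(pts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(pts) < window:
        return pts
    kernel = np.ones(window) / window
    out = pts.copy().astype(float)
    for d in range(2):
        out[:, d] = np.convolve(
            np.pad(pts[:, d].astype(float), window // 2, mode="edge"),
            kernel, mode="valid")[: len(pts)]
    out[0], out[-1] = pts[0], pts[-1]
    return out


def compute_midline(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Midline of the cone: ridge of the interior distance transform.

    The mask is skeletonized, the skeleton's maximum-arc-length
    endpoint-to-endpoint path is taken, and the path is smoothed with a
    short moving average. Returned as (n, 2) (x, y) μm ordered
    proximal → tip, where proximal is the endpoint nearer the declared
    neurite entry edge.

    Raises
    ------
    ValueError
        If the mask is empty or too small to skeletonize into a path.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.sum() < 4:
        raise ValueError("mask too small to skeletonize")
    skel = morphology.skeletonize(mask)
    if skel.sum() == 0:
        raise ValueError("mask too small to skeletonize")
    path = _longest_skeleton_path(_skeleton_graph(skel))
    if len(path) < 2:
        # rotationally symmetric mask: skeleton collapses to a point;
        # the midline degenerates to a unit segment along the major axis
        props = measure.regionprops(mask.astype(np.uint8))[0]
        ang = props.orientation
        centre = np.array([path[0][1], path[0][0]], dtype=float)
        direction = np.array([math.sin(ang), math.cos(ang)])
        pts = np.array([centre - 0.5 * direction, centre,
                        centre + 0.5 * direction])
    else:
        pts = np.array([(c, r) for r, c in path], dtype=float)  # (x, y) px
    pts = _smooth_polyline(pts, params.midline_smooth_window)
    # orient proximal → tip relative to the neurite entry edge
    h, w = mask.shape
    edge_coord = {
        "left": lambda p: p[0], "right": lambda p: w - 1 - p[0],
        "top": lambda p: p[1], "bottom": lambda p: h - 1 - p[1],
    }[params.entry_edge]
    if edge_coord(pts[0]) > edge_coord(pts[-1]):
        pts = pts[::-1]
    return pts * pixel_size


def _arc_lengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arc_length(poly: np.ndarray, s: float) -> tuple[np.ndarray, int]:
    cum = _arc_lengths(poly)
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(poly) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (s - cum[i]) / seg
    return poly[i] + t * (poly[i + 1] - poly[i]), i


def _ray_to_boundary(midline: np.ndarray, boundary: np.ndarray) -> np.ndarray:
    """Tip point: distal midline endpoint projected along the end tangent
    to the boundary.

    The skeleton-based midline stops short of the boundary, so the tip
    is found by casting a ray from the distal endpoint along the local
    midline direction and taking the nearest boundary-segment
    intersection; falls back to the nearest boundary vertex when the
    ray misses (concave tips).
    """
    end = midline[-1]
    k = max(len(midline) - 4, 0)
    direction = midline[-1] - midline[k]
    n = np.linalg.norm(direction)
    if n == 0:
        return boundary[np.argmin(np.linalg.norm(boundary - end, axis=1))].copy()
    direction = direction / n
    a = boundary
    b = np.roll(boundary, -1, axis=0)
    best_t = np.inf
    # ray end + t*direction against each boundary segment a->b
    for ai, bi in zip(a, b):
        seg = bi - ai
        denom = direction[0] * (-seg[1]) - direction[1] * (-seg[0])
        if abs(denom) < 1e-12:
            continue
        rhs = ai - end
        t = (rhs[0] * (-seg[1]) - rhs[1] * (-seg[0])) / denom
        u = (direction[0] * rhs[1] - direction[1] * rhs[0]) / denom
        if t >= 0 and 0.0 <= u <= 1.0 and t < best_t:
            best_t = t
    if not np.isfinite(best_t):
        return boundary[np.argmin(np.linalg.norm(boundary - end, axis=1))].copy()
    return end + best_t * direction


def compute_front(
    midline_um: np.ndarray,
    boundary_um: np.ndarray,
    front_fraction: float = FRONT_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Front arc and tip point from the midline division rule.

    The division point lies on the midline at ``front_fraction`` of the
    arc length from the tip end (1:1.7 front:rear partition by default).
    The front is the contiguous boundary sub-arc on the tip side of the
    line through the division point perpendicular to the local midline
    direction; the tip point is the distal midline endpoint projected to
    the nearest boundary vertex.

    Returns
    -------
    front : numpy.ndarray
        (m, 2) contiguous boundary sub-arc (μm).
    tip : numpy.ndarray
        (2,) tip point (μm).
    """
    midline = np.asarray(midline_um, dtype=float)
    boundary = np.asarray(boundary_um, dtype=float)
    if len(midline) < 3:
        raise ValueError("midline must have at least 3 points")
    if len(boundary) < 3:
        raise ValueError("boundary must have at least 3 points")
    total = _arc_lengths(midline)[-1]
    s_div = (1.0 - front_fraction) * total  # from proximal end
    div_pt, i = _point_at_arc_length(midline, s_div)
    # local midline direction, pointing tip-ward
    j0, j1 = max(i - 1, 0), min(i + 2, len(midline) - 1)
    direction = midline[j1] - midline[j0]
    n = np.linalg.norm(direction)
    if n == 0:
        direction = midline[-1] - midline[0]
        n = np.linalg.norm(direction)
    direction = direction / n
    proj = (boundary - div_pt) @ direction
    ahead = proj > 0
    tip = _ray_to_boundary(midline, boundary)
    if not ahead.any():
        # degenerate fraction (e.g. 0): collapse to the tip neighborhood
        k = int(np.argmin(np.linalg.norm(boundary - tip, axis=1)))
        idx = [(k - 1) % len(boundary), k, (k + 1) % len(boundary)]
        return boundary[idx], tip
    # contiguous circular run of `ahead` containing the most-distal vertex
    k = int(np.argmax(proj))
    m = len(boundary)
    lo = k
    while ahead[(lo - 1) % m] and (lo - 1) % m != k:
        lo -= 1
    hi = k
    while ahead[(hi + 1) % m] and (hi + 1) % m != lo % m:
        hi += 1
    idx = [(j % m) for j in range(lo, hi + 1)]
    return boundary[idx], tip


def _mask_boundary(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Closed boundary polygon of the largest contour of a mask, (x, y) μm."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    contour = max(contours, key=len)  # (row, col)
    return np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size


def analyze_frame(
    frame_or_mask: np.ndarray,
    pixel_size: float,
    params: SegmentationParams | None = None,
    frame_index: int = 0,
    is_mask: bool = False,
) -> GrowthConeGeometry:
    """Full per-frame geometry: segmentation → landmarks → morphology.

    Set ``is_mask=True`` to skip segmentation and analyze a given binary
    mask directly (used for ground-truth geometry).
    """
    params = params or SegmentationParams()
    if is_mask:
        mask = np.asarray(frame_or_mask, dtype=bool)
    else:
        mask = segment_growth_cone(frame_or_mask, params, pixel_size)
    feats = morphology_features(mask, pixel_size)
    boundary = _mask_boundary(mask, pixel_size)
    midline = compute_midline(mask, pixel_size, params)
    front, tip = compute_front(midline, boundary, params.front_fraction)
    return GrowthConeGeometry(
        frame=frame_index, mask=mask, boundary_um=boundary,
        midline_um=midline, front_um=front, tip_um=tip,
        area_um2=feats["area_um2"], perimeter_um=feats["perimeter_um"],
        length_um=feats["length_um"], width_um=feats["width_um"],
        eccentricity=feats["eccentricity"], centroid_um=feats["centroid_um"])
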