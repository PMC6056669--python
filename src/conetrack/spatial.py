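"""Comet localization relative to growth-cone landmarks.

Each detected comet position is mapped to its minimal Euclidean distance
from the front arc and from the midline; the net path of a track is
classified as anterograde, retrograde or lateral by its angle to the
local tip-ward midline tangent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import GrowthConeGeometry
from .stats import median_ci
from .tracking import CometTrack

logger = logging.getLogger(__name__)

__all__ = [
    "AngleThresholds",
    "distance_to_curve",
    "comet_landmark_distances",
    "path_angle_class",
    "front_zone_speed_profile",
]


@dataclass
class AngleThresholds:
    """Direction-class partition of path angles (degrees).

    |angle| ≤ anterograde_max → anterograde; |angle| ≥ retrograde_min →
    retrograde; otherwise lateral. Defaults split the circle into
    symmetric quadrants.
    """

    anterograde_max: float = 45.0
    retrograde_min: float = 135.0

    def __post_init__(self) -> None:
        if not 0 < self.anterograde_max < self.retrograde_min <= 180:
            raise ValueError(
                "need 0 < anterograde_max < retrograde_min <= 180")

    def classify(self, angle_deg: float) -> str:
        a = abs(angle_deg)
        if a <= self.anterograde_max:
            return "anterograde"
        if a >= self.retrograde_min:
            return "retrograde"
        return "lateral"


def distance_to_curve(point, curve) -> float:
    """Minimal Euclidean distance from a point to a polyline (μm).

    The minimum over all curve segments of the point-to-segment
    distance; a single-vertex curve degenerates to point-to-point
    distance.
    """
    p = np.asarray(point, dtype=float)
    c = np.atleast_2d(np.asarray(curve, dtype=float))
    if len(c) == 0:
        raise ValueError("empty curve")
    if len(c) == 1:
        return float(np.linalg.norm(p - c[0]))
    a, b = c[:-1], c[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.zeros(len(a))
    nz = denom > 0
    t[nz] = np.einsum("ij,ij->i", p - a[nz], ab[nz]) / denom[nz]
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def _tangent_at_nearest(midline: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Tip-ward unit tangent of the midline at its vertex nearest to point.

    Central differences on the (already smoothed) polyline.
    """
    i = int(np.argmin(np.linalg.norm(midline - point, axis=1)))
    j0, j1 = max(i - 1, 0), min(i + 1, len(midline) - 1)
    t = midline[j1] - midline[j0]
    n = np.linalg.norm(t)
    if n == 0:
        t = midline[-1] - midline[0]
        n = np.linalg.norm(t)
    return t / n


def path_angle_class(
    track: CometTrack,
    midline_um: np.ndarray,
    thresholds: AngleThresholds | None = None,
) -> tuple[float, str] | None:
    """Angle (deg, signed in [−180, 180]) of a track's net path to the
    midline tangent, and its direction class.

    The tangent is the tip-ward midline direction at the vertex nearest
    to the track's starting position. Returns None (with a warning) for
    zero net paths, which have no direction.
    """
    th = thresholds or AngleThresholds()
    net = np.asarray(track.net_path_um, dtype=float)
    norm = np.linalg.norm(net)
    if norm == 0:
        logger.warning("track %d has zero net path; direction undefined",
                       track.track_id)
        return None
    tangent = _tangent_at_nearest(np.asarray(midline_um), track.positions_um[0])
    cross = tangent[0] * net[1] - tangent[1] * net[0]
    dot = float(tangent @ net)
    angle = float(np.degrees(np.arctan2(cross, dot)))
    return angle, th.classify(angle)


def comet_landmark_distances(
    track: CometTrack,
    geometries: dict[int, GrowthConeGeometry],
    thresholds: AngleThresholds | None = None,
) -> pd.DataFrame:
    """Per-detection landmark distances and the track's direction class.

    One row per detection with distance to the front arc and to the
    midline; distance-to-front at birth and death are populated only for
    tracks that appear and disappear within the burst (otherwise birth
    and death are censored by the burst boundaries). Detections whose
    frame has no geometry are skipped with a warning.
    """
    rows = []
    angle = np.nan
    dclass = "undefined"
    first_geom = None
    for f in track.frames:
        if int(f) in geometries:
            first_geom = geometries[int(f)]
            break
    if first_geom is not None:
        res = path_angle_class(track, first_geom.midline_um, thresholds)
        if res is not None:
            angle, dclass = res
    for f, pos in zip(track.frames, track.positions_um):
        geom = geometries.get(int(f))
        if geom is None:
            logger.warning("no geometry for frame %d; record skipped", f)
            continue
        d_front = distance_to_curve(pos, geom.front_um)
        d_mid = distance_to_curve(pos, geom.midline_um)
        rows.append((track.track_id, track.burst, int(f), d_front, d_mid,
                     angle, dclass))
    df = pd.DataFrame(
        rows, columns=["track_id", "burst", "frame", "dist_front_um",
                       "dist_midline_um", "path_angle_deg", "direction_class"])
    df["dist_front_birth_um"] = np.nan
    df["dist_front_death_um"] = np.nan
    if track.complete_within_burst and len(df):
        df["dist_front_birth_um"] = df["dist_front_um"].iloc[0]
        df["dist_front_death_um"] = df["dist_front_um"].iloc[-1]
    return df


def front_zone_speed_profile(
    records: pd.DataFrame,
    bin_width_um: float = 1.0,
    speed_col: str = "speed_um_s",
    dist_col: str = "dist_front_um",
) -> pd.DataFrame:
    """Median comet speed (with CI) per distance-to-front interval.

    Instantaneous speeds are grouped by ``bin_width_um``-wide intervals
    of distance to the growth-cone front; empty bins are omitted (and
    logged). Returns a tidy frame with bin edges, n, median and the
    notch-style CI from :func:`conetrack.stats.median_ci`.
    """
    df = records.dropna(subset=[speed_col, dist_col])
    if df.empty:
        raise ValueError("no usable records")
    edges = np.arange(0.0, df[dist_col].max() + bin_width_um, bin_width_um)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = df[(df[dist_col] >= lo) & (df[dist_col] < hi)]
        if sel.empty:
            logger.info("front-distance bin [%g, %g) empty; omitted", lo, hi)
            continue
        med, lo_ci, hi_ci = median_ci(sel[speed_col].to_numpy())
        rows.append((lo, hi, len(sel), med, lo_ci, hi_ci))
    return pd.DataFrame(
        rows, columns=["bin_lo_um", "bin_hi_um", "n", "median", "ci_low",
                       "ci_high"])
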