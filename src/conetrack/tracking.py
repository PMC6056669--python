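"""EB3-comet detection and gap-closing trajectory linking.

Detection is difference-of-Gaussians band-pass filtering, local-maxima
extraction above an adaptive threshold, and intensity-weighted centroid
refinement. Linking solves a global one-to-one assignment per frame pair
(displacement-minimizing, gated by a search radius adapted between the
configured minimum and maximum), then closes gaps of up to the maximum
gap length subject to forward/backward angular cones, a shrinkage bound
on backward displacements, and a fluctuation-radius exemption for small
displacements. Tracks shorter than the minimum length are discarded.

Default parameters follow the plus-end tracking settings used for
growth-cone comets: search radius 1.5–6 px, minimum track length 3
frames, maximum gap 3 frames, shrinkage factor 1.4, forward cone 35°,
backward cone 15°, fluctuation radius 1.25 px.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "TrackingParams",
    "DetectionParams",
    "CometTrack",
    "detect_comets",
    "link_tracks",
    "filter_tracks",
    "track_kinematics",
    "tracks_to_frames",
]


@dataclass
class TrackingParams:
    """Gap-closing particle-linking constraints (pixel units for radii)."""

    search_radius_min: float = 1.5
    search_radius_max: float = 6.0
    min_track_length: int = 3
    max_gap_length: int = 3
    max_shrinkage_factor: float = 1.4
    max_forward_angle: float = 35.0
    max_backward_angle: float = 15.0
    fluctuation_radius: float = 1.25

    def __post_init__(self) -> None:
        if not 0 < self.search_radius_min <= self.search_radius_max:
            raise ValueError("need 0 < search_radius_min <= search_radius_max")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")
        if self.max_gap_length < 0:
            raise ValueError("max_gap_length must be >= 0")
        for name in ("max_forward_angle", "max_backward_angle"):
            v = getattr(self, name)
            if not 0 < v <= 180:
                raise ValueError(f"{name} must be in (0, 180]")


@dataclass
class DetectionParams:
    """Difference-of-Gaussians spot-detection settings (pixel units)."""

    sigma_small: float = 1.0
    sigma_large: float = 3.0
    threshold_factor: float = 6.0   # threshold = factor × robust SD of DoG
    min_separation: int = 2         # px between local maxima
    refine_radius: int = 4          # centroid-refinement half window
    neighbor_sigma: float = 1.6     # effective spot σ for neighbor removal
    background_median_size: int = 5  # spot-free background estimate
    dedup_radius: float = 1.5       # merge refined duplicates within (px)


@dataclass
class CometTrack:
    """One plus-end trajectory within a single burst.

    ``frames`` and ``positions_um`` cover detections only; gap frames
    are absent but implied by non-consecutive frame indices.
    """

    track_id: int
    burst: int
    frames: np.ndarray              # (n,) int, strictly increasing
    positions_um: np.ndarray        # (n, 2) float
    speeds_um_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    median_speed_um_s: float = np.nan
    lifetime_s: float = np.nan
    net_path_um: np.ndarray = field(default_factory=lambda: np.zeros(2))
    complete_within_burst: bool = False

    @property
    def n_detections(self) -> int:
        return len(self.frames)

    @property
    def birth_frame(self) -> int:
        return int(self.frames[0])

    @property
    def death_frame(self) -> int:
        return int(self.frames[-1])


def detect_comets(
    frame: np.ndarray,
    pixel_size: float,
    params: DetectionParams | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Detect comet spots in one frame; returns (n, 2) (x, y) μm positions.

    Band-pass (DoG) filtering suppresses the smooth cytoplasmic
    background; maxima above ``threshold_factor`` robust standard
    deviations of the filtered image are kept and refined to sub-pixel
    precision with an intensity-weighted centroid. An optional mask
    restricts detections to the growth cone.
    """
    p = params or DetectionParams()
    img = np.asarray(frame, dtype=float)

    def bandpass(x: np.ndarray) -> np.ndarray:
        return (ndimage.gaussian_filter(x, p.sigma_small)
                - ndimage.gaussian_filter(x, p.sigma_large))

    dog = bandpass(img)
    if p.background_median_size > 1:
        # cancel the band-pass response of the cone body and its edge:
        # the median filter removes the spots but keeps the background
        dog = dog - bandpass(ndimage.median_filter(
            img, size=p.background_median_size))
    # robust scale: MAD inside the cone (shot noise there dominates the
    # background read noise), floored at the band-pass response of shot
    # noise on the cytoplasmic background level so that residual
    # background structure never masquerades as spots in low-noise data
    region = np.asarray(mask, dtype=bool) if mask is not None else \
        np.ones_like(img, dtype=bool)
    noise_region = dog[region]
    mad = np.median(np.abs(noise_region - np.median(noise_region)))
    ss, sl = p.sigma_small**2, p.sigma_large**2
    dog_noise_gain = math.sqrt(max(
        1 / (4 * math.pi * ss) + 1 / (4 * math.pi * sl)
        - 2 / (2 * math.pi * (ss + sl)), 0.0))
    shot_floor = dog_noise_gain * math.sqrt(
        max(float(np.median(img[region])), 0.0))
    thresh = p.threshold_factor * max(1.4826 * mad, shot_floor, 1e-12)
    footprint = np.ones((2 * p.min_separation + 1,) * 2, dtype=bool)
    is_max = dog == ndimage.maximum_filter(dog, footprint=footprint)
    cand = is_max & (dog > thresh)
    if mask is not None:
        # tolerate boundary comets whose pixel rounds just outside
        cand &= ndimage.binary_dilation(np.asarray(mask, dtype=bool),
                                        iterations=2)
    rows, cols = np.nonzero(cand)
    if len(rows) == 0:
        return np.empty((0, 2))
    h, w = img.shape
    r_ref = p.refine_radius

    def centroid(image: np.ndarray, r: float, c: float) -> tuple[float, float]:
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = max(ri - r_ref, 0), min(ri + r_ref + 1, h)
        c0, c1 = max(ci - r_ref, 0), min(ci + r_ref + 1, w)
        win = image[r0:r1, c0:c1].copy()
        win[win < 0] = 0.0
        total = win.sum()
        if total <= 0:
            return float(c), float(r)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        return (float((xx * win).sum() / total),
                float((yy * win).sum() / total))

    # first pass: plain weighted centroids and peak amplitudes
    first = [centroid(dog, r, c) for r, c in zip(rows, cols)]
    amps = [float(dog[r, c]) for r, c in zip(rows, cols)]
    # second pass: re-centroid after subtracting neighboring spots,
    # which otherwise pull the window centroid toward them
    out = []
    sig = p.neighbor_sigma
    for i, (x, y) in enumerate(first):
        clean = dog
        near = [j for j in range(len(first)) if j != i
                and (first[j][0] - x) ** 2 + (first[j][1] - y) ** 2
                < (2 * r_ref + 4 * sig) ** 2]
        if near:
            clean = dog.copy()
            for j in near:
                xj, yj = first[j]
                r0 = max(int(yj) - 8, 0)
                r1 = min(int(yj) + 9, h)
                c0 = max(int(xj) - 8, 0)
                c1 = min(int(xj) + 9, w)
                yy, xx = np.mgrid[r0:r1, c0:c1]
                clean[r0:r1, c0:c1] -= amps[j] * np.exp(
                    -(((xx - xj) ** 2 + (yy - yj) ** 2)) / (2 * sig**2))
        out.append(centroid(clean, y, x))
    pts = np.array(out)
    # merge duplicates produced by plateau maxima
    order = np.argsort(-np.asarray(amps))
    keep: list[int] = []
    for i in order:
        if all(np.sum((pts[i] - pts[k]) ** 2) > p.dedup_radius**2
               for k in keep):
            keep.append(i)
    return pts[sorted(keep)] * pixel_size


# --------------------------------------------------------------------------
# linking


def _assign(prev: np.ndarray, curr: np.ndarray, radius: float,
            directions: list[np.ndarray | None] | None = None,
            mean_steps: list[float] | None = None,
            p: TrackingParams | None = None,
            pixel_size: float = 1.0) -> list[tuple[int, int]]:
    """Globally optimal one-to-one matching with distance and angle gating.

    Candidate pairs farther apart than ``radius`` are excluded. When a
    previous track has an established direction, displacements beyond
    the fluctuation radius must fall within the forward cone, or within
    the backward cone with magnitude bounded by the shrinkage factor ×
    the track's mean step. Returns (index into prev, index into curr).
    """
    if len(prev) == 0 or len(curr) == 0:
        return []
    disp = curr[None, :, :] - prev[:, None, :]
    d = np.linalg.norm(disp, axis=2)
    ok = d <= radius
    if directions is not None and p is not None:
        fluct = p.fluctuation_radius * pixel_size
        for i, direction in enumerate(directions):
            if direction is None:
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = np.clip((disp[i] @ direction)
                                 / np.where(d[i] > 0, d[i], np.inf),
                                 -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
            forward = ang <= p.max_forward_angle
            backward = (ang >= 180.0 - p.max_backward_angle) & (
                d[i] <= p.max_shrinkage_factor
                * max(mean_steps[i], fluct))
            ok[i] &= forward | backward | (d[i] <= fluct)
    big = 1e6
    cost = np.where(ok, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if cost[r, c] < big]


def _mean_direction(track_pos: list[np.ndarray]) -> np.ndarray | None:
    """Unit displacement vector over the last up-to-3 contiguous steps."""
    if len(track_pos) < 2:
        return None
    tail = track_pos[-4:]
    v = tail[-1] - tail[0]
    n = np.linalg.norm(v)
    return None if n == 0 else v / n


def _mean_step(track_pos: list[np.ndarray]) -> float:
    steps = [np.linalg.norm(b - a)
             for a, b in zip(track_pos[:-1], track_pos[1:])]
    return float(np.mean(steps)) if steps else 0.0


def link_tracks(
    spots_per_frame: list[np.ndarray],
    params: TrackingParams | None = None,
    pixel_size: float = 1.0,
    burst: int = 0,
) -> list[CometTrack]:
    """Link per-frame spot lists (μm positions) into comet tracks.

    Stage 1 matches consecutive frames by a displacement-minimizing
    global assignment gated at the adaptive search radius (clamped to
    the configured range; 3× the median per-frame displacement of the
    tracks formed so far). Stage 2 closes gaps of up to
    ``max_gap_length`` frames between track ends and later track starts,
    requiring the bridging displacement to lie within the forward cone
    of the track's recent direction (or the backward cone with magnitude
    at most ``max_shrinkage_factor`` × the track's mean growth step);
    displacements below ``fluctuation_radius`` are exempt from the
    angle tests. Tracks returned here are unfiltered; apply
    :func:`filter_tracks`.
    """
    p = params or TrackingParams()
    spots = [np.asarray(s, dtype=float).reshape(-1, 2)
             for s in spots_per_frame]
    n_frames = len(spots)
    if n_frames < 2:
        raise ValueError("need at least 2 frames of detections")

    # deterministic, order-independent: sort spots within each frame
    for f in range(n_frames):
        if len(spots[f]):
            order = np.lexsort((spots[f][:, 1], spots[f][:, 0]))
            spots[f] = spots[f][order]

    radius_max_um = p.search_radius_max * pixel_size
    radius_min_um = p.search_radius_min * pixel_size

    # stage 1: frame-to-frame assignment
    tracks: list[dict] = []      # {frames: [..], pos: [..]}
    active: dict[int, int] = {}  # spot index in current frame -> track index
    link_dists: list[float] = []
    for i in range(len(spots[0])):
        tracks.append({"frames": [0], "pos": [spots[0][i]]})
        active[i] = len(tracks) - 1
    for f in range(1, n_frames):
        steps = []
        for t in tracks:
            if len(t["pos"]) >= 2:
                steps.append(np.linalg.norm(t["pos"][-1] - t["pos"][-2]))
        if steps:
            radius = float(np.clip(3.0 * np.median(steps),
                                   radius_min_um, radius_max_um))
        else:
            radius = radius_max_um
        prev_idx = sorted(active)
        prev_pos = (np.array([tracks[active[i]]["pos"][-1] for i in prev_idx])
                    if prev_idx else np.empty((0, 2)))
        directions = [_mean_direction(tracks[active[i]]["pos"])
                      for i in prev_idx]
        mean_steps = [_mean_step(tracks[active[i]]["pos"]) for i in prev_idx]
        pairs = _assign(prev_pos, spots[f], radius, directions, mean_steps,
                        p, pixel_size)
        new_active: dict[int, int] = {}
        matched_curr = set()
        for r, c in pairs:
            ti = active[prev_idx[r]]
            link_dists.append(float(np.linalg.norm(
                spots[f][c] - tracks[ti]["pos"][-1])))
            tracks[ti]["frames"].append(f)
            tracks[ti]["pos"].append(spots[f][c])
            new_active[c] = ti
            matched_curr.add(c)
        for c in range(len(spots[f])):
            if c not in matched_curr:
                tracks.append({"frames": [f], "pos": [spots[f][c]]})
                new_active[c] = len(tracks) - 1
        active = new_active

    # stage 2: global gap closing with birth/death competition
    merged = _close_gaps(tracks, p, pixel_size, link_dists)

    out = []
    for tid, t in enumerate(merged):
        out.append(CometTrack(
            track_id=tid, burst=burst,
            frames=np.array(t["frames"], dtype=int),
            positions_um=np.array(t["pos"], dtype=float)))
    return out


def _gap_link_ok(track: dict, start_pos: np.ndarray, n_intervals: int,
                 p: TrackingParams, pixel_size: float) -> bool:
    """Angle/shrinkage/speed admissibility of bridging a gap.

    ``n_intervals`` is the number of frame intervals the bridge spans
    (gap + 1). Forward continuations must lie within the forward cone
    and be speed-consistent (within the shrinkage elasticity of the
    track's mean step × the elapsed intervals); backward continuations
    within the backward cone with magnitude bounded by the shrinkage
    factor × the mean step. Displacements below the fluctuation radius
    are always admissible.
    """
    disp = start_pos - track["pos"][-1]
    dist = float(np.linalg.norm(disp))
    fluct = p.fluctuation_radius * pixel_size
    if dist <= fluct:
        return True
    direction = _mean_direction(track["pos"])
    step = max(_mean_step(track["pos"]), fluct)
    if direction is None:
        # no established direction: accept speed-consistent distances only
        return dist <= min(p.max_shrinkage_factor * step * n_intervals,
                           p.search_radius_max * pixel_size * n_intervals)
    cosang = float(np.clip(disp @ direction / dist, -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    if ang <= p.max_forward_angle:
        return dist <= p.max_shrinkage_factor * step * n_intervals + fluct
    if ang >= 180.0 - p.max_backward_angle:
        return dist <= p.max_shrinkage_factor * step
    return False


def _close_gaps(tracks: list[dict], p: TrackingParams, pixel_size: float,
                link_dists: list[float]) -> list[dict]:
    """Global gap closing as a linear assignment with birth/death costs.

    Candidate bridges (track end → later track start, gap ≤ max gap,
    admissible per :func:`_gap_link_ok`) compete against the
    alternative of ending one track and starting another, whose cost is
    set from the upper range of the observed frame-to-frame link
    distances. Chains of accepted bridges are concatenated in one pass.
    """
    tracks = [t for t in tracks if t["frames"]]
    n = len(tracks)
    if n == 0:
        return tracks
    cands: list[tuple[int, int, float]] = []
    for i, ti in enumerate(tracks):
        for j, tj in enumerate(tracks):
            if i == j:
                continue
            gap = tj["frames"][0] - ti["frames"][-1] - 1
            if not 1 <= gap <= p.max_gap_length:
                continue
            start = np.asarray(tj["pos"][0])
            end = np.asarray(ti["pos"][-1])
            dist = float(np.linalg.norm(start - end))
            if dist > p.search_radius_max * pixel_size * (gap + 1):
                continue
            if not _gap_link_ok(ti, start, gap + 1, p, pixel_size):
                continue
            # motion-extrapolated cost: deviation from where the comet
            # would reappear if it kept moving through the gap
            direction = _mean_direction(ti["pos"])
            if direction is not None:
                predicted = end + direction * _mean_step(ti["pos"]) * (gap + 1)
                cost_ij = float(np.sum((start - predicted) ** 2))
            else:
                cost_ij = dist ** 2
            cands.append((i, j, cost_ij))
    if not cands:
        return tracks
    # birth/death alternative: a bridge must be cheaper (per interval)
    # than the upper range of ordinary frame-to-frame displacements
    if link_dists:
        alt = (1.05 * float(np.percentile(link_dists, 90))) ** 2
    else:
        alt = (p.fluctuation_radius * pixel_size) ** 2
    alt = max(alt, (p.fluctuation_radius * pixel_size) ** 2)
    big = 1e9
    cost = np.full((2 * n, 2 * n), big)
    for i, j, c in cands:
        cost[i, j] = c
    cost[np.arange(n), np.arange(n) + n] = alt       # end i dies
    cost[np.arange(n) + n, np.arange(n)] = alt       # start j is a birth
    cost[n:, n:] = 0.0                               # slack block
    rows, cols = linear_sum_assignment(cost)
    nxt: dict[int, int] = {}
    for r, c in zip(rows, cols):
        if r < n and c < n and cost[r, c] < big:
            nxt[r] = c
    continued = set(nxt.values())
    out = []
    for i in range(n):
        if i in continued:
            continue
        chain = tracks[i]
        k = i
        while k in nxt:
            k = nxt[k]
            chain["frames"].extend(tracks[k]["frames"])
            chain["pos"].extend(tracks[k]["pos"])
        out.append(chain)
    return out


def filter_tracks(
    tracks: list[CometTrack],
    params: TrackingParams | None = None,
    frames_per_burst: int | None = None,
) -> list[CometTrack]:
    """Drop tracks below the minimum detection count; flag completeness.

    A track is complete-within-burst iff its first detection is after
    frame 0 and its last detection is before the last frame of the
    burst (the comet appeared and disappeared inside the burst).
    """
    p = params or TrackingParams()
    out = []
    for t in tracks:
        if t.n_detections < p.min_track_length:
            continue
        if frames_per_burst is not None:
            t.complete_within_burst = (
                t.birth_frame > 0 and t.death_frame < frames_per_burst - 1)
        out.append(t)
    for new_id, t in enumerate(out):
        t.track_id = new_id
    return out


def track_kinematics(
    track: CometTrack,
    frame_interval: float,
) -> CometTrack:
    """Fill in instantaneous speeds, median speed, lifetime and net path.

    Instantaneous speed_i = |pos_{i+1} − pos_i| / Δt over consecutive
    detections; a step spanning a gap is divided by the full elapsed
    time and contributes a single speed sample. Lifetime runs from first
    to last detection.
    """
    pos = track.positions_um
    frames = track.frames
    if len(pos) >= 2:
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        dt = np.diff(frames) * frame_interval
        track.speeds_um_s = disp / dt
        track.median_speed_um_s = float(np.median(track.speeds_um_s))
    else:
        track.speeds_um_s = np.empty(0)
        track.median_speed_um_s = np.nan
    track.lifetime_s = float((frames[-1] - frames[0]) * frame_interval)
    track.net_path_um = pos[-1] - pos[0]
    return track


def tracks_to_frames(tracks: list[CometTrack],
                     frame_interval: float) -> pd.DataFrame:
    """Tidy per-detection table: one row per (track, frame)."""
    rows = []
    for t in tracks:
        for k, (f, (x, y)) in enumerate(zip(t.frames, t.positions_um)):
            gap_after = bool(k + 1 < len(t.frames)
                             and t.frames[k + 1] > f + 1)
            rows.append((t.track_id, t.burst, int(f), x, y, gap_after))
    return pd.DataFrame(
        rows, columns=["track_id", "burst", "frame", "x_um", "y_um",
                       "gap_after"])
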