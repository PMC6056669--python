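"""End-to-end analysis pipeline tying the stages into reproducible runs.

``run_pipeline`` executes simulate (optional) → segment → detect/track →
map → score → statistics on a single growth-cone ROI, writing every
stage's output as CSV plus a provenance JSON, all driven by a
serializable :class:`RunConfig`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ctio
from .behavior import score_behavior_series
from .schedule import AcquisitionSchedule, make_schedule
from .segmentation import GrowthConeGeometry, SegmentationParams, analyze_frame
from .simulate import SimulationConfig, simulate_sequence
from .spatial import AngleThresholds, comet_landmark_distances
from .stats import ObservationTables, assemble_observations
from .tracking import (CometTrack, DetectionParams, TrackingParams,
                       detect_comets, filter_tracks, link_tracks,
                       track_kinematics, tracks_to_frames)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_burst", "analyze_stack"]


@dataclass
class RunConfig:
    """Serializable description of one reproducible run."""

    input: str = "synthetic"   # "synthetic" or a directory of burst TIFFs
    outdir: str = "run"
    schedule: dict = field(default_factory=lambda: dict(
        frames_per_burst=33, frame_interval=2.0, burst_interval=600.0,
        n_bursts=4, pixel_size=0.211))
    simulation: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    dead_zone_um: float = 1.0
    seed: int = 0
    cone_id: int = 0
    group: str = ""

    def make_schedule(self) -> AcquisitionSchedule:
        return make_schedule(**self.schedule)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def _per_detection_speeds(track: CometTrack) -> np.ndarray:
    """Speed sample attached to each detection (step starting there)."""
    out = np.full(track.n_detections, np.nan)
    if len(track.speeds_um_s):
        out[:-1] = track.speeds_um_s
    return out


def analyze_burst(
    burst_stack: np.ndarray,
    burst: int,
    schedule: AcquisitionSchedule,
    seg_params: SegmentationParams,
    track_params: TrackingParams,
    det_params: DetectionParams,
    thresholds: AngleThresholds | None = None,
    segment_every_frame: bool = True,
) -> tuple[dict[int, GrowthConeGeometry], list[CometTrack], pd.DataFrame]:
    """Segment, detect, track and spatially map one burst.

    Returns per-frame geometries (keyed by within-burst frame index),
    kinematics-filled filtered tracks, and the merged per-detection
    record table (positions, speeds, landmark distances, direction).
    """
    px = schedule.pixel_size
    geometries: dict[int, GrowthConeGeometry] = {}
    spots = []
    for f in range(len(burst_stack)):
        if segment_every_frame or f == 0:
            geometries[f] = analyze_frame(burst_stack[f], px, seg_params,
                                          frame_index=f)
        mask = geometries[f if segment_every_frame else 0].mask
        spots.append(detect_comets(burst_stack[f], px, det_params, mask=mask))
    if not segment_every_frame:
        geometries = {f: geometries[0] for f in range(len(burst_stack))}
    tracks = link_tracks(spots, track_params, px, burst=burst)
    tracks = filter_tracks(tracks, track_params, len(burst_stack))
    tracks = [track_kinematics(t, schedule.frame_interval) for t in tracks]

    det = tracks_to_frames(tracks, schedule.frame_interval)
    speed_rows = []
    spatial_frames = []
    for t in tracks:
        sp = _per_detection_speeds(t)
        for f, s in zip(t.frames, sp):
            speed_rows.append((t.track_id, int(f), s))
        spatial_frames.append(comet_landmark_distances(t, geometries,
                                                       thresholds))
    speeds = pd.DataFrame(speed_rows,
                          columns=["track_id", "frame", "speed_um_s"])
    records = det.merge(speeds, on=["track_id", "frame"], how="left")
    if spatial_frames:
        spatial = pd.concat(spatial_frames, ignore_index=True)
        records = records.merge(
            spatial.drop(columns=["burst"]), on=["track_id", "frame"],
            how="left")
    return geometries, tracks, records


def analyze_stack(
    stack: np.ndarray,
    schedule: AcquisitionSchedule,
    seg_params: SegmentationParams | None = None,
    track_params: TrackingParams | None = None,
    det_params: DetectionParams | None = None,
    dead_zone_um: float = 1.0,
    cone_id: int = 0,
    group: str = "",
) -> dict:
    """Run the full analysis on a burst-major stack.

    Returns a dict with ``geometry`` (per-frame scalar table), ``tracks``
    (summary), ``records`` (per-detection), ``behavior`` and the
    assembled :class:`ObservationTables` under ``observations``.
    """
    seg_params = seg_params or SegmentationParams()
    track_params = track_params or TrackingParams()
    det_params = det_params or DetectionParams()
    fpb = schedule.frames_per_burst

    all_geoms: list[tuple[int, GrowthConeGeometry]] = []
    burst_first_geoms: list[GrowthConeGeometry] = []
    all_records = []
    all_tracks: list[CometTrack] = []
    track_offset = 0
    for b in range(schedule.n_bursts):
        sub = stack[b * fpb:(b + 1) * fpb]
        geoms, tracks, records = analyze_burst(
            sub, b, schedule, seg_params, track_params, det_params)
        for t in tracks:
            t.track_id += track_offset
        if len(records):
            records["track_id"] += track_offset
        track_offset += len(tracks)
        burst_first_geoms.append(geoms[0])
        for f, g in geoms.items():
            all_geoms.append((b * fpb + f, g))
        records["frame_global"] = records["frame"] + b * fpb
        all_records.append(records)
        all_tracks.extend(tracks)

    geometry_rows = []
    for gf, g in all_geoms:
        row = g.scalar_row()
        row["frame_global"] = gf
        row["burst"] = gf // fpb
        geometry_rows.append(row)
    geometry = pd.DataFrame(geometry_rows)
    geometry["cone_id"] = cone_id
    geometry["t_s"] = [schedule.time_of(r // fpb, r % fpb)
                       for r in geometry["frame_global"]]

    records = (pd.concat(all_records, ignore_index=True)
               if all_records else pd.DataFrame())
    records["cone_id"] = cone_id

    behavior = score_behavior_series(burst_first_geoms, dead_zone_um,
                                     cone_id=cone_id)

    track_rows = []
    for t in all_tracks:
        track_rows.append(dict(
            track_id=t.track_id, burst=t.burst, cone_id=cone_id,
            birth_frame=t.birth_frame, death_frame=t.death_frame,
            n_detections=t.n_detections, lifetime_s=t.lifetime_s,
            median_speed_um_s=t.median_speed_um_s,
            net_path_x_um=float(t.net_path_um[0]),
            net_path_y_um=float(t.net_path_um[1]),
            complete_within_burst=t.complete_within_burst))
    track_summary = pd.DataFrame(track_rows)

    observations = assemble_observations(geometry, records, behavior,
                                         group=group)
    return {
        "geometry": geometry,
        "tracks": track_summary,
        "records": records,
        "behavior": behavior,
        "observations": observations,
        "track_objects": all_tracks,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run and write outputs to ``config.outdir``.

    Stages: simulate (if input == "synthetic") → segment → detect/track
    → map → score → assemble. Each stage's output is written as CSV; the
    run parameters are echoed to ``provenance.json``; a plain-text log
    with stage timings goes to ``run.log``. Returns the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage: str, t0: float) -> None:
        line = f"{stage}: {time.perf_counter() - t0:.2f} s"
        log_lines.append(line)
        logger.info(line)

    schedule = config.make_schedule()
    t0 = time.perf_counter()
    if config.input == "synthetic":
        sim = SimulationConfig.from_dict(
            {**config.simulation, "seed": config.simulation.get(
                "seed", config.seed)})
        stack, truth = simulate_sequence(sim, schedule)
        ctio.write_burst_stacks(stack, schedule, outdir / "stacks")
        ctio.write_tables({"ground_truth_comets": truth.comets,
                           "ground_truth_behavior": truth.behavior},
                          outdir / "truth")
        import tifffile
        tifffile.imwrite(outdir / "truth" / "masks.tif",
                         truth.masks.astype(np.uint8),
                         photometric="minisblack")
        log("simulate", t0)
    else:
        paths = ctio.discover_bursts(config.input)
        if not paths:
            raise FileNotFoundError(
                f"no burst TIFFs found in {config.input}")
        stack = np.concatenate([ctio.read_stack(p) for p in paths])
        log("load", t0)

    t0 = time.perf_counter()
    try:
        result = analyze_stack(
            stack, schedule,
            SegmentationParams(**config.segmentation),
            TrackingParams(**config.tracking),
            DetectionParams(**config.detection),
            dead_zone_um=config.dead_zone_um,
            cone_id=config.cone_id, group=config.group)
    except Exception as exc:
        (outdir / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED: {exc}"]) + "\n")
        raise
    log("analyze", t0)

    t0 = time.perf_counter()
    ctio.write_tables({
        "geometry": result["geometry"],
        "tracks": result["tracks"],
        "records": result["records"],
        "behavior": result["behavior"],
        "cone_observations": result["observations"].cones,
        "comet_observations": result["observations"].comets,
    }, outdir)
    ctio.save_provenance(config.to_dict(), outdir / "provenance.json")
    log("write", t0)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
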