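"""Comet detection, gap-closing linking, filtering and kinematics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conetrack import (CometTrack, DetectionParams, SimulationConfig,
                       TrackingParams, detect_comets, filter_tracks,
                       link_tracks, make_schedule, simulate_sequence,
                       track_kinematics)

PX = 0.211


def _render_spot(shape, x, y, amp=300.0, sigma=1.5, background=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return background + amp * np.exp(
        -0.5 * (((xx - x) / sigma) ** 2 + ((yy - y) / sigma) ** 2))


# --------------------------------------------------------------------------
# detection


def test_single_spot_detected_subpixel():
    frame = _render_spot((64, 64), 30.3, 21.7)
    spots = detect_comets(frame, 1.0)
    assert len(spots) == 1
    assert np.linalg.norm(spots[0] - [30.3, 21.7]) < 0.5


def test_blank_frame_empty():
    rng = np.random.default_rng(0)
    frame = 100 + rng.normal(0, 3, size=(64, 64))
    assert len(detect_comets(frame, 1.0)) == 0


def test_two_spots_matched_one_to_one():
    frame = (_render_spot((64, 64), 20.0, 30.0)
             + _render_spot((64, 64), 30.0, 30.0, background=0.0))
    spots = detect_comets(frame, 1.0)
    assert len(spots) == 2
    truth = np.array([[20.0, 30.0], [30.0, 30.0]])
    d = cdist(truth, spots)
    assert d.min(axis=1).max() < 0.5
    assert len(set(d.argmin(axis=1))) == 2


# --------------------------------------------------------------------------
# linking


def test_straight_comet_single_track():
    """Unambiguous linking: one spot per frame, constant velocity."""
    spots = [np.array([[10.0 + 1.5 * f, 20.0]]) for f in range(10)]
    tracks = filter_tracks(link_tracks(spots, pixel_size=1.0),
                           frames_per_burst=10)
    assert len(tracks) == 1
    t = tracks[0]
    assert np.array_equal(t.frames, np.arange(10))
    np.testing.assert_allclose(t.positions_um[:, 0],
                               10.0 + 1.5 * np.arange(10))


def test_gap_longer_than_max_splits():
    """A 4-frame dropout exceeds the 3-frame maximum gap: two tracks."""
    spots = []
    for f in range(14):
        if 4 <= f <= 7:
            spots.append(np.empty((0, 2)))
        else:
            spots.append(np.array([[10.0 + 2.0 * f, 20.0]]))
    tracks = filter_tracks(link_tracks(spots, pixel_size=1.0),
                           frames_per_burst=14)
    assert len(tracks) == 2


def test_gap_within_max_closed():
    """A 2-frame dropout of a moving comet is bridged into one track."""
    spots = []
    for f in range(12):
        if f in (4, 5):
            spots.append(np.empty((0, 2)))
        else:
            spots.append(np.array([[10.0 + 2.0 * f, 20.0]]))
    tracks = filter_tracks(link_tracks(spots, pixel_size=1.0),
                           frames_per_burst=12)
    assert len(tracks) == 1
    assert 4 not in tracks[0].frames and 5 not in tracks[0].frames


def test_forward_angle_gate_rejects_40_degrees():
    """A gap continuation 40° off-axis beyond the fluctuation radius is
    rejected (max forward angle 35°)."""
    base = [np.array([[10.0 + 2.0 * f, 20.0]]) for f in range(5)]

    def continuation(angle_deg):
        d = 4.0  # two intervals at the track speed, > fluctuation radius
        a = np.radians(angle_deg)
        start = np.array([18.0, 20.0]) + d * np.array([np.cos(a), np.sin(a)])
        spots = list(base) + [np.empty((0, 2))]
        for k in range(3):
            spots.append(np.array([start + 2.0 * k * np.array(
                [np.cos(a), np.sin(a)])]))
        return spots

    ok = filter_tracks(link_tracks(continuation(20.0), pixel_size=1.0),
                       frames_per_burst=9)
    rej = filter_tracks(link_tracks(continuation(40.0), pixel_size=1.0),
                        frames_per_burst=9)
    assert len(ok) == 1       # within the forward cone: bridged
    assert len(rej) == 2      # outside the cone: two separate tracks


def test_linking_invariant_to_spot_order():
    rng = np.random.default_rng(3)
    spots = []
    for f in range(8):
        pts = np.array([[10.0 + f, 10.0], [30.0 - f, 30.0],
                        [20.0, 15.0 + 1.2 * f]])
        spots.append(pts)
    shuffled = [s[rng.permutation(len(s))] for s in spots]
    t1 = filter_tracks(link_tracks(spots, pixel_size=1.0), frames_per_burst=8)
    t2 = filter_tracks(link_tracks(shuffled, pixel_size=1.0),
                       frames_per_burst=8)
    key = lambda ts: sorted(tuple(map(tuple, np.round(t.positions_um, 9)))
                            for t in ts)
    assert key(t1) == key(t2)


def test_output_tracks_respect_constraints(default_sim, burst_schedule):
    """No emitted track violates the minimum-length or maximum-gap
    constraints (exhaustive check)."""
    _, stack, _ = default_sim
    params = TrackingParams()
    spots = [detect_comets(stack[f], PX) for f in range(33)]
    tracks = filter_tracks(link_tracks(spots, params, PX),
                           params, frames_per_burst=33)
    assert len(tracks) > 5
    for t in tracks:
        assert t.n_detections >= params.min_track_length
        assert np.all(np.diff(t.frames) >= 1)
        assert np.max(np.diff(t.frames)) - 1 <= params.max_gap_length


# --------------------------------------------------------------------------
# filtering and kinematics


def _track(frames, xs, ys=None):
    frames = np.asarray(frames)
    pos = np.column_stack([xs, ys if ys is not None else np.zeros(len(xs))])
    return CometTrack(track_id=0, burst=0, frames=frames, positions_um=pos)


def test_short_track_removed():
    tracks = filter_tracks([_track([0, 1], [0.0, 1.0])])
    assert tracks == []


def test_complete_within_burst_flag():
    kept = filter_tracks([_track([5, 6, 7], [0, 1, 2])],
                         frames_per_burst=33)
    assert kept[0].complete_within_burst is True
    border = filter_tracks([_track([0, 1, 2], [0, 1, 2])],
                           frames_per_burst=33)
    assert border[0].complete_within_burst is False
    tail = filter_tracks([_track([30, 31, 32], [0, 1, 2])],
                         frames_per_burst=33)
    assert tail[0].complete_within_burst is False


def test_kinematics_arithmetic():
    """0.22 μm per 2-s frame → 0.11 μm/s instantaneous speed."""
    t = _track([0, 1, 2, 3], [0.0, 0.22, 0.44, 0.66])
    t = track_kinematics(t, 2.0)
    np.testing.assert_allclose(t.speeds_um_s, 0.11)
    assert t.median_speed_um_s == pytest.approx(0.11)
    assert t.lifetime_s == pytest.approx(6.0)
    np.testing.assert_allclose(t.net_path_um, [0.66, 0.0])


def test_stationary_comet_zero_speed():
    t = track_kinematics(_track([0, 1, 2], [5.0, 5.0, 5.0]), 2.0)
    np.testing.assert_allclose(t.speeds_um_s, 0.0)
    np.testing.assert_allclose(t.net_path_um, 0.0)


def test_gap_spanning_speed_attribution():
    """A gap-crossing displacement is divided by the full elapsed time
    and yields a single speed sample."""
    t = _track([0, 1, 4], [0.0, 0.2, 0.8])
    t = track_kinematics(t, 2.0)
    np.testing.assert_allclose(t.speeds_um_s, [0.1, 0.1])


@pytest.mark.parametrize("median,rel", [
    # at 0.05 μm/s a 2-s step is 0.47 px; the shot-noise localization
    # floor (~0.08 px per axis at the default photon budget) inflates
    # per-step speeds of such slow comets irreducibly, so the recovery
    # bound is wider there
    (0.05, 0.15),
    (0.11, 0.05),
    (0.20, 0.05),
])
def test_median_speed_recovery_across_medians(median, rel):
    """Pipeline median-speed bias across configured speed medians at
    default noise, on an optically resolvable comet field."""
    s = make_schedule(33, 2, 600, 2, PX)
    cfg = SimulationConfig(seed=20, speed_median_um_s=median,
                           birth_rate_per_um2_s=0.004,
                           min_birth_separation_um=2.5)
    stack, truth = simulate_sequence(cfg, s)
    speeds = []
    for b in range(2):
        spots = [detect_comets(stack[b * 33 + f], PX,
                               mask=truth.masks[b * 33 + f])
                 for f in range(33)]
        tracks = filter_tracks(link_tracks(spots, pixel_size=PX, burst=b),
                               frames_per_burst=33)
        for t in tracks:
            t = track_kinematics(t, 2.0)
            speeds.extend(t.speeds_um_s)
    true_med = np.nanmedian(truth.comets.step_speed_um_s)
    assert np.median(speeds) == pytest.approx(true_med, rel=rel)


def test_noise_free_single_track_recovery():
    """≥95% of ground-truth comets with ≥3 rendered frames come back as
    one track each (no splits or merges) on a noise-free, optically
    resolvable field, with sub-half-pixel positions."""
    from collections import Counter
    s = make_schedule(33, 2, 600, 3, PX)
    per = Counter()
    pos_errs = []
    n_truth = 0
    for seed in (5, 6, 7):
        cfg = SimulationConfig(seed=seed, birth_rate_per_um2_s=0.004,
                               min_birth_separation_um=2.5,
                               poisson_noise=False, read_noise_sigma=0.0)
        stack, truth = simulate_sequence(cfg, s)
        tc = truth.comets
        local = Counter()
        for b in range(3):
            spots = [detect_comets(stack[b * 33 + f], PX,
                                   mask=truth.masks[b * 33 + f])
                     for f in range(33)]
            tracks = filter_tracks(link_tracks(spots, pixel_size=PX, burst=b),
                                   frames_per_burst=33)
            for t in tracks:
                ids = []
                for f, pos in zip(t.frames, t.positions_um):
                    sub = tc[(tc.burst == b) & (tc.frame == f)]
                    d = np.linalg.norm(
                        sub[["x_um", "y_um"]].to_numpy() - pos, axis=1)
                    if len(d) and d.min() < 0.25:
                        ids.append(int(sub.comet_id.iloc[d.argmin()]))
                        pos_errs.append(d.min())
                    else:
                        ids.append(-1)
                c = Counter(i for i in ids if i >= 0)
                if not c:
                    continue
                main, cnt = c.most_common(1)[0]
                if cnt / len(ids) >= 0.8:
                    local[main] += 1
        gt = truth.comet_summary[truth.comet_summary.n_frames >= 3]
        n_truth += len(gt)
        for cid in gt.comet_id:
            if local.get(cid, 0) == 1:
                per["single"] += 1
    assert n_truth >= 50
    assert per["single"] / n_truth >= 0.95
    assert np.mean(pos_errs) < 0.5 * PX
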