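"""Turn-angle rule, switch detection, classification, frequency statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myxotrack.pipeline import PipelineConfig, build_event_table
from myxotrack.reversals import (
    call_directional_changes,
    classify_events,
    compute_turn_angle,
    detect_fluor_switches,
    reversal_statistics,
)
from myxotrack.simulate import SimulationConfig, simulate_trajectories, tracks_from_truth
from myxotrack.tracking import Track


def _track(centroids, i1=None, i2=None, frame_interval=15.0):
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    i1 = np.ones(n) if i1 is None else np.asarray(i1, dtype=float)
    i2 = np.zeros(n) if i2 is None else np.asarray(i2, dtype=float)
    return Track(
        track_id=0, frames=np.arange(n), x=pts[:, 0], y=pts[:, 1],
        pole1=pts.copy(), pole2=pts.copy(), pole1_intensity=i1,
        pole2_intensity=i2, length=np.full(n, 5.0), area=np.full(n, 3.4),
        orientation=np.zeros(n), frame_interval=frame_interval,
    )


@pytest.mark.parametrize("triplet,expected", [
    (((0, 0), (1, 0), (2, 0)), 180.0),   # collinear forward
    (((0, 0), (1, 0), (0, 0)), 0.0),     # exact retrace
    (((0, 0), (1, 0), (1, 1)), 90.0),    # right angle
])
def test_turn_angle_unit_triplets(triplet, expected):
    p_prev, p, p_next = (np.array(v, dtype=float) for v in triplet)
    assert compute_turn_angle(p_prev, p, p_next) == pytest.approx(expected, abs=1e-9)


def test_turn_angle_undefined_below_min_step():
    assert compute_turn_angle((0, 0), (0.05, 0), (0.1, 0), min_step=0.1) is None
    assert compute_turn_angle((0, 0), (0, 0), (1, 0)) is None  # zero step


@given(
    st.floats(-math.pi, math.pi),
    st.floats(-50, 50), st.floats(-50, 50),
    st.floats(0.1, 20),
)
@settings(max_examples=60, deadline=None)
def test_turn_angle_invariant_under_similarity_transforms(theta, tx, ty, scale):
    pts = [np.array([0.0, 0.0]), np.array([1.0, 0.0]), np.array([1.7, 0.9])]
    base = compute_turn_angle(*pts)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    moved = [scale * (rot @ p) + np.array([tx, ty]) for p in pts]
    assert compute_turn_angle(*moved) == pytest.approx(base, abs=1e-6)


def test_straight_track_has_zero_events():
    tr = _track([(0.4 * t, 0.0) for t in range(40)])
    assert call_directional_changes(tr) == []


def test_single_retrace_gives_one_event_at_the_vertex():
    xs = list(np.arange(0, 10, 0.5)) + list(np.arange(10, 3, -0.5))
    tr = _track([(x, 0.0) for x in xs])
    events = call_directional_changes(tr)
    assert len(events) == 1
    assert events[0].frame == 20  # the vertex of the retrace
    assert events[0].turn_angle == pytest.approx(0.0, abs=1e-9)


def _zigzag(n_segments=20, angles=(30.0, 170.0), step=1.0):
    """Polyline whose vertex angles alternate between the given values."""
    pts = [np.zeros(2)]
    heading = 0.0
    for k in range(n_segments):
        if k > 0:
            vertex_angle = angles[(k - 1) % 2]
            heading += 180.0 - vertex_angle  # exterior turn
        u = np.array([math.cos(math.radians(heading)),
                      math.sin(math.radians(heading))])
        pts.append(pts[-1] + step * u)
    return np.array(pts)


def test_zigzag_event_count_matches_vertex_enumeration():
    pts = _zigzag(20)
    tr = _track(pts)
    events = call_directional_changes(tr, refractory=0)
    # independent oracle: brute-force count over every vertex
    expected = sum(
        1 for t in range(1, len(pts) - 1)
        if compute_turn_angle(pts[t - 1], pts[t], pts[t + 1]) < 90.0
    )
    assert expected == 10
    assert len(events) == expected


def test_ninety_degree_vertex_is_not_a_reversal():
    tr = _track([(0, 0), (1, 0), (1, 1)])
    assert call_directional_changes(tr, refractory=0) == []


def test_refractory_window_merges_adjacent_vertices():
    # a retrace spanning two vertices (out, back, out) -> one event kept
    tr = _track([(0, 0), (1, 0), (0.2, 0), (1.2, 0), (2.2, 0), (3.2, 0)])
    events = call_directional_changes(tr, refractory=2)
    assert len(events) == 1
    assert events[0].frame == 1
    assert len(call_directional_changes(tr, refractory=0)) == 2


def test_switch_detection_constant_dominance_none():
    n = 30
    tr = _track([(0.4 * t, 0) for t in range(n)],
                i1=np.full(n, 2.0), i2=np.full(n, 1.0))
    assert detect_fluor_switches(tr) == []


def test_switch_detected_at_step_exchange():
    n = 40
    i1 = np.where(np.arange(n) < 20, 2.0, 0.5)
    i2 = np.where(np.arange(n) < 20, 0.5, 2.0)
    tr = _track([(0.4 * t, 0) for t in range(n)], i1=i1, i2=i2)
    switches = detect_fluor_switches(tr, smoothing=3, min_persistence=2)
    assert len(switches) == 1
    assert abs(switches[0].frame - 20) <= 1  # within smoothing half-width
    assert switches[0].pre_dominant == "pole1"
    assert switches[0].post_dominant == "pole2"


def test_one_frame_flicker_is_not_a_switch():
    n = 30
    i1 = np.full(n, 2.0)
    i1[15] = 0.1
    i2 = np.full(n, 1.0)
    tr = _track([(0.4 * t, 0) for t in range(n)], i1=i1, i2=i2)
    assert detect_fluor_switches(tr, smoothing=1, min_persistence=3) == []


def test_all_zero_fluorescence_warns_and_returns_nothing():
    n = 10
    tr = _track([(0.4 * t, 0) for t in range(n)],
                i1=np.zeros(n), i2=np.zeros(n))
    with pytest.warns(UserWarning, match="all-zero"):
        assert detect_fluor_switches(tr) == []


def test_classification_window_and_modes():
    from myxotrack.reversals import DirectionalChangeEvent, SwitchEvent

    ev = [DirectionalChangeEvent(track_id=0, frame=10, turn_angle=5.0,
                                 step_before=0.4, step_after=0.4)]
    sw = [SwitchEvent(track_id=0, frame=11, pre_dominant="pole1",
                      post_dominant="pole2", persistence=5)]
    out = classify_events(list(ev), sw, window=2)
    assert out[0].classification == "confirmed"
    assert out[0].matched_switch_frame == 11

    ev2 = [DirectionalChangeEvent(track_id=0, frame=10, turn_angle=5.0,
                                  step_before=0.4, step_after=0.4)]
    assert classify_events(ev2, [], window=2)[0].classification == "stick_slip"
    ev3 = [DirectionalChangeEvent(track_id=0, frame=10, turn_angle=5.0,
                                  step_before=0.4, step_after=0.4)]
    out3 = classify_events(ev3, [], window=2, fluorescence_available=False)
    assert out3[0].classification == "unconfirmed"

    # out-of-window switch does not confirm
    ev4 = [DirectionalChangeEvent(track_id=0, frame=10, turn_angle=5.0,
                                  step_before=0.4, step_after=0.4)]
    sw4 = [SwitchEvent(track_id=0, frame=14, pre_dominant="pole1",
                       post_dominant="pole2", persistence=5)]
    assert classify_events(ev4, sw4, window=2)[0].classification == "stick_slip"


def test_population_event_recovery_on_exact_trajectories():
    """Reversals and stick-slips fully separated on noise-free tracks."""
    cfg = SimulationConfig(
        n_cells=40, duration=1800.0, reversal_rate=0.1, stickslip_rate=0.1,
        noise_sd=0.0, confine=False, field_size=(30000, 30000), rng_seed=77,
    )
    truth = simulate_trajectories(cfg)
    tracks = tracks_from_truth(truth)
    events_df = build_event_table(tracks, PipelineConfig())
    dt = cfg.frame_interval
    true_rev = {(c, int(round(t / dt))) for c, t in truth.true_reversals}
    true_ss = {(c, int(round(t / dt))) for c, t in truth.true_stickslips}
    confirmed = events_df[events_df.classification == "confirmed"]
    called = {(int(r.track_id), int(r.frame)) for r in confirmed.itertuples()}
    matched = {(c, f) for c, f in called
               if any((c, g) in true_rev for g in (f - 1, f, f + 1))}
    assert len(matched) == len(called) == len(true_rev)  # precision = recall = 1
    # no confirmed call lands on a stick-slip
    for c, f in called:
        assert not any((c, g) in true_ss for g in (f - 1, f, f + 1))


def test_event_count_hierarchy_invariant():
    """confirmed <= directional changes <= interior vertices."""
    cfg = SimulationConfig(n_cells=10, duration=1800.0, noise_sd=0.0,
                           confine=False, field_size=(30000, 30000), rng_seed=13)
    truth = simulate_trajectories(cfg)
    for track in tracks_from_truth(truth):
        changes = call_directional_changes(track)
        switches = detect_fluor_switches(track)
        classified = classify_events(changes, switches)
        n_confirmed = sum(e.classification == "confirmed" for e in classified)
        assert n_confirmed <= len(changes) <= track.n_frames - 2


def test_reversal_statistics_arithmetic():
    n = 121  # 30 min at 15 s
    tr = _track([(0.4 * t, 0) for t in range(n)])
    from myxotrack.reversals import DirectionalChangeEvent

    frames = [10, 20, 40, 70, 90, 110]
    events = [DirectionalChangeEvent(track_id=0, frame=f, turn_angle=0.0,
                                     step_before=0.4, step_after=0.4,
                                     classification="confirmed")
              for f in frames]
    stats = reversal_statistics(tr, events, mode="confirmed")
    assert stats["frequency_per_10min"] == pytest.approx(2.0)
    gaps_min = np.diff(frames) * 15.0 / 60.0
    assert stats["mean_inter_reversal_min"] == pytest.approx(gaps_min.mean())

    none = reversal_statistics(tr, [], mode="confirmed")
    assert none["frequency_per_10min"] == 0.0
    assert none["mean_inter_reversal_min"] is None


def test_frequency_estimator_unbiased_on_poisson_truth():
    # lambda = 0.1/min -> 1.0 per 10 min; estimate within 2 SE over 100 cells
    cfg = SimulationConfig(
        n_cells=100, duration=1800.0, reversal_rate=0.1, stickslip_rate=0.1,
        noise_sd=0.0, confine=False, field_size=(50000, 50000), rng_seed=55,
    )
    truth = simulate_trajectories(cfg)
    tracks = tracks_from_truth(truth)
    events_df = build_event_table(tracks, PipelineConfig())
    freqs = []
    for track in tracks:
        sub = events_df[(events_df.track_id == track.track_id)
                        & (events_df.classification == "confirmed")]
        freqs.append(len(sub) / (track.duration / 60.0) * 10.0)
    freqs = np.array(freqs)
    se = freqs.std(ddof=1) / math.sqrt(len(freqs))
    assert abs(freqs.mean() - 1.0) <= 2 * se


def test_precision_degrades_monotonically_with_noise(small_run):
    """Noise ladder: confirmed-call precision never improves with noise."""
    import myxotrack as mt

    cfg0, _, _, _ = small_run
    precisions = []
    for noise in (0.0, 60.0, 200.0):
        cfg = SimulationConfig(n_cells=6, duration=900.0, noise_sd=noise,
                               rng_seed=11)
        truth = simulate_trajectories(cfg)
        stack = mt.render_movie(truth, cfg)
        res = mt.run_pipeline(mt.PipelineConfig(), stack=stack)
        rep = mt.validate(res.tracks, res.events_df, truth)
        precisions.append(rep.precision)
    assert precisions[0] == 1.0
    assert all(a >= b for a, b in zip(precisions, precisions[1:]))
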