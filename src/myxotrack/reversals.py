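"""Calling reversals from tracks and polar fluorescence.

A candidate directional change is a trajectory vertex: the angle at the
cell center at time t between the segments to the centers at t-1 and t+1.
Straight motion gives 180 degrees, an exact retrace 0 degrees; a vertex
angle strictly below the threshold (default 90 degrees) with both steps
above a minimum displacement is scored as a directional change.

Genuine reversals exchange the polarity marker between the poles, so each
directional change is then correlated with the crossings of the two
smoothed per-pole fluorescence intensity traces: changes with a crossing
within the correlation window are confirmed reversals, changes without one
are discarded as stick-slip motions.  Without a fluorescence channel the
changes stay unconfirmed (pure-motion counts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from myxotrack.tracking import Track

__all__ = [
    "DirectionalChangeEvent",
    "SwitchEvent",
    "compute_turn_angle",
    "call_directional_changes",
    "detect_fluor_switches",
    "classify_events",
    "reversal_statistics",
]


@dataclass
class DirectionalChangeEvent:
    """A trajectory vertex scored as a directional change."""

    track_id: int
    frame: int                    # vertex frame (time t)
    turn_angle: float             # degrees at the vertex, 0..180
    step_before: float            # µm, t-1 -> t
    step_after: float             # µm, t -> t+1
    classification: str = "unconfirmed"   # confirmed | stick_slip | unconfirmed
    matched_switch_frame: int | None = None


@dataclass
class SwitchEvent:
    """A crossing of the two per-pole fluorescence traces."""

    track_id: int
    frame: int                    # first frame with the new dominant pole
    pre_dominant: str             # "pole1" or "pole2"
    post_dominant: str
    persistence: int              # frames the new sign persists


def compute_turn_angle(
    p_prev: np.ndarray,
    p: np.ndarray,
    p_next: np.ndarray,
    min_step: float = 0.0,
) -> float | None:
    """Vertex angle (degrees) at ``p`` between (p_prev - p) and (p_next - p).

    Collinear forward motion gives 180, an exact retrace 0.  If either
    step is shorter than ``min_step`` the angle is undefined (``None``):
    a displacement gate that keeps localization jitter from producing
    pseudo-angles.  Invariant under rotation, translation and uniform
    scaling of the three points.
    """
    v1 = np.asarray(p_prev, dtype=float) - np.asarray(p, dtype=float)
    v2 = np.asarray(p_next, dtype=float) - np.asarray(p, dtype=float)
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if n1 < min_step or n2 < min_step or n1 == 0.0 or n2 == 0.0:
        return None
    cosang = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def call_directional_changes(
    track: Track,
    angle_threshold: float = 90.0,
    min_step: float = 0.1,
    refractory: int = 2,
) -> list[DirectionalChangeEvent]:
    """Score directional changes at trajectory vertices.

    An event is called at every vertex whose angle is defined (both steps
    at least ``min_step`` µm) and strictly below ``angle_threshold``
    degrees; 90 degrees exactly is not a reversal.  Events within
    ``refractory`` frames of the previously kept event are merged into it
    (the earliest vertex is kept), so one physical reversal spanning two
    vertices is counted once.
    """
    events: list[DirectionalChangeEvent] = []
    if track.n_frames < 3:
        return events
    pts = track.centroids
    last_kept = -10 * (refractory + 1)
    for t in range(1, track.n_frames - 1):
        angle = compute_turn_angle(pts[t - 1], pts[t], pts[t + 1], min_step=min_step)
        if angle is None or angle >= angle_threshold:
            continue
        if t - last_kept <= refractory:
            continue  # merged into the previous event
        events.append(DirectionalChangeEvent(
            track_id=track.track_id,
            frame=int(track.frames[t]),
            turn_angle=angle,
            step_before=float(np.hypot(*(pts[t] - pts[t - 1]))),
            step_after=float(np.hypot(*(pts[t + 1] - pts[t]))),
        ))
        last_kept = t
    return events


def _moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return np.asarray(series, dtype=float)
    s = np.asarray(series, dtype=float)
    half = window // 2
    out = np.empty_like(s)
    for i in range(len(s)):
        lo = max(0, i - half)
        hi = min(len(s), i + half + 1)
        out[i] = s[lo:hi].mean()
    return out


def detect_fluor_switches(
    track: Track,
    smoothing: int = 3,
    min_persistence: int = 2,
) -> list[SwitchEvent]:
    """Find pole-to-pole exchanges of the fluorescent marker.

    Both per-pole intensity traces are smoothed by a centered moving
    average; a switch is recorded at each sign change of (pole1 - pole2)
    whose new sign persists for at least ``min_persistence`` frames, i.e.
    at each crossing of the two traces.  Zero differences inherit the
    previous sign so plateaus do not create spurious switches.
    """
    i1 = np.asarray(track.pole1_intensity, dtype=float)
    i2 = np.asarray(track.pole2_intensity, dtype=float)
    if np.all(np.nan_to_num(i1) == 0) and np.all(np.nan_to_num(i2) == 0):
        warnings.warn(f"track {track.track_id}: all-zero fluorescence, no switches")
        return []
    diff = _moving_average(i1, smoothing) - _moving_average(i2, smoothing)
    signs = np.sign(diff)
    for i in range(1, len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    # leading zeros take the first nonzero sign
    nz = np.nonzero(signs)[0]
    if len(nz) == 0:
        return []
    signs[: nz[0]] = signs[nz[0]]

    switches: list[SwitchEvent] = []
    run_start = 0
    runs: list[tuple[int, int, float]] = []  # (start, length, sign)
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[run_start]:
            runs.append((run_start, i - run_start, signs[run_start]))
            run_start = i
    dominant = runs[0][2]
    for start, length, sign in runs[1:]:
        # a run too short to persist never changes the dominant pole
        if length < min_persistence or sign == dominant:
            continue
        switches.append(SwitchEvent(
            track_id=track.track_id,
            frame=int(track.frames[start]),
            pre_dominant="pole1" if dominant > 0 else "pole2",
            post_dominant="pole1" if sign > 0 else "pole2",
            persistence=int(length),
        ))
        dominant = sign
    return switches


def classify_events(
    events: list[DirectionalChangeEvent],
    switches: list[SwitchEvent],
    window: int = 2,
    fluorescence_available: bool = True,
) -> list[DirectionalChangeEvent]:
    """Label directional changes as confirmed reversals or stick-slips.

    Changes and switches from the same track are matched one-to-one,
    closest frame distance first, within ``±window`` frames; each switch
    confirms at most one change.  Unmatched changes are stick-slip motions
    when fluorescence data exist, otherwise they stay unconfirmed
    (pure-motion mode).  Classification is assigned exactly once.
    """
    pairs = []
    for ei, ev in enumerate(events):
        for si, sw in enumerate(switches):
            d = abs(ev.frame - sw.frame)
            if d <= window:
                pairs.append((d, ev.frame, sw.frame, ei, si))
    pairs.sort()
    used_e: set[int] = set()
    used_s: set[int] = set()
    for d, _, _, ei, si in pairs:
        if ei in used_e or si in used_s:
            continue
        used_e.add(ei)
        used_s.add(si)
        events[ei].classification = "confirmed"
        events[ei].matched_switch_frame = switches[si].frame
    for ei, ev in enumerate(events):
        if ei not in used_e:
            ev.classification = "stick_slip" if fluorescence_available else "unconfirmed"
            ev.matched_switch_frame = None
    return events


def reversal_statistics(
    track: Track,
    events: list[DirectionalChangeEvent],
    mode: str = "confirmed",
) -> dict:
    """Per-cell reversal frequency and mean inter-reversal time.

    ``mode='confirmed'`` counts only fluorescence-confirmed reversals
    (stick-slip filter on); ``mode='all'`` counts every directional change
    (filter off).  Frequency is reported in reversals per 10 minutes;
    the mean time between consecutive reversals is in minutes and defined
    only for tracks with at least two counted events.
    """
    if track.duration <= 0:
        raise ValueError("track has zero duration; filter tracks first")
    if mode == "confirmed":
        counted = [e for e in events if e.classification == "confirmed"]
    elif mode == "all":
        counted = list(events)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    duration_min = track.duration / 60.0
    frames = sorted(e.frame for e in counted)
    mean_gap = None
    if len(frames) >= 2:
        gaps = np.diff(frames) * track.frame_interval / 60.0
        mean_gap = float(gaps.mean())
    return {
        "track_id": track.track_id,
        "n_events": len(counted),
        "duration_min": duration_min,
        "frequency_per_10min": len(counted) / duration_min * 10.0,
        "mean_inter_reversal_min": mean_gap,
    }
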