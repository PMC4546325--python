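"""Frame-to-frame linking of detections into per-cell tracks.

Linking follows the nearest-object rule: all distances between detections
in consecutive frames are computed and the closest pairs are linked
greedily, rejecting pairs farther apart than a gate.  Ambiguities —
detections contested at exactly equal distance, or two cells approaching
within the gate of each other (crossing) — are conservatively discarded:
the affected tracks terminate and the counts are logged.  This automated
QC replaces interactive verification of trajectories, so that the whole
analysis is reproducible without a human in the loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from myxotrack.imaging import CellDetection

__all__ = ["Track", "LinkResult", "link_frames", "build_tracks",
           "filter_tracks", "assign_pole_identity"]

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """Per-cell time series with persistent pole labels.

    Frames are strictly increasing and gap-free (a missed detection
    terminates a track; there is no gap closing).  ``pole1``/``pole2``
    keep the same physical cell end across frames by construction.
    """

    track_id: int
    frames: np.ndarray            # frame indices
    x: np.ndarray                 # centroid, µm
    y: np.ndarray
    pole1: np.ndarray             # (T, 2) µm
    pole2: np.ndarray
    pole1_intensity: np.ndarray   # background-subtracted a.u.
    pole2_intensity: np.ndarray
    length: np.ndarray            # µm
    area: np.ndarray              # µm²
    orientation: np.ndarray       # degrees
    frame_interval: float         # s
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be consecutive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Track duration in seconds: (n_frames - 1) * frame_interval."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def centroids(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def step_lengths(self) -> np.ndarray:
        """Frame-to-frame displacement magnitudes, µm (length T-1)."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    @property
    def speed(self) -> np.ndarray:
        """Instantaneous speed in µm/min; NaN at the first frame."""
        out = np.full(self.n_frames, np.nan)
        out[1:] = self.step_lengths / self.frame_interval * 60.0
        return out

    @property
    def cumulated_distance(self) -> np.ndarray:
        """Cumulated traveled distance in µm (0 at the first frame)."""
        out = np.zeros(self.n_frames)
        out[1:] = np.cumsum(self.step_lengths)
        return out

    @property
    def mean_speed(self) -> float:
        """Mean speed over the whole track, µm/min."""
        if self.n_frames < 2:
            return 0.0
        return float(self.step_lengths.mean() / self.frame_interval * 60.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "track_id": self.track_id,
            "frame": self.frames,
            "time_s": self.frames * self.frame_interval,
            "x_um": self.x,
            "y_um": self.y,
            "pole1_x_um": self.pole1[:, 0],
            "pole1_y_um": self.pole1[:, 1],
            "pole2_x_um": self.pole2[:, 0],
            "pole2_y_um": self.pole2[:, 1],
            "pole1_intensity_au": self.pole1_intensity,
            "pole2_intensity_au": self.pole2_intensity,
            "length_um": self.length,
            "area_um2": self.area,
            "orientation_deg": self.orientation,
            "speed_um_per_min": self.speed,
            "cumulated_distance_um": self.cumulated_distance,
        })


@dataclass
class LinkResult:
    pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]


def link_frames(
    points_a: np.ndarray,
    points_b: np.ndarray,
    max_disp: float,
) -> LinkResult:
    """Greedy mutual-nearest assignment between two consecutive frames.

    Candidate pairs closer than ``max_disp`` are accepted in ascending
    distance order, each detection matching at most once.  If a detection
    is claimed by two candidate pairs at exactly equal distance, all the
    tied links are dropped and the contested detections stay unmatched
    (ambiguity is conservatively discarded).  Deterministic and symmetric
    in the roles of the two frames.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        return LinkResult([], list(range(len(a))), list(range(len(b))))
    dist = cdist(a, b)
    ii, jj = np.nonzero(dist <= max_disp)
    order = np.lexsort((jj, ii, dist[ii, jj]))
    cand = [(dist[ii[k], jj[k]], int(ii[k]), int(jj[k])) for k in order]

    matched_a: set[int] = set()
    matched_b: set[int] = set()
    banned_a: set[int] = set()
    banned_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    k = 0
    while k < len(cand):
        # process one exact-distance group at a time
        d0 = cand[k][0]
        group = []
        while k < len(cand) and cand[k][0] == d0:
            _, i, j = cand[k]
            if (i not in matched_a and i not in banned_a
                    and j not in matched_b and j not in banned_b):
                group.append((i, j))
            k += 1
        count_a: dict[int, int] = {}
        count_b: dict[int, int] = {}
        for i, j in group:
            count_a[i] = count_a.get(i, 0) + 1
            count_b[j] = count_b.get(j, 0) + 1
        for i, j in group:
            if count_a[i] > 1 or count_b[j] > 1:
                banned_a.add(i)
                banned_b.add(j)
        for i, j in group:
            if (count_a[i] == 1 and count_b[j] == 1
                    and i not in banned_a and j not in banned_b):
                pairs.append((i, j))
                matched_a.add(i)
                matched_b.add(j)
    pairs.sort()
    unmatched_a = [i for i in range(len(a)) if i not in matched_a]
    unmatched_b = [j for j in range(len(b)) if j not in matched_b]
    return LinkResult(pairs, unmatched_a, unmatched_b)


class _TrackBuilder:
    __slots__ = ("track_id", "dets", "pole_order", "qc_flags")

    def __init__(self, track_id: int, det: CellDetection):
        self.track_id = track_id
        self.dets: list[CellDetection] = [det]
        # pole_order[t] is True when detection poles (a, b) map to (1, 2)
        self.pole_order: list[bool] = [True]
        self.qc_flags: list[str] = []

    def labeled_poles(self) -> tuple[np.ndarray, np.ndarray]:
        det = self.dets[-1]
        if self.pole_order[-1]:
            return det.pole_a, det.pole_b
        return det.pole_b, det.pole_a

    def extend(self, det: CellDetection) -> None:
        p1, p2 = self.labeled_poles()
        cost_keep = (np.hypot(*(det.pole_a - p1)) + np.hypot(*(det.pole_b - p2)))
        cost_swap = (np.hypot(*(det.pole_b - p1)) + np.hypot(*(det.pole_a - p2)))
        if det.degenerate_axis:
            self.qc_flags.append(f"degenerate_poles_frame_{det.frame}")
        # labeled_poles() is already in label order, so the comparison
        # directly decides whether (pole_a, pole_b) map to (1, 2);
        # a tie keeps the (a, b) -> (1, 2) orientation
        self.pole_order.append(cost_keep <= cost_swap)
        self.dets.append(det)

    def build(self, frame_interval: float) -> Track:
        n = len(self.dets)
        p1 = np.empty((n, 2))
        p2 = np.empty((n, 2))
        i1 = np.empty(n)
        i2 = np.empty(n)
        for t, (det, order) in enumerate(zip(self.dets, self.pole_order)):
            if order:
                p1[t], p2[t] = det.pole_a, det.pole_b
                i1[t], i2[t] = det.pole_a_intensity, det.pole_b_intensity
            else:
                p1[t], p2[t] = det.pole_b, det.pole_a
                i1[t], i2[t] = det.pole_b_intensity, det.pole_a_intensity
        return Track(
            track_id=self.track_id,
            frames=np.array([d.frame for d in self.dets]),
            x=np.array([d.centroid[0] for d in self.dets]),
            y=np.array([d.centroid[1] for d in self.dets]),
            pole1=p1, pole2=p2,
            pole1_intensity=i1, pole2_intensity=i2,
            length=np.array([d.length for d in self.dets]),
            area=np.array([d.area for d in self.dets]),
            orientation=np.array([d.orientation for d in self.dets]),
            frame_interval=frame_interval,
            qc_flags=self.qc_flags,
        )


def build_tracks(
    detections_per_frame: list[list[CellDetection]],
    max_disp: float,
    frame_interval: float,
) -> tuple[list[Track], dict]:
    """Chain frame-to-frame links into tracks with automated QC.

    Crossing cells (two detections, or a track end and two candidates,
    within ``max_disp`` of each other) terminate the involved tracks at the
    conflict frame rather than risking an identity swap.  Pole labels are
    assigned persistently while extending: at each new frame the detection
    poles take the labels that minimize the summed distance to the
    previously labeled poles.

    Returns the track list (stable ids in creation order) and a QC log of
    per-stage counts.
    """
    qc = {"n_frames": len(detections_per_frame), "detections": 0,
          "conflict_terminations": 0, "gate_terminations": 0,
          "tracks_started": 0}
    tracks: list[Track] = []
    active: list[_TrackBuilder] = []
    next_id = 0

    def start(det: CellDetection) -> None:
        nonlocal next_id
        active.append(_TrackBuilder(next_id, det))
        qc["tracks_started"] += 1
        next_id += 1

    if not detections_per_frame:
        return [], qc
    qc["detections"] += len(detections_per_frame[0])
    for det in detections_per_frame[0]:
        start(det)

    for t in range(1, len(detections_per_frame)):
        dets = detections_per_frame[t]
        qc["detections"] += len(dets)
        if not active:
            for det in dets:
                start(det)
            continue
        ends = np.array([b.dets[-1].centroid for b in active])
        if dets:
            pts = np.array([d.centroid for d in dets])
            dist = cdist(ends, pts)
            within = dist <= max_disp
            amb_end = within.sum(axis=1) > 1
            amb_det = within.sum(axis=0) > 1
            # a track end competing for a contested detection is also dropped
            amb_end |= (within & amb_det[None, :]).any(axis=1)
        else:
            amb_end = np.zeros(len(active), dtype=bool)
            amb_det = np.zeros(0, dtype=bool)

        survivors: list[_TrackBuilder] = []
        for b, amb in zip(active, amb_end):
            if amb:
                b.qc_flags.append(f"conflict_frame_{t}")
                qc["conflict_terminations"] += 1
                tracks.append(b.build(frame_interval))
            else:
                survivors.append(b)

        free_idx = [j for j in range(len(dets)) if not (len(amb_det) and amb_det[j])]
        end_pts = np.array([b.dets[-1].centroid for b in survivors]).reshape(-1, 2)
        det_pts = np.array([dets[j].centroid for j in free_idx]).reshape(-1, 2)
        res = link_frames(end_pts, det_pts, max_disp)
        extended = set()
        for i, j in res.pairs:
            survivors[i].extend(dets[free_idx[j]])
            extended.add(i)
        still_active = []
        for i, b in enumerate(survivors):
            if i in extended:
                still_active.append(b)
            else:
                qc["gate_terminations"] += 1
                tracks.append(b.build(frame_interval))
        active = still_active
        # unmatched detections (including contested ones) seed new tracks
        matched_dets = {free_idx[j] for _, j in res.pairs}
        for j in range(len(dets)):
            if j not in matched_dets:
                start(dets[j])

    for b in active:
        tracks.append(b.build(frame_interval))
    tracks.sort(key=lambda tr: tr.track_id)
    qc["tracks_built"] = len(tracks)
    return tracks, qc


def filter_tracks(tracks: list[Track], min_duration: float = 600.0) -> list[Track]:
    """Keep tracks observed for at least ``min_duration`` seconds (inclusive).

    The default of 600 s keeps only cells followed for 10 minutes or more,
    which stabilizes per-cell reversal frequencies.  The number of removed
    tracks is logged.
    """
    kept = [t for t in tracks if t.duration >= min_duration]
    removed = len(tracks) - len(kept)
    if removed:
        logger.info("duration filter removed %d of %d tracks", removed, len(tracks))
    return kept


def assign_pole_identity(track: Track) -> Track:
    """Re-derive persistent pole labels along a track, in place.

    Frame-0 labels are kept as given; at every later frame the two poles
    take the labels that minimize the summed distance to the previous
    labeled poles.  Labels never swap while the cell moves less than half
    a cell length per frame; a 180-degree body rotation within one frame
    can defeat the rule and is flagged by geometry QC upstream.
    """
    for t in range(1, track.n_frames):
        cost_keep = (np.hypot(*(track.pole1[t] - track.pole1[t - 1]))
                     + np.hypot(*(track.pole2[t] - track.pole2[t - 1])))
        cost_swap = (np.hypot(*(track.pole2[t] - track.pole1[t - 1]))
                     + np.hypot(*(track.pole1[t] - track.pole2[t - 1])))
        if cost_swap < cost_keep:
            track.pole1[t], track.pole2[t] = track.pole2[t].copy(), track.pole1[t].copy()
            track.pole1_intensity[t], track.pole2_intensity[t] = (
                track.pole2_intensity[t], track.pole1_intensity[t])
    return track
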