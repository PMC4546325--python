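"""End-to-end orchestration: stack -> tracks -> events -> group statistics.

``run_pipeline`` chains stabilization, segmentation, tracking, reversal
calling, classification and summary statistics, writing CSV/JSON outputs
with units in the column names and echoing the configuration alongside
them for provenance.  ``validate`` scores called events against a
simulation's ground truth at a stated frame tolerance — the quantitative
replacement for interactive verification of trajectories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from myxotrack.imaging import FrameStack, detect_stack, stabilize_stack
from myxotrack.reversals import (
    call_directional_changes,
    classify_events,
    detect_fluor_switches,
    reversal_statistics,
)
from myxotrack.simulate import GroundTruth, SimulationConfig, render_movie, simulate_trajectories
from myxotrack.stats import speed_summary, summarize_group
from myxotrack.tracking import Track, build_tracks, filter_tracks

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ValidationReport",
    "analyze_stack",
    "run_pipeline",
    "validate",
    "match_tracks_to_truth",
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis chain (units in names)."""

    # stabilization
    stabilize: bool = True
    upsample_factor: int = 20
    # segmentation
    segmentation_method: str = "otsu"     # "otsu" or "fixed"
    fixed_threshold: float | None = None
    min_area_um2: float = 1.0
    pole_radius_px: float = 3.0
    annulus_px: tuple[float, float] = (5.0, 7.0)
    # tracking
    max_disp_um: float = 1.7              # 4 x (speed_mean x frame_interval)
    min_duration_s: float = 600.0         # keep cells tracked >= 10 min
    # reversal calling
    angle_threshold_deg: float = 90.0     # strict: 90 exactly is not a reversal
    min_step_um: float = 0.1
    refractory_frames: int = 2
    correlation_window_frames: int = 2
    smoothing_frames: int = 3
    min_persistence_frames: int = 2
    mode: str = "confirmed"               # "confirmed" or "all"
    # statistics
    n_rule_threshold: int = 40
    welch: bool = False

    def validate(self) -> None:
        if self.max_disp_um <= 0 or self.min_area_um2 < 0:
            raise ValueError("max_disp_um must be > 0 and min_area_um2 >= 0")
        if self.min_duration_s < 0 or self.min_step_um < 0:
            raise ValueError("min_duration_s and min_step_um must be >= 0")
        if not 0 < self.angle_threshold_deg <= 180:
            raise ValueError("angle_threshold_deg must be in (0, 180]")
        if self.refractory_frames < 0 or self.correlation_window_frames < 0:
            raise ValueError("frame windows must be >= 0")
        if self.mode not in ("confirmed", "all"):
            raise ValueError("mode must be 'confirmed' or 'all'")
        if self.segmentation_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed segmentation requires fixed_threshold")

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["annulus_px"] = list(doc["annulus_px"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "annulus_px" in doc:
            doc["annulus_px"] = tuple(doc["annulus_px"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    tracks: list[Track]
    tracks_df: pd.DataFrame
    events_df: pd.DataFrame
    per_track: pd.DataFrame       # per-cell reversal statistics
    group: dict                   # group summary (percentiles, speed)
    log: dict
    truth: GroundTruth | None = None
    offsets_px: np.ndarray | None = None


_EVENT_COLUMNS = [
    "track_id", "frame", "time_s", "angle_deg",
    "step_before_um", "step_after_um", "classification",
    "matched_switch_frame",
]


def analyze_stack(
    stack: FrameStack,
    config: PipelineConfig | None = None,
) -> tuple[list[Track], pd.DataFrame, dict, np.ndarray | None]:
    """Stack -> duration-filtered tracks + classified event table + QC log."""
    config = config or PipelineConfig()
    config.validate()
    log: dict = {}
    offsets = None
    if config.stabilize and stack.n_frames >= 2:
        stack, offsets = stabilize_stack(stack, upsample_factor=config.upsample_factor)
        log["max_stabilization_offset_px"] = float(np.abs(offsets).max())
    detections = detect_stack(
        stack,
        min_area=config.min_area_um2,
        method=config.segmentation_method,
        threshold=config.fixed_threshold,
        pole_radius_px=config.pole_radius_px,
        annulus_px=config.annulus_px,
    )
    tracks, qc = build_tracks(detections, config.max_disp_um, stack.frame_interval)
    log.update(qc)
    kept = filter_tracks(tracks, min_duration=config.min_duration_s)
    log["tracks_dropped_by_duration"] = len(tracks) - len(kept)
    log["tracks_kept"] = len(kept)

    has_fluor = "fluorescence" in stack.channels
    events_df = build_event_table(kept, config, fluorescence_available=has_fluor)
    log["events_total"] = int(len(events_df))
    for cls in ("confirmed", "stick_slip", "unconfirmed"):
        log[f"events_{cls}"] = int((events_df["classification"] == cls).sum())
    return kept, events_df, log, offsets


def build_event_table(
    tracks: list[Track],
    config: PipelineConfig | None = None,
    fluorescence_available: bool = True,
) -> pd.DataFrame:
    """Call, confirm and tabulate directional-change events for tracks."""
    config = config or PipelineConfig()
    rows = []
    for track in tracks:
        events = call_directional_changes(
            track,
            angle_threshold=config.angle_threshold_deg,
            min_step=config.min_step_um,
            refractory=config.refractory_frames,
        )
        if fluorescence_available:
            switches = detect_fluor_switches(
                track,
                smoothing=config.smoothing_frames,
                min_persistence=config.min_persistence_frames,
            )
        else:
            switches = []
        events = classify_events(
            events, switches,
            window=config.correlation_window_frames,
            fluorescence_available=fluorescence_available,
        )
        for ev in events:
            rows.append({
                "track_id": ev.track_id,
                "frame": ev.frame,
                "time_s": ev.frame * track.frame_interval,
                "angle_deg": ev.turn_angle,
                "step_before_um": ev.step_before,
                "step_after_um": ev.step_after,
                "classification": ev.classification,
                "matched_switch_frame": ev.matched_switch_frame,
            })
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)


def _per_track_table(tracks: list[Track], events_df: pd.DataFrame,
                     mode: str) -> pd.DataFrame:
    from myxotrack.reversals import DirectionalChangeEvent

    rows = []
    for track in tracks:
        sub = events_df[events_df["track_id"] == track.track_id]
        events = [
            DirectionalChangeEvent(
                track_id=int(r.track_id), frame=int(r.frame),
                turn_angle=float(r.angle_deg),
                step_before=float(r.step_before_um),
                step_after=float(r.step_after_um),
                classification=str(r.classification),
            )
            for r in sub.itertuples()
        ]
        stats = reversal_statistics(track, events, mode=mode)
        stats["mean_speed_um_per_min"] = track.mean_speed
        rows.append(stats)
    return pd.DataFrame(rows, columns=[
        "track_id", "n_events", "duration_min", "frequency_per_10min",
        "mean_inter_reversal_min", "mean_speed_um_per_min",
    ])


def run_pipeline(
    config: PipelineConfig | None = None,
    stack: FrameStack | None = None,
    sim_config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    group_label: str = "group",
) -> PipelineResult:
    """Run the full analysis on a stack or on a fresh simulation.

    Exactly one of ``stack`` / ``sim_config`` must be given.  Outputs
    (when ``out_dir`` is set): ``tracks.csv``, ``events.csv``,
    ``per_track.csv``, ``group_stats.json``, ``qc_log.json``,
    ``config.yaml`` and, for simulations, ``ground_truth.json``.
    Deterministic for fixed inputs and seed.
    """
    config = config or PipelineConfig()
    config.validate()
    if (stack is None) == (sim_config is None):
        raise ValueError("provide exactly one of stack or sim_config")
    truth = None
    if sim_config is not None:
        truth = simulate_trajectories(sim_config)
        stack = render_movie(truth, sim_config)

    tracks, events_df, log, offsets = analyze_stack(stack, config)
    tracks_df = (
        pd.concat([t.to_dataframe() for t in tracks], ignore_index=True)
        if tracks else pd.DataFrame()
    )
    per_track = _per_track_table(tracks, events_df, config.mode)

    group: dict = {"label": group_label, "n_tracks": len(tracks),
                   "frequency_unit": "reversals per 10 min",
                   "mode": config.mode}
    if len(per_track):
        gs = summarize_group(per_track["frequency_per_10min"].to_numpy(), group_label)
        group.update({
            "mean_frequency_per_10min": gs.mean,
            "percentiles": {f"p{p}": v for p, v in gs.percentiles.items()},
        })
    group["speed"] = speed_summary(tracks)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tracks_df.to_csv(out / "tracks.csv", index=False)
        events_df.to_csv(out / "events.csv", index=False)
        per_track.to_csv(out / "per_track.csv", index=False)
        (out / "group_stats.json").write_text(
            json.dumps(group, indent=2, sort_keys=True), encoding="utf-8")
        (out / "qc_log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True), encoding="utf-8")
        config.to_yaml(out / "config.yaml")
        if truth is not None:
            from myxotrack.simulate import write_ground_truth
            write_ground_truth(truth, out / "ground_truth.json")

    return PipelineResult(
        tracks=tracks, tracks_df=tracks_df, events_df=events_df,
        per_track=per_track, group=group, log=log,
        truth=truth, offsets_px=offsets,
    )


@dataclass
class ValidationReport:
    """Event-level precision/recall of the caller against ground truth."""

    precision: float
    recall: float
    n_called: int
    n_true: int
    n_matched: int
    frame_tolerance: int
    tracking_identity_accuracy: float
    n_tracks_matched: int
    n_tracks_unmatched: int
    zero_calls: bool
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def match_tracks_to_truth(
    tracks: list[Track],
    truth: GroundTruth,
    max_mean_dist_um: float = 3.0,
) -> dict[int, int]:
    """Map track_id -> simulated cell_id by mean positional distance.

    Each track is assigned to the cell whose true trajectory is closest on
    average over the track's frames; assignments farther than
    ``max_mean_dist_um`` are rejected.  One cell may collect several track
    fragments (a track broken by QC), but each track maps to one cell.
    """
    mapping: dict[int, int] = {}
    for track in tracks:
        fr = track.frames
        best, best_d = None, np.inf
        for cell in truth.cells:
            if fr[-1] >= len(cell.x):
                continue
            d = float(np.hypot(cell.x[fr] - track.x, cell.y[fr] - track.y).mean())
            if d < best_d:
                best, best_d = cell.cell_id, d
        if best is not None and best_d <= max_mean_dist_um:
            mapping[track.track_id] = best
    return mapping


def validate(
    tracks: list[Track],
    events_df: pd.DataFrame,
    truth: GroundTruth,
    frame_tolerance: int = 1,
    max_mean_dist_um: float = 3.0,
    config: PipelineConfig | None = None,
) -> ValidationReport:
    """Score confirmed reversal calls against the simulation's truth.

    Called events (classification ``confirmed``) are matched one-to-one,
    smallest frame distance first, to the true reversal frames of the cell
    their track maps to, within ``±frame_tolerance`` frames.  Precision is
    matched/called and recall is matched/true, where the truth denominator
    counts the reversals that are observable, i.e. that fall strictly
    inside the frame span of a matched track (a vertex needs both
    neighboring frames).  With zero calls precision is reported as 1.0 and
    flagged.  Tracking identity accuracy is the fraction of matched tracks
    whose assigned cell is the nearest true cell at every frame.
    """
    mapping = match_tracks_to_truth(tracks, truth, max_mean_dist_um)
    dt = truth.frame_interval
    true_by_cell: dict[int, list[int]] = {}
    for cid, t_s in truth.true_reversals:
        true_by_cell.setdefault(cid, []).append(int(round(t_s / dt)))

    n_called = 0
    n_matched = 0
    n_true_observable = 0
    identity_ok = 0
    cells_by_id = {c.cell_id: c for c in truth.cells}

    for track in tracks:
        cid = mapping.get(track.track_id)
        sub = events_df[(events_df["track_id"] == track.track_id)
                        & (events_df["classification"] == "confirmed")]
        called = sorted(int(f) for f in sub["frame"])
        n_called += len(called)
        if cid is None:
            continue
        cell = cells_by_id[cid]
        lo, hi = int(track.frames[0]), int(track.frames[-1])
        true_frames = sorted(f for f in true_by_cell.get(cid, [])
                             if lo + 1 <= f <= hi - 1)
        n_true_observable += len(true_frames)
        # one-to-one greedy matching, closest frame distance first
        pairs = sorted(
            (abs(cf - tf), cf, tf, i, j)
            for i, cf in enumerate(called)
            for j, tf in enumerate(true_frames)
            if abs(cf - tf) <= frame_tolerance
        )
        used_c: set[int] = set()
        used_t: set[int] = set()
        for _, _, _, i, j in pairs:
            if i in used_c or j in used_t:
                continue
            used_c.add(i)
            used_t.add(j)
            n_matched += 1
        # identity: assigned cell must be the nearest cell at every frame
        ok = True
        fr = track.frames
        d_own = np.hypot(cell.x[fr] - track.x, cell.y[fr] - track.y)
        for other in truth.cells:
            if other.cell_id == cid:
                continue
            d_other = np.hypot(other.x[fr] - track.x, other.y[fr] - track.y)
            if np.any(d_other < d_own):
                ok = False
                break
        identity_ok += int(ok)

    n_tracks_matched = len(mapping)
    zero_calls = n_called == 0
    precision = 1.0 if zero_calls else n_matched / n_called
    recall = 0.0 if n_true_observable == 0 else n_matched / n_true_observable
    return ValidationReport(
        precision=precision,
        recall=recall,
        n_called=n_called,
        n_true=n_true_observable,
        n_matched=n_matched,
        frame_tolerance=frame_tolerance,
        tracking_identity_accuracy=(
            identity_ok / n_tracks_matched if n_tracks_matched else 1.0),
        n_tracks_matched=n_tracks_matched,
        n_tracks_unmatched=len(tracks) - n_tracks_matched,
        zero_calls=zero_calls,
        config_echo=asdict(config) if config is not None else {},
    )
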