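"""Ground-truthed synthetic movies of run-and-reverse gliding cells.

Emulates single-cell Tfp-dependent motility assays in a microfluidic
chamber imaged every 15 s in two channels: transmitted light (dark rods on
a bright background) and a polar fluorescent marker (two spots whose
intensities exchange between the poles when the cell reverses).  Cells move
along their long axis at a per-cell constant speed, reverse direction as a
Poisson process, and additionally show "stick-slip" motions: short
back-and-forth displacements completed within two frames that are *not*
accompanied by a fluorescence exchange.  The generator records every true
event so that downstream reversal calling can be validated at event level.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SimulationConfig",
    "CellTruth",
    "GroundTruth",
    "simulate_trajectories",
    "render_movie",
    "write_ground_truth",
    "read_ground_truth",
    "tracks_from_truth",
]

# A physical reversal is scheduled no closer than this many frames to the
# previous event so that distinct events remain resolvable at the movie's
# time resolution (two events inside one refractory window are one vertex).
_BOUNCE_WAIT_FRAMES = 3


@dataclass
class SimulationConfig:
    """Parameters of a synthetic motility movie.

    Units: times in seconds, lengths in micrometres, speeds in µm/min,
    rates in events per minute per cell, field geometry in pixels.
    """

    n_cells: int = 20
    duration: float = 1800.0           # total movie length, s
    frame_interval: float = 15.0       # s between frames
    pixel_size: float = 0.1            # µm per pixel
    field_size: tuple[int, int] | None = None   # (height, width) px; None -> auto grid
    speed_mean: float = 1.7            # µm/min
    speed_sd: float = 0.8              # µm/min
    speed_min: float = 0.5             # truncation floor for motile cells, µm/min
    reversal_rate: float = 0.1         # reversals / min / cell
    stickslip_rate: float = 0.1        # stick-slips / min / cell
    stickslip_excursion: float = 0.75  # µm, back-and-forth amplitude
    cell_length_mean: float = 5.0      # µm
    cell_length_sd: float = 0.3        # µm
    cell_width: float = 0.7            # µm
    fluor_relocalization_frames: int = 1
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px per frame
    noise_sd: float = 20.0             # additive Gaussian noise, intensity units
    rng_seed: int = 0
    # motion details
    angular_jitter_deg: float = 5.0    # per-frame heading jitter, degrees
    confine: bool = True               # keep each cell inside its own tile
    tile_um: float = 22.0              # tile edge when auto-placing cells
    confine_margin_um: float = 6.0     # reversal triggered this far from tile edge
    min_event_separation_s: float = 60.0
    field_pad_px: int = 30
    # rendering
    bit_depth: int = 16
    bg_transmitted: float = 1000.0     # bright background level
    cell_depth: float = 600.0          # transmitted-channel contrast of the rod
    bg_fluor: float = 100.0
    fluor_amp: float = 600.0           # spot amplitude for a pole at level 1.0
    fluor_spot_sigma_um: float = 0.25
    leading_level: float = 1.0         # marker level at the leading pole
    lagging_level: float = 0.3
    # static background mottle in the transmitted channel (glass texture /
    # uneven illumination); it drifts with the stage and is what frame
    # registration locks onto, as in real movies
    bg_texture_sd: float = 40.0
    bg_texture_scale_px: float = 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = {
            "duration": self.duration,
            "frame_interval": self.frame_interval,
            "pixel_size": self.pixel_size,
            "speed_mean": self.speed_mean,
            "speed_sd": self.speed_sd,
            "speed_min": self.speed_min,
            "reversal_rate": self.reversal_rate,
            "stickslip_rate": self.stickslip_rate,
            "stickslip_excursion": self.stickslip_excursion,
            "cell_length_mean": self.cell_length_mean,
            "cell_width": self.cell_width,
            "noise_sd": self.noise_sd,
        }
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.frame_interval <= 0 or self.pixel_size <= 0 or self.duration <= 0:
            raise ValueError("frame_interval, pixel_size and duration must be > 0")
        for name in ("reversal_rate", "stickslip_rate", "noise_sd", "speed_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.speed_min <= 0:
            raise ValueError("speed_min must be > 0 (speeds are truncated positive)")
        if self.fluor_relocalization_frames < 1:
            raise ValueError("fluor_relocalization_frames must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def resolved_field_size(self) -> tuple[int, int]:
        """(height, width) in px, laying cells out on a tile grid if unset."""
        if self.field_size is not None:
            return tuple(int(v) for v in self.field_size)
        n = max(self.n_cells, 1)
        cols = int(math.ceil(math.sqrt(n)))
        rows = int(math.ceil(n / cols))
        tile_px = int(round(self.tile_um / self.pixel_size))
        h = rows * tile_px + 2 * self.field_pad_px
        w = cols * tile_px + 2 * self.field_pad_px
        return (h, w)


@dataclass
class CellTruth:
    """True state of one simulated cell at every frame.

    ``pole_a``/``pole_b`` are the two physical cell ends with fixed
    identity over time; their fluorescence levels exchange at reversals.
    """

    cell_id: int
    speed: float                      # µm/min, constant for the cell
    length: float                     # µm
    x: np.ndarray                     # centroid, µm
    y: np.ndarray
    heading_deg: np.ndarray           # direction of motion, degrees
    pole_a: np.ndarray                # (T, 2) µm
    pole_b: np.ndarray
    fluor_a: np.ndarray               # marker level at pole A, arbitrary units
    fluor_b: np.ndarray
    in_field: np.ndarray = field(default=None)  # set by the renderer

    def __post_init__(self) -> None:
        if self.in_field is None:
            self.in_field = np.ones(len(self.x), dtype=bool)


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    true_reversals: list[tuple[int, float]]    # (cell_id, time s)
    true_stickslips: list[tuple[int, float]]
    frame_interval: float
    pixel_size: float
    duration: float

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _draw_speeds(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cell speeds from a normal truncated below at ``speed_min``."""
    if cfg.speed_sd == 0:
        return np.full(cfg.n_cells, float(max(cfg.speed_mean, cfg.speed_min)))
    a = (cfg.speed_min - cfg.speed_mean) / cfg.speed_sd
    return sps.truncnorm.rvs(
        a, np.inf, loc=cfg.speed_mean, scale=cfg.speed_sd,
        size=cfg.n_cells, random_state=rng,
    )


def _schedule_events(
    cfg: SimulationConfig, rng: np.random.Generator, n_steps: int
) -> list[tuple[int, str]]:
    """Poisson event times for one cell, quantized to movie steps.

    Counts follow Poisson(rate x duration); times are uniform over the
    steps at which the resulting trajectory vertex is observable.  Events
    closer than the minimum separation are pushed later (count-preserving)
    and dropped only if pushed off the end of the movie.
    """
    dt_min = cfg.frame_interval / 60.0
    sep = max(1, int(round(cfg.min_event_separation_s / cfg.frame_interval)))
    # events are placed so their full signature fits inside the movie: the
    # vertex needs both neighbours and a fluorescence exchange needs a few
    # frames to persist, so the last allowed step is n_steps - 4.  Counts
    # stay Poisson(rate x duration); only the placement window shrinks.
    out: list[tuple[int, str]] = []
    for kind, rate, last_ok in (
        ("reversal", cfg.reversal_rate, n_steps - 4),
        ("stickslip", cfg.stickslip_rate, n_steps - 4),
    ):
        if rate <= 0 or last_ok < 1:
            continue
        n = rng.poisson(rate * dt_min * n_steps)
        steps = rng.integers(1, last_ok + 1, size=n)
        out.extend((int(s), kind) for s in steps)
    out.sort(key=lambda e: (e[0], e[1]))
    spaced: list[tuple[int, str]] = []
    prev_end = -10 * sep
    for step, kind in out:
        step = max(step, prev_end + sep)
        if step > n_steps - 4:
            continue  # pushed off the end; negligible edge loss
        spaced.append((step, kind))
        prev_end = step + (1 if kind == "stickslip" else 0)
    return spaced


# last step at which any event (incl. a confinement reversal) may occur,
# relative to n_steps; see _schedule_events
_LAST_EVENT_OFFSET = 4


def simulate_trajectories(config: SimulationConfig) -> GroundTruth:
    """Simulate run-and-reverse trajectories with known event times.

    Deterministic for a fixed ``config.rng_seed``.  Each cell moves along
    its body axis at constant speed with small per-frame heading jitter;
    reversals flip the heading by 180 degrees (plus jitter) and exchange
    the pole fluorescence levels within ``fluor_relocalization_frames``;
    stick-slips displace the cell backward and forward by
    ``stickslip_excursion`` within two frames with no fluorescence change.
    When ``confine`` is set, each cell is kept inside its own tile by
    triggering a (recorded) reversal near the tile edge, which keeps the
    scene well separated for the whole movie.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval
    n_frames = config.n_frames
    n_steps = n_frames - 1
    h_px, w_px = config.resolved_field_size()
    field_um = (h_px * config.pixel_size, w_px * config.pixel_size)

    speeds = _draw_speeds(config, rng)
    lengths = np.clip(
        rng.normal(config.cell_length_mean, config.cell_length_sd, config.n_cells),
        0.5 * config.cell_length_mean, 1.5 * config.cell_length_mean,
    )

    # cell placement: tile grid (confined) or uniform with margin
    n = max(config.n_cells, 1)
    cols = int(math.ceil(math.sqrt(n)))
    pad_um = config.field_pad_px * config.pixel_size

    cells: list[CellTruth] = []
    true_reversals: list[tuple[int, float]] = []
    true_stickslips: list[tuple[int, float]] = []
    sep = max(1, int(round(config.min_event_separation_s / config.frame_interval)))

    for cid in range(config.n_cells):
        speed = float(speeds[cid])
        length = float(lengths[cid])
        step_len = speed * dt / 60.0  # µm per frame

        if config.confine:
            r, c = divmod(cid, cols)
            cx = pad_um + (c + 0.5) * config.tile_um
            cy = pad_um + (r + 0.5) * config.tile_um
            half = config.tile_um / 2.0 - config.confine_margin_um
            box = (cx - half, cx + half, cy - half, cy + half)
            pos = np.array([
                cx + rng.uniform(-0.5, 0.5) * half,
                cy + rng.uniform(-0.5, 0.5) * half,
            ])
        else:
            box = None
            pos = np.array([
                rng.uniform(pad_um, field_um[1] - pad_um),
                rng.uniform(pad_um, field_um[0] - pad_um),
            ])

        heading = rng.uniform(0.0, 360.0)
        s_pole = 1.0  # pole A sits at +heading side initially (leading)
        fl_a, fl_b = config.leading_level, config.lagging_level
        tgt_a, tgt_b = fl_a, fl_b
        trans_left = 0

        events = _schedule_events(config, rng, n_steps)
        ev_idx = 0
        last_event_end = -10 * sep
        stickslip_phase = 0

        x = np.empty(n_frames)
        y = np.empty(n_frames)
        hdg = np.empty(n_frames)
        fa = np.empty(n_frames)
        fb = np.empty(n_frames)
        pa = np.empty((n_frames, 2))
        pb = np.empty((n_frames, 2))

        def record(t: int) -> None:
            x[t], y[t] = pos
            hdg[t] = heading % 360.0
            u = np.array([math.cos(math.radians(heading)),
                          math.sin(math.radians(heading))])
            pa[t] = pos + s_pole * u * length / 2.0
            pb[t] = pos - s_pole * u * length / 2.0
            fa[t], fb[t] = fl_a, fl_b

        record(0)
        for t in range(n_steps):
            executed = False
            # scheduled Poisson event, pushed if a recent event (e.g. a
            # confinement reversal) would make the two unresolvable
            if (
                ev_idx < len(events)
                and t >= events[ev_idx][0]
                and t >= last_event_end + sep
                and stickslip_phase == 0
            ):
                _, kind = events[ev_idx]
                if t > n_steps - _LAST_EVENT_OFFSET:
                    ev_idx += 1  # too late to be observable; dropped
                else:
                    ev_idx += 1
                    executed = True
                    if kind == "reversal":
                        heading += 180.0 + rng.normal(0.0, config.angular_jitter_deg)
                        s_pole = -s_pole
                        tgt_a, tgt_b = tgt_b, tgt_a
                        trans_left = config.fluor_relocalization_frames
                        true_reversals.append((cid, t * dt))
                        last_event_end = t
                    else:
                        stickslip_phase = 2
                        true_stickslips.append((cid, t * dt))
                        last_event_end = t + 1

            # confinement: reverse (a real, recorded reversal) near tile edge
            if (
                not executed
                and box is not None
                and stickslip_phase == 0
                and t >= last_event_end + _BOUNCE_WAIT_FRAMES
                and t <= n_steps - _LAST_EVENT_OFFSET
            ):
                u = np.array([math.cos(math.radians(heading)),
                              math.sin(math.radians(heading))])
                nxt = pos + u * step_len
                if not (box[0] <= nxt[0] <= box[1] and box[2] <= nxt[1] <= box[3]):
                    heading += 180.0 + rng.normal(0.0, config.angular_jitter_deg)
                    s_pole = -s_pole
                    tgt_a, tgt_b = tgt_b, tgt_a
                    trans_left = config.fluor_relocalization_frames
                    true_reversals.append((cid, t * dt))
                    last_event_end = t

            # displacement for step t -> t+1
            if stickslip_phase == 2:
                u = np.array([math.cos(math.radians(heading)),
                              math.sin(math.radians(heading))])
                pos = pos - u * config.stickslip_excursion
                stickslip_phase = 1
            elif stickslip_phase == 1:
                u = np.array([math.cos(math.radians(heading)),
                              math.sin(math.radians(heading))])
                pos = pos + u * config.stickslip_excursion
                stickslip_phase = 0
            else:
                heading += rng.normal(0.0, config.angular_jitter_deg)
                u = np.array([math.cos(math.radians(heading)),
                              math.sin(math.radians(heading))])
                pos = pos + u * step_len

            # fluorescence relaxation toward post-event targets
            if trans_left > 0:
                fl_a += (tgt_a - fl_a) / trans_left
                fl_b += (tgt_b - fl_b) / trans_left
                trans_left -= 1

            record(t + 1)

        cells.append(CellTruth(
            cell_id=cid, speed=speed, length=length,
            x=x, y=y, heading_deg=hdg,
            pole_a=pa, pole_b=pb, fluor_a=fa, fluor_b=fb,
        ))

    true_reversals.sort()
    true_stickslips.sort()
    return GroundTruth(
        cells=cells,
        true_reversals=true_reversals,
        true_stickslips=true_stickslips,
        frame_interval=dt,
        pixel_size=config.pixel_size,
        duration=n_steps * dt,
    )


def _draw_capsule(frame: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                  half_width_px: float, depth: float) -> None:
    """Subtract a dark capsule (segment p1-p2 dilated by half_width) in place.

    Coordinates in px, (x, y) = (col, row).  Edge softened over one pixel
    so centroids are stable at sub-pixel level.
    """
    h, w = frame.shape
    rad = half_width_px + 1.5
    x0 = max(int(math.floor(min(p1[0], p2[0]) - rad)), 0)
    x1 = min(int(math.ceil(max(p1[0], p2[0]) + rad)), w - 1)
    y0 = max(int(math.floor(min(p1[1], p2[1]) - rad)), 0)
    y1 = min(int(math.ceil(max(p1[1], p2[1]) + rad)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    d = p2 - p1
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.hypot(gx - p1[0], gy - p1[1])
    else:
        tt = ((gx - p1[0]) * d[0] + (gy - p1[1]) * d[1]) / seg_len2
        tt = np.clip(tt, 0.0, 1.0)
        dist = np.hypot(gx - (p1[0] + tt * d[0]), gy - (p1[1] + tt * d[1]))
    cover = np.clip(half_width_px + 0.5 - dist, 0.0, 1.0)
    frame[y0:y1 + 1, x0:x1 + 1] -= depth * cover


def _draw_spot(frame: np.ndarray, center: np.ndarray, sigma_px: float,
               amplitude: float) -> None:
    h, w = frame.shape
    rad = 4.0 * sigma_px
    x0 = max(int(math.floor(center[0] - rad)), 0)
    x1 = min(int(math.ceil(center[0] + rad)), w - 1)
    y0 = max(int(math.floor(center[1] - rad)), 0)
    y1 = min(int(math.ceil(center[1] + rad)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    r2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2
    frame[y0:y1 + 1, x0:x1 + 1] += amplitude * np.exp(-r2 / (2.0 * sigma_px ** 2))


def render_movie(truth: GroundTruth, config: SimulationConfig):
    """Render ground truth into a two-channel stack.

    Channel 0 (transmitted): dark capsules on a bright background.
    Channel 1 (fluorescence): Gaussian spots at the poles, amplitude
    proportional to the per-pole marker level.  Global stage drift
    ``drift_per_frame`` is applied to both channels; Gaussian read noise is
    added; intensities are clipped to the declared bit depth.  Cells whose
    body leaves the field are rendered clipped and flagged in the truth.
    Deterministic for a fixed ``config.rng_seed``.
    """
    from myxotrack.imaging import FrameStack  # local import, no cycle at load

    if truth.n_frames != config.n_frames or truth.frame_interval != config.frame_interval:
        raise ValueError("ground truth frame times do not match the config")
    h, w = config.resolved_field_size()
    n_frames = truth.n_frames
    ps = config.pixel_size
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 7]))
    vmax = float(2 ** config.bit_depth - 1)
    half_w_px = config.cell_width / 2.0 / ps
    sigma_px = config.fluor_spot_sigma_um / ps

    pixels = np.empty((n_frames, 2, h, w), dtype=np.uint16)
    drift = np.asarray(config.drift_per_frame, dtype=float)
    for cell in truth.cells:
        cell.in_field = np.ones(n_frames, dtype=bool)

    texture = None
    if config.bg_texture_sd > 0:
        from scipy import ndimage
        trng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
        white = trng.normal(0.0, 1.0, (h, w))
        texture = ndimage.gaussian_filter(white, config.bg_texture_scale_px,
                                          mode="wrap")
        texture *= config.bg_texture_sd / texture.std()

    for t in range(n_frames):
        trans = np.full((h, w), config.bg_transmitted, dtype=np.float64)
        if texture is not None:
            off = drift * t
            if off[0] == 0 and off[1] == 0:
                trans += texture
            else:
                from scipy import ndimage
                trans += ndimage.shift(texture, (off[1], off[0]), order=1,
                                       mode="grid-wrap")
        fluor = np.full((h, w), config.bg_fluor, dtype=np.float64)
        off = drift * t
        for cell in truth.cells:
            pa = cell.pole_a[t] / ps + off
            pb = cell.pole_b[t] / ps + off
            # body segment shortened so hemispherical caps end at the poles
            center = (pa + pb) / 2.0
            axis = pb - pa
            norm = np.hypot(*axis)
            if norm > 0:
                axis = axis / norm
            body_half = max(norm / 2.0 - half_w_px, 0.0)
            p1 = center - axis * body_half
            p2 = center + axis * body_half
            _draw_capsule(trans, p1, p2, half_w_px, config.cell_depth)
            _draw_spot(fluor, pa, sigma_px, config.fluor_amp * cell.fluor_a[t])
            _draw_spot(fluor, pb, sigma_px, config.fluor_amp * cell.fluor_b[t])
            margin = half_w_px + 1.0
            lo = min(pa[0], pb[0]) - margin, min(pa[1], pb[1]) - margin
            hi = max(pa[0], pb[0]) + margin, max(pa[1], pb[1]) + margin
            if lo[0] < 0 or lo[1] < 0 or hi[0] > w - 1 or hi[1] > h - 1:
                cell.in_field[t] = False
        if config.noise_sd > 0:
            trans = trans + rng.normal(0.0, config.noise_sd, size=(h, w))
            fluor = fluor + rng.normal(0.0, config.noise_sd, size=(h, w))
        pixels[t, 0] = np.clip(trans, 0.0, vmax).astype(np.uint16)
        pixels[t, 1] = np.clip(fluor, 0.0, vmax).astype(np.uint16)

    return FrameStack(
        pixels=pixels,
        pixel_size=ps,
        frame_interval=config.frame_interval,
        channels=("transmitted", "fluorescence"),
    )


# ---------------------------------------------------------------------------
# ground-truth serialization (JSON, lossless float round trip)

class GroundTruthParseError(ValueError):
    """Raised when a ground-truth file violates the format or invariants."""


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "format": "myxotrack-ground-truth",
        "version": 1,
        "frame_interval_s": truth.frame_interval,
        "pixel_size_um": truth.pixel_size,
        "duration_s": truth.duration,
        "true_reversals": [[int(c), float(t)] for c, t in truth.true_reversals],
        "true_stickslips": [[int(c), float(t)] for c, t in truth.true_stickslips],
        "cells": [
            {
                "cell_id": int(c.cell_id),
                "speed_um_per_min": float(c.speed),
                "length_um": float(c.length),
                "x_um": c.x.tolist(),
                "y_um": c.y.tolist(),
                "heading_deg": c.heading_deg.tolist(),
                "pole_a_um": c.pole_a.tolist(),
                "pole_b_um": c.pole_b.tolist(),
                "fluor_a": c.fluor_a.tolist(),
                "fluor_b": c.fluor_b.tolist(),
                "in_field": c.in_field.astype(int).tolist(),
            }
            for c in truth.cells
        ],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_ground_truth(path: str | Path) -> GroundTruth:
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GroundTruthParseError(
            f"{path}: not valid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if doc.get("format") != "myxotrack-ground-truth":
        raise GroundTruthParseError(f"{path}: missing ground-truth format marker")
    for key in ("frame_interval_s", "pixel_size_um", "duration_s", "cells"):
        if key not in doc:
            raise GroundTruthParseError(f"{path}: missing field {key!r}")
    for name in ("true_reversals", "true_stickslips"):
        for i, (cid, t) in enumerate(doc.get(name, [])):
            if t < 0:
                raise GroundTruthParseError(
                    f"{path}: {name}[{i}] has negative time {t!r} (cell {cid})"
                )
    cells = []
    for i, c in enumerate(doc["cells"]):
        try:
            cells.append(CellTruth(
                cell_id=int(c["cell_id"]),
                speed=float(c["speed_um_per_min"]),
                length=float(c["length_um"]),
                x=np.asarray(c["x_um"], dtype=float),
                y=np.asarray(c["y_um"], dtype=float),
                heading_deg=np.asarray(c["heading_deg"], dtype=float),
                pole_a=np.asarray(c["pole_a_um"], dtype=float),
                pole_b=np.asarray(c["pole_b_um"], dtype=float),
                fluor_a=np.asarray(c["fluor_a"], dtype=float),
                fluor_b=np.asarray(c["fluor_b"], dtype=float),
                in_field=np.asarray(c["in_field"], dtype=bool),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise GroundTruthParseError(f"{path}: malformed cell record {i}: {exc}") from exc
    return GroundTruth(
        cells=cells,
        true_reversals=[(int(c), float(t)) for c, t in doc.get("true_reversals", [])],
        true_stickslips=[(int(c), float(t)) for c, t in doc.get("true_stickslips", [])],
        frame_interval=float(doc["frame_interval_s"]),
        pixel_size=float(doc["pixel_size_um"]),
        duration=float(doc["duration_s"]),
    )


def tracks_from_truth(truth: GroundTruth) -> list:
    """Convert true trajectories into Track objects, bypassing imaging.

    Useful to exercise reversal calling and statistics on exact
    coordinates: pole labels are the physical pole identities and the pole
    intensity series are the true marker levels (arbitrary units).
    """
    from myxotrack.tracking import Track

    tracks = []
    for c in truth.cells:
        n = len(c.x)
        tracks.append(Track(
            track_id=c.cell_id,
            frames=np.arange(n),
            x=c.x.copy(), y=c.y.copy(),
            pole1=c.pole_a.copy(), pole2=c.pole_b.copy(),
            pole1_intensity=c.fluor_a.copy(),
            pole2_intensity=c.fluor_b.copy(),
            length=np.full(n, c.length),
            area=np.full(n, np.nan),
            orientation=c.heading_deg % 180.0,
            frame_interval=truth.frame_interval,
        ))
    return tracks
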