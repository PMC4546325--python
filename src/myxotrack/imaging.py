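"""From raw two-channel stacks to per-frame cell detections.

Detection follows the classic recipe for phase-contrast movies of rod
bacteria: register every frame to the first one (stage drift), threshold
the inverted transmitted channel (cells are dark), keep connected
components above a minimum area that do not touch the border, and measure
for each component a sub-pixel intensity-weighted centroid, the principal
axis, the two pole positions, and background-subtracted fluorescence at
each pole.

Coordinate convention: 0-based pixel indices, ``x`` = column, ``y`` = row;
physical coordinates are ``pixel * pixel_size`` in µm.  Sub-pixel values
are allowed everywhere.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrameStack",
    "CellDetection",
    "stabilize_stack",
    "segment_frame",
    "extract_poles",
    "measure_pole_intensity",
    "detect_stack",
]


@dataclass
class FrameStack:
    """Two-channel calibrated image time series.

    ``pixels`` has shape (T, C, H, W); channel roles are named in
    ``channels`` (by default transmitted light first, fluorescence second).
    """

    pixels: np.ndarray
    pixel_size: float        # µm / px
    frame_interval: float    # s
    channels: tuple[str, ...] = ("transmitted", "fluorescence")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be a (T, C, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if len(self.channels) != self.pixels.shape[1]:
            raise ValueError("channel names do not match the channel axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[:, self.channels.index(role)]

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF (TCYX) plus a JSON calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.pixels, metadata={"axes": "TCYX"})
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "channels": list(self.channels),
        }), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None,
             frame_interval: float | None = None,
             channels: tuple[str, ...] | None = None) -> "FrameStack":
        path = Path(path)
        pixels = tifffile.imread(path)
        if pixels.ndim == 3:  # single channel stack
            pixels = pixels[:, None]
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text(encoding="utf-8"))
            pixel_size = pixel_size or meta.get("pixel_size_um")
            frame_interval = frame_interval or meta.get("frame_interval_s")
            channels = channels or tuple(meta.get("channels", ()))
        if not pixel_size or not frame_interval:
            raise ValueError(
                f"{path}: pixel size and frame interval must be supplied "
                "(sidecar missing or incomplete)"
            )
        if not channels:
            channels = ("transmitted", "fluorescence")[: pixels.shape[1]]
        return cls(pixels=pixels, pixel_size=float(pixel_size),
                   frame_interval=float(frame_interval), channels=tuple(channels))


@dataclass
class CellDetection:
    """One segmented cell in one frame (physical units)."""

    frame: int
    centroid: np.ndarray        # (x, y) µm, sub-pixel
    area: float                 # µm²
    orientation: float          # degrees in [0, 180)
    length: float               # µm, extent along the principal axis
    pole_a: np.ndarray          # (x, y) µm
    pole_b: np.ndarray
    pole_a_intensity: float = np.nan   # background-subtracted, a.u.
    pole_b_intensity: float = np.nan
    degenerate_axis: bool = False
    partial_pole_measure: bool = False


def stabilize_stack(
    stack: FrameStack,
    upsample_factor: int = 20,
    mode: str = "sequential",
) -> tuple[FrameStack, np.ndarray]:
    """Register every frame to frame 0 by translation (stage drift removal).

    Offsets are estimated on the transmitted channel by phase
    cross-correlation with sub-pixel refinement.  In ``sequential`` mode
    (default) the shift between each pair of consecutive frames is
    estimated and accumulated into the offset relative to frame 0 — robust
    when the only image structure is the cells themselves, which move
    little between adjacent frames.  In ``first`` mode every frame is
    correlated directly with frame 0, appropriate when a static scene or
    background texture dominates.  Each frame is then shifted once (both
    channels by the same offset).

    Returns the stabilized stack and the applied offsets as an (T, 2)
    array of (dx, dy) in px — the negative of the estimated drift.
    Featureless (zero-variance) frames get an identity step with a warning.
    """
    if stack.n_frames < 2:
        raise ValueError("stabilization needs at least 2 frames")
    if mode not in ("sequential", "first"):
        raise ValueError(f"unknown stabilization mode {mode!r}")
    trans = stack.channel("transmitted").astype(np.float64)
    offsets = np.zeros((stack.n_frames, 2))  # (dx, dy) applied to each frame
    cum = np.zeros(2)  # (drow, dcol)
    for t in range(1, stack.n_frames):
        ref = trans[0] if mode == "first" else trans[t - 1]
        frame = trans[t]
        if ref.std() == 0 or frame.std() == 0:
            warnings.warn(f"featureless frame near index {t}; identity offset used")
            step = np.zeros(2)
        else:
            step, _, _ = phase_cross_correlation(
                ref, frame, upsample_factor=upsample_factor, normalization=None
            )
        cum = step if mode == "first" else cum + step
        offsets[t] = (cum[1], cum[0])  # (dx, dy)

    out = np.empty_like(stack.pixels)
    out[0] = stack.pixels[0]
    is_int = np.issubdtype(stack.pixels.dtype, np.integer)
    for t in range(1, stack.n_frames):
        shift_rc = (offsets[t, 1], offsets[t, 0])  # (drow, dcol)
        if offsets[t, 0] == 0 and offsets[t, 1] == 0:
            out[t] = stack.pixels[t]
            continue
        for c in range(stack.pixels.shape[1]):
            shifted = ndimage.shift(
                stack.pixels[t, c].astype(np.float64),
                shift=shift_rc, order=1, mode="nearest",
            )
            if is_int:
                info = np.iinfo(stack.pixels.dtype)
                shifted = np.clip(np.rint(shifted), info.min, info.max)
            out[t, c] = shifted.astype(stack.pixels.dtype)
    stabilized = FrameStack(
        pixels=out, pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval, channels=stack.channels,
    )
    return stabilized, offsets


def _principal_axis(coords: np.ndarray, weights: np.ndarray,
                    centroid_px: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted principal axis of pixel coordinates; returns (unit xy, anisotropy)."""
    d = coords - centroid_px  # (N, 2) in (x, y)
    w = weights / weights.sum()
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, -1]
    anisotropy = math.sqrt(max(evals[-1], 1e-12) / max(evals[0], 1e-12))
    # deterministic sign: positive x, tie broken toward positive y
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    return u, anisotropy


def extract_poles(
    coords_px: np.ndarray,
    weights: np.ndarray,
    centroid_px: np.ndarray,
    min_anisotropy: float = 1.3,
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Pole positions of one connected component (px units).

    Poles are the points on the principal axis at the extreme projections
    of the component's pixels, ordered lexicographically (x, then y) so
    the geometric output is deterministic; persistent identity over time
    is assigned later by tracking.  Degenerate (round) components fall
    back to a fixed horizontal axis and are flagged.

    Returns (pole_a, pole_b, length_px, orientation_deg, degenerate).
    """
    u, aniso = _principal_axis(coords_px, weights, centroid_px)
    degenerate = aniso < min_anisotropy
    if degenerate:
        u = np.array([1.0, 0.0])
    proj = (coords_px - centroid_px) @ u
    t_min, t_max = float(proj.min()), float(proj.max())
    length_px = t_max - t_min + 1.0  # +1: pixels have unit extent
    pole_a = centroid_px + u * t_max
    pole_b = centroid_px + u * t_min
    if (pole_a[0], pole_a[1]) > (pole_b[0], pole_b[1]):
        pole_a, pole_b = pole_b, pole_a
    orientation = math.degrees(math.atan2(u[1], u[0])) % 180.0
    return pole_a, pole_b, length_px, orientation, degenerate


def segment_frame(
    image: np.ndarray,
    pixel_size: float,
    min_area: float = 1.0,
    method: str = "otsu",
    threshold: float | None = None,
    frame: int = 0,
) -> list[CellDetection]:
    """Detect cells in one transmitted-light frame by global thresholding.

    Cells are dark on a bright background, so pixels below the threshold
    (Otsu by default, or a fixed value) form the foreground.  Connected
    components smaller than ``min_area`` (µm²) or touching the image
    border are discarded.  Centroids are intensity-weighted (weight =
    darkness below threshold) and therefore sub-pixel.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.std() == 0:
        warnings.warn(f"frame {frame}: constant image, no cells detected")
        return []
    med = float(np.median(img))
    sigma_rob = 1.4826 * float(np.median(np.abs(img - med)))
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold method requires a threshold value")
        thr = float(threshold)
    elif method == "robust":
        thr = med - 5.0 * sigma_rob
    elif method == "otsu":
        thr = float(threshold_otsu(img))
        # Otsu splits the background mode when cells cover a tiny fraction
        # of the field; fall back to background statistics in that case
        if sigma_rob > 0 and float((img < thr).mean()) > 0.15:
            thr = med - 5.0 * sigma_rob
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = img < thr
    labels = label(mask, connectivity=2)
    h, w = img.shape
    min_area_px = min_area / pixel_size ** 2
    detections: list[CellDetection] = []
    sizes = np.bincount(labels.ravel())
    slices = ndimage.find_objects(labels)
    for region_label, sl in enumerate(slices, start=1):
        if sl is None or sizes[region_label] < min_area_px:
            continue
        sub = labels[sl] == region_label
        ys, xs = np.nonzero(sub)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        if xs.min() == 0 or ys.min() == 0 or xs.max() == w - 1 or ys.max() == h - 1:
            continue  # border-touching cells are not tracked
        coords = np.column_stack([xs, ys]).astype(float)
        weights = thr - img[ys, xs]
        weights = np.clip(weights, 1e-6, None)
        centroid_px = (coords * (weights / weights.sum())[:, None]).sum(axis=0)
        pole_a, pole_b, length_px, orientation, degenerate = extract_poles(
            coords, weights, centroid_px
        )
        detections.append(CellDetection(
            frame=frame,
            centroid=centroid_px * pixel_size,
            area=len(xs) * pixel_size ** 2,
            orientation=orientation,
            length=length_px * pixel_size,
            pole_a=pole_a * pixel_size,
            pole_b=pole_b * pixel_size,
            degenerate_axis=degenerate,
        ))
    detections.sort(key=lambda d: (d.centroid[0], d.centroid[1]))
    return detections


def measure_pole_intensity(
    fluor_image: np.ndarray,
    pole_um: np.ndarray,
    pixel_size: float,
    radius_px: float = 3.0,
    annulus_px: tuple[float, float] = (5.0, 7.0),
) -> tuple[float, bool]:
    """Background-subtracted fluorescence at a pole.

    Mean intensity inside a disc of ``radius_px`` centered on the pole,
    minus the local background (median of the surrounding annulus),
    clamped at zero.  If the disc or annulus crosses the field boundary
    only in-field pixels are used and the measurement is flagged partial.
    """
    img = np.asarray(fluor_image, dtype=np.float64)
    h, w = img.shape
    cx, cy = float(pole_um[0]) / pixel_size, float(pole_um[1]) / pixel_size
    r_out = annulus_px[1]
    x0, x1 = int(math.floor(cx - r_out)), int(math.ceil(cx + r_out))
    y0, y1 = int(math.floor(cy - r_out)), int(math.ceil(cy + r_out))
    partial = x0 < 0 or y0 < 0 or x1 > w - 1 or y1 > h - 1
    x0c, x1c = max(x0, 0), min(x1, w - 1)
    y0c, y1c = max(y0, 0), min(y1, h - 1)
    if x1c < x0c or y1c < y0c:
        return 0.0, True
    xs = np.arange(x0c, x1c + 1)
    ys = np.arange(y0c, y1c + 1)
    gx, gy = np.meshgrid(xs, ys)
    r = np.hypot(gx - cx, gy - cy)
    patch = img[y0c:y1c + 1, x0c:x1c + 1]
    disc = r <= radius_px
    ann = (r >= annulus_px[0]) & (r <= annulus_px[1])
    if not disc.any():
        return 0.0, True
    background = float(np.median(patch[ann])) if ann.any() else 0.0
    value = float(patch[disc].mean()) - background
    return max(value, 0.0), partial


def detect_stack(
    stack: FrameStack,
    min_area: float = 1.0,
    method: str = "otsu",
    threshold: float | None = None,
    pole_radius_px: float = 3.0,
    annulus_px: tuple[float, float] = (5.0, 7.0),
) -> list[list[CellDetection]]:
    """Segment every frame and measure pole fluorescence for each detection."""
    has_fluor = "fluorescence" in stack.channels
    trans = stack.channel("transmitted")
    fluor = stack.channel("fluorescence") if has_fluor else None
    per_frame: list[list[CellDetection]] = []
    for t in range(stack.n_frames):
        dets = segment_frame(
            trans[t], stack.pixel_size, min_area=min_area,
            method=method, threshold=threshold, frame=t,
        )
        if has_fluor:
            for det in dets:
                va, pa = measure_pole_intensity(
                    fluor[t], det.pole_a, stack.pixel_size,
                    radius_px=pole_radius_px, annulus_px=annulus_px,
                )
                vb, pb = measure_pole_intensity(
                    fluor[t], det.pole_b, stack.pixel_size,
                    radius_px=pole_radius_px, annulus_px=annulus_px,
                )
                det.pole_a_intensity = va
                det.pole_b_intensity = vb
                det.partial_pole_measure = pa or pb
        per_frame.append(dets)
    return per_frame
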