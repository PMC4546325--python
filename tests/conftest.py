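"""Shared fixtures: simulated scenes reused across the suite.

The expensive renders (benchmark movie, small movie) are session-scoped;
everything else is generated per test.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from myxotrack.pipeline import PipelineConfig, run_pipeline
from myxotrack.simulate import (
    CellTruth,
    GroundTruth,
    SimulationConfig,
    render_movie,
    simulate_trajectories,
)


@pytest.fixture(scope="session")
def small_run():
    """6 cells, 15 min, noise-free: quick end-to-end scene with truth."""
    cfg = SimulationConfig(n_cells=6, duration=900.0, noise_sd=0.0, rng_seed=11)
    truth = simulate_trajectories(cfg)
    stack = render_movie(truth, cfg)
    result = run_pipeline(PipelineConfig(), stack=stack)
    return cfg, truth, stack, result


@pytest.fixture(scope="session")
def benchmark_run():
    """20 cells, 30 min, noise-free: the event-recovery benchmark scene."""
    cfg = SimulationConfig(n_cells=20, duration=1800.0, noise_sd=0.0, rng_seed=42)
    truth = simulate_trajectories(cfg)
    stack = render_movie(truth, cfg)
    result = run_pipeline(PipelineConfig(), stack=stack)
    return cfg, truth, result


def make_static_truth(
    config: SimulationConfig,
    positions_um: list[tuple[float, float]],
    headings_deg: list[float] | None = None,
) -> GroundTruth:
    """Ground truth with immobile cells at given positions (no events)."""
    n_frames = config.n_frames
    headings = headings_deg or [0.0] * len(positions_um)
    cells = []
    for cid, ((px, py), hdg) in enumerate(zip(positions_um, headings)):
        u = np.array([math.cos(math.radians(hdg)), math.sin(math.radians(hdg))])
        length = config.cell_length_mean
        center = np.array([px, py])
        ones = np.ones(n_frames)
        cells.append(CellTruth(
            cell_id=cid,
            speed=0.0,
            length=length,
            x=ones * px,
            y=ones * py,
            heading_deg=ones * hdg,
            pole_a=np.tile(center + u * length / 2.0, (n_frames, 1)),
            pole_b=np.tile(center - u * length / 2.0, (n_frames, 1)),
            fluor_a=ones * config.leading_level,
            fluor_b=ones * config.lagging_level,
        ))
    return GroundTruth(
        cells=cells,
        true_reversals=[],
        true_stickslips=[],
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
        duration=(n_frames - 1) * config.frame_interval,
    )
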