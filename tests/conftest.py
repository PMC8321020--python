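"""Shared fixtures: synthetic scenarios rendered once per session."""

from __future__ import annotations

import math

import numpy as np
import pytest

from macrotrack import PipelineConfig, Scenario, run_pipeline, simulate_ground_truth
from macrotrack.synthgen import GroundTruth, render_stack


def make_contact_scenario(
    turn_a_deg: float = 60.0,
    turn_b_deg: float = -60.0,
    start: int = 24,
    end: int = 36,
    n_frames: int = 60,
    seed: int = 7,
    noise_sd: float = 0.0,
) -> Scenario:
    """Two cells, one programmed contact, generous frame."""
    return Scenario(
        n_cells=2,
        n_frames=n_frames,
        frame_shape=(360, 440),
        contact_events=[
            (0, 1, start, end,
             math.radians(turn_a_deg), math.radians(turn_b_deg))
        ],
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def contact_scenario() -> Scenario:
    return make_contact_scenario()


@pytest.fixture(scope="session")
def contact_truth(contact_scenario):
    return simulate_ground_truth(contact_scenario)


@pytest.fixture(scope="session")
def contact_stack(contact_truth, contact_scenario):
    return render_stack(contact_truth, contact_scenario)


@pytest.fixture(scope="session")
def contact_pipeline(contact_scenario, tmp_path_factory):
    """Full pipeline result for the standard two-cell contact scenario."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(output_dir=str(out), scenario=contact_scenario)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def three_cell_clump_truth():
    """Three cells riding abreast so their halos merge into one clump.

    Hand-built trajectories (no programmed pair events): three parallel
    cells 20 px apart moving right together, close enough that the green
    halos (radius 12) chain into a single connected component while the
    nuclei (radius 5) stay separate.
    """
    n_frames = 30
    positions = np.zeros((3, n_frames, 2))
    for c in range(3):
        for t in range(n_frames):
            positions[c, t] = (40.0 + 3.0 * t, 60.0 + 20.0 * c)
    return GroundTruth(positions=positions)


@pytest.fixture(scope="session")
def three_cell_clump_scenario():
    return Scenario(
        n_cells=3,
        n_frames=30,
        frame_shape=(180, 220),
        cell_speed=3.0,
        noise_sd=0.0,
        seed=3,
    )
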