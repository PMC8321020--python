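"""Generator contract: programmed contacts and turns are realised exactly."""

from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.ndimage as ndi

from macrotrack import Scenario, simulate_ground_truth
from macrotrack.synthgen import (
    BACKGROUND_LEVEL,
    FOREGROUND_LEVEL,
    GroundTruth,
    ScenarioError,
    read_ground_truth,
    render_stack,
    truth_to_table,
    write_ground_truth,
)

from conftest import make_contact_scenario


def waypoint_angle_change(positions, f0, f1, s):
    """Independent oracle: direction change from raw waypoints via arctan2.

    Angles measured y-up (rows negated), difference wrapped to (-pi, pi].
    """
    u = positions[f0] - positions[f0 - s]
    w = positions[f1 + s] - positions[f1]
    a = math.atan2(-u[1], u[0])
    b = math.atan2(-w[1], w[0])
    d = (b - a + math.pi) % (2 * math.pi) - math.pi
    return math.pi if d == -math.pi else d


class TestSimulate:
    def test_empty_scenario_gives_empty_trajectories(self):
        truth = simulate_ground_truth(Scenario(n_cells=0, n_frames=10))
        assert truth.positions.shape == (0, 10, 2)
        assert truth.contact_frames == ()

    def test_no_events_keeps_cells_apart(self):
        sc = Scenario(n_cells=2, n_frames=30, frame_shape=(200, 260), seed=1)
        truth = simulate_ground_truth(sc)
        assert truth.contact_frames == ()
        d = np.linalg.norm(truth.positions[0] - truth.positions[1], axis=1)
        assert np.all(d > 2 * sc.halo_radius)

    @pytest.mark.parametrize(
        "turn_a,turn_b",
        [(60.0, -60.0), (120.0, -90.0), (-45.0, 30.0), (90.0, 90.0)],
    )
    def test_planted_turns_recovered_from_waypoints(self, turn_a, turn_b):
        sc = make_contact_scenario(turn_a, turn_b, start=20, end=35,
                                   n_frames=55, seed=11)
        truth = simulate_ground_truth(sc)
        for cell, planted in ((0, turn_a), (1, turn_b)):
            for s in (3, 5):
                measured = waypoint_angle_change(
                    truth.positions[cell], 20, 35, s
                )
                assert measured == pytest.approx(math.radians(planted),
                                                 abs=1e-9)

    def test_contact_distance_band(self, contact_scenario, contact_truth):
        sc, truth = contact_scenario, contact_truth
        (start, end), = truth.contact_frames
        d = np.linalg.norm(truth.positions[0] - truth.positions[1], axis=1)
        inside = d[start : end + 1]
        assert np.all(inside <= 2 * sc.halo_radius - 2 + 1e-9)
        assert np.all(inside > 2 * sc.nucleus_radius + 2)
        assert d[start - 1] > 2 * sc.halo_radius
        assert d[end + 1] > 2 * sc.halo_radius

    def test_deterministic_given_seed(self, contact_scenario, contact_truth):
        again = simulate_ground_truth(make_contact_scenario())
        np.testing.assert_array_equal(contact_truth.positions, again.positions)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ScenarioError, match="overlapping"):
            Scenario(
                n_cells=3,
                n_frames=60,
                contact_events=[
                    (0, 1, 10, 20, 1.0, -1.0),
                    (0, 2, 15, 25, 1.0, -1.0),
                ],
            )

    def test_frame_exit_rejected(self):
        sc = make_contact_scenario()
        sc = Scenario(
            n_cells=2,
            n_frames=60,
            frame_shape=(64, 64),  # far too small for the paths
            contact_events=sc.contact_events,
            seed=7,
        )
        with pytest.raises(ScenarioError, match="fit"):
            simulate_ground_truth(sc)

    def test_radius_and_speed_validation(self):
        with pytest.raises(ScenarioError):
            Scenario(n_cells=1, n_frames=5, nucleus_radius=6, halo_radius=6)
        with pytest.raises(ScenarioError, match="halo_radius >= nucleus"):
            Scenario(n_cells=1, n_frames=5, nucleus_radius=6, halo_radius=7)
        with pytest.raises(ScenarioError, match="cell_speed too small"):
            Scenario(
                n_cells=2,
                n_frames=40,
                cell_speed=1.0,
                contact_events=[(0, 1, 10, 20, 1.0, -1.0)],
            )


class TestRender:
    def test_static_cell_disk_area(self):
        sc = Scenario(n_cells=1, n_frames=4, frame_shape=(80, 80),
                      noise_sd=0.0)
        centre = np.array([40.0, 37.0])
        truth = GroundTruth(
            positions=np.tile(centre, (1, sc.n_frames, 1)).reshape(1, -1, 2)
        )
        stack = render_stack(truth, sc)
        # oracle: exhaustive pixel scan with the same disk criterion
        yy, xx = np.mgrid[0:80, 0:80]
        expected = int(
            np.sum((xx - centre[0]) ** 2 + (yy - centre[1]) ** 2
                   <= sc.nucleus_radius**2)
        )
        for t in range(sc.n_frames):
            red = stack.frame(t)[..., 0]
            assert int(np.sum(red == FOREGROUND_LEVEL)) == expected
        np.testing.assert_array_equal(stack.frame(0), stack.frame(3))

    def test_contact_merges_green_components(self, contact_truth,
                                             contact_scenario, contact_stack):
        (start, end), = contact_truth.contact_frames
        mid = (start + end) // 2
        green = contact_stack.frame(mid)[..., 1] > BACKGROUND_LEVEL
        _, n_green = ndi.label(green, structure=np.ones((3, 3)))
        red = contact_stack.frame(mid)[..., 0] > BACKGROUND_LEVEL
        _, n_red = ndi.label(red, structure=np.ones((3, 3)))
        assert n_green == contact_scenario.n_cells - 1
        assert n_red == contact_scenario.n_cells

    def test_centroids_recover_truth_within_one_pixel(self, contact_truth,
                                                      contact_stack):
        red = contact_stack.frame(0)[..., 0] > FOREGROUND_LEVEL / 2
        labels, n = ndi.label(red, structure=np.ones((3, 3)))
        assert n == 2
        found = np.array(ndi.center_of_mass(red, labels, range(1, n + 1)))
        found_xy = found[:, ::-1]  # (row, col) -> (x, y)
        truth_xy = contact_truth.positions[:, 0]
        for p in truth_xy:
            assert np.min(np.linalg.norm(found_xy - p, axis=1)) < 1.0


class TestGroundTruthTable:
    def test_roundtrip(self, contact_truth, tmp_path):
        path = tmp_path / "truth.csv"
        write_ground_truth(contact_truth, path)
        back = read_ground_truth(path)
        np.testing.assert_allclose(back.positions, contact_truth.positions)
        assert back.contact_frames == contact_truth.contact_frames

    def test_empty_truth_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_ground_truth(GroundTruth(positions=np.zeros((0, 0, 2))), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1  # header only

    def test_row_count(self):
        sc = Scenario(n_cells=2, n_frames=50, frame_shape=(300, 300), seed=2)
        table = truth_to_table(simulate_ground_truth(sc))
        assert len(table) == 100
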