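"""Interaction selection, direction change, alignment, exit distance."""

from __future__ import annotations

import math

import numpy as np
import pytest

from macrotrack import (
    AnalysisConfig,
    ClumpInstance,
    Track,
    align_track,
    direction_change,
    exit_distance,
    select_interactions,
    time_in_clump,
)
from macrotrack.interactions import DegenerateDirectionError


def make_track(tid, points, first_frame=0):
    return Track(
        id=tid,
        positions={first_frame + i: np.asarray(p, dtype=float)
                   for i, p in enumerate(points)},
    )


def straight_track(tid, start, velocity, n):
    start, velocity = np.asarray(start, float), np.asarray(velocity, float)
    return make_track(tid, [start + t * velocity for t in range(n)])


PAIR = ClumpInstance(members=frozenset({1, 2}), tk0=10, tkC=15)


class TestTimeInClump:
    def test_single_frame_contact(self):
        assert time_in_clump(ClumpInstance(frozenset({1, 2}), 4, 4)) == 0

    def test_difference_formula(self):
        # 18 frames at 10 s/frame is 3 minutes of contact
        inst = ClumpInstance(frozenset({1, 2}), 10, 28)
        assert time_in_clump(inst) == 18

    def test_generator_event(self, contact_pipeline, contact_truth):
        (start, end), = contact_truth.contact_frames
        (inst,) = contact_pipeline.instances
        assert time_in_clump(inst) == end - start


class TestDirectionChange:
    def test_straight_track_zero(self):
        tr = straight_track(1, (0, 0), (2, 1), 25)
        assert direction_change(tr, PAIR, 5) == pytest.approx(0.0)

    def test_exact_reversal_is_plus_pi(self):
        # +x before, -x after: the antipodal case maps to +pi
        pts = [(t, 0.0) for t in range(11)] + [
            (10.0 - t, 0.0) for t in range(1, 11)
        ]
        tr = make_track(1, pts)
        inst = ClumpInstance(frozenset({1, 2}), 10, 10)
        assert direction_change(tr, inst, 5) == pytest.approx(math.pi)

    @pytest.mark.parametrize("phi_deg", [-170, -90, -30, 0.5, 45, 120, 179])
    def test_rotation_oracle(self, phi_deg):
        """w = R(phi) u (y-up rotation matrix applied in the test) must be
        measured as exactly phi."""
        rng = np.random.default_rng(int(abs(phi_deg) * 10))
        phi = math.radians(phi_deg)
        u = rng.uniform(-5, 5, size=2)
        ux, uy_up = u[0], -u[1]
        c, s = math.cos(phi), math.sin(phi)
        wx, wy_up = c * ux - s * uy_up, s * ux + c * uy_up
        w = np.array([wx, -wy_up])
        positions = {
            5: np.zeros(2), 10: u * 1.0,
            15: np.array([50.0, 50.0]), 20: np.array([50.0, 50.0]) + w,
        }
        tr = Track(id=1, positions=positions)
        assert direction_change(tr, PAIR, 5) == pytest.approx(phi, abs=1e-9)

    def test_zero_displacement_is_degenerate(self):
        tr = make_track(1, [(3.0, 3.0)] * 25)
        with pytest.raises(DegenerateDirectionError):
            direction_change(tr, PAIR, 5)


class TestAlignTrack:
    def test_identity_when_already_along_plus_x(self):
        tr = straight_track(1, (0, 0), (2, 0), 25)
        aligned = align_track(tr, PAIR, 5)
        assert aligned.rotation == pytest.approx(0.0)
        np.testing.assert_allclose(aligned.pre[-1], [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(aligned.pre[0], [-10.0, 0.0], atol=1e-12)

    def test_half_turn_for_minus_x_path(self):
        tr = straight_track(1, (100, 0), (-2, 0), 25)
        aligned = align_track(tr, PAIR, 5)
        assert abs(aligned.rotation) == pytest.approx(math.pi)
        np.testing.assert_allclose(aligned.pre[0], [-10.0, 0.0], atol=1e-9)

    def test_rigidity_and_theta_consistency(self):
        """Pairwise distances preserved to 1e-9 and the aligned post
        displacement angle equals the measured direction change."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            pts = rng.uniform(0, 200, size=(21, 2))
            tr = make_track(1, pts)
            aligned = align_track(tr, PAIR, 5)
            theta = direction_change(tr, PAIR, 5)
            for window, frames in (
                (aligned.pre, range(5, 11)),
                (aligned.post, range(15, 21)),
            ):
                raw = pts[list(frames)]
                d_raw = np.linalg.norm(
                    raw[:, None, :] - raw[None, :, :], axis=2
                )
                d_aligned = np.linalg.norm(
                    window[:, None, :] - window[None, :, :], axis=2
                )
                np.testing.assert_allclose(d_aligned, d_raw, atol=1e-9)
            post_disp = aligned.post[-1] - aligned.post[0]
            assert math.atan2(post_disp[1], post_disp[0]) == pytest.approx(
                theta, abs=1e-9
            )

    def test_zero_pre_displacement_rejected(self):
        tr = make_track(1, [(3.0, 3.0)] * 25)
        with pytest.raises(DegenerateDirectionError):
            align_track(tr, PAIR, 5)


class TestExitDistance:
    def test_stationary_cell(self):
        tr = make_track(1, [(float(t), 0.0) for t in range(16)]
                        + [(15.0, 0.0)] * 9)
        aligned = align_track(tr, PAIR, 5)
        assert exit_distance(aligned) == pytest.approx(0.0)

    def test_three_four_five(self):
        pts = [(float(t), 0.0) for t in range(16)]
        pts += [(15.0 + 3.0 * t / 5, 4.0 * t / 5) for t in range(1, 6)]
        tr = make_track(1, pts)
        aligned = align_track(tr, PAIR, 5)
        assert exit_distance(aligned) == pytest.approx(5.0)

    def test_path_length_mode_vs_norm_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 50, size=(21, 2))
        tr = make_track(1, pts)
        aligned = align_track(tr, PAIR, 5)
        assert exit_distance(aligned) == pytest.approx(
            np.linalg.norm(aligned.post[-1])
        )
        segs = np.linalg.norm(np.diff(pts[15:21], axis=0), axis=1)
        assert exit_distance(aligned, "path_length") == pytest.approx(
            segs.sum()
        )


class TestSelection:
    def test_three_member_instance_excluded(self):
        inst = ClumpInstance(frozenset({1, 2, 3}), 10, 15)
        tracks = [straight_track(i, (0, 10 * i), (2, 0), 25) for i in (1, 2, 3)]
        assert select_interactions([inst], tracks) == []

    def test_movie_starting_inside_contact_excludes_cell(self):
        inst = ClumpInstance(frozenset({1, 2}), 2, 8)  # tk0 < S
        tracks = [straight_track(i, (0, 10 * i), (2, 0), 25) for i in (1, 2)]
        assert select_interactions([inst], tracks,
                                   AnalysisConfig(S=5)) == []

    def test_partial_qualification_keeps_instance(self):
        inst = ClumpInstance(frozenset({1, 2}), 10, 15)
        full = straight_track(1, (0, 0), (2, 0), 25)
        # track 2 appears only from frame 8: no pre window
        late = Track(
            id=2,
            positions={f: np.array([2.0 * f, 30.0]) for f in range(8, 25)},
        )
        (it,) = select_interactions([inst], [full, late])
        assert [c.track_id for c in it.cells] == [1]

    def test_synthetic_event_fully_selected(self, contact_pipeline,
                                            contact_truth, contact_scenario):
        (start, end), = contact_truth.contact_frames
        (it,) = contact_pipeline.interactions
        assert it.instance.tk0 == start
        assert it.instance.tkC == end
        assert len(it.cells) == 2
        measured = sorted(c.theta for c in it.cells)
        planted = sorted(contact_truth.programmed_turns[0])
        for m, p in zip(measured, planted):
            assert m == pytest.approx(p, abs=math.radians(5))

    def test_s_monotonicity(self, contact_pipeline):
        """Raising S never increases the number of qualifying cells."""
        counts = []
        for s in range(1, 9):
            its = select_interactions(
                contact_pipeline.instances,
                contact_pipeline.tracks,
                AnalysisConfig(S=s),
            )
            counts.append(sum(len(it.cells) for it in its))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
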