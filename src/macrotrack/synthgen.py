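"""Synthetic two-channel movies of migrating cells with programmed contacts.

The generator plants cells as a small red nucleus disk inside a larger green
halo disk (emulating a nuclear label and a microtubule label).  Cells move
with piecewise-constant velocity.  A *contact event* between two cells is
choreographed so that their halo disks overlap during exactly the programmed
frame interval while the nuclei stay separate, and so that after the contact
each cell leaves with its pre-contact heading rotated by a programmed turn
angle.  This gives exact ground truth for every downstream stage: contact
interval, time in clump, and post-contact direction change.

Choreography
------------
During a contact the pair pivots about a fixed midpoint at constant
separation ``d_edge = 2*halo_radius - 3`` pixels (halos overlap, nuclei do
not).  The relative entry vector is placed anti-parallel to the relative
pre-contact velocity and the exit vector parallel to the relative
post-contact velocity, so the centre distance grows monotonically outside
the programmed frames and overlap starts/ends frame-exactly.  The relative
entry heading between the two cells is set to ``pi - D/2`` where ``D`` is
the (wrapped) difference of the turn angles, which bounds the separation
rate below by ``2 * cell_speed * cos(D/4) >= 1.41 * cell_speed``.

Angles follow the package convention: counter-clockwise positive when the
image is viewed y-up (rows negated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .geometry import angle_of, signed_angle, unit_from_angle, wrap_angle
from .stack import FrameStack

__all__ = [
    "ContactEvent",
    "Scenario",
    "GroundTruth",
    "simulate_ground_truth",
    "render_stack",
    "write_ground_truth",
    "read_ground_truth",
    "truth_to_table",
]

#: intensity levels used by the renderer (8-bit).  A zero background keeps
#: the low hysteresis level (a fraction of the Otsu level) strictly above
#: background even for noise-free, two-valued frames.
BACKGROUND_LEVEL = 0
FOREGROUND_LEVEL = 200

#: pixel clearance demanded outside programmed contacts, beyond 2*halo_radius,
#: so that discretised halo disks can never touch diagonally (sqrt(2) ~ 1.42)
_SEPARATION_CLEARANCE = 1.5
#: clearance demanded at the frames immediately adjacent to a contact
_BOUNDARY_CLEARANCE = 2.0


class ScenarioError(ValueError):
    """Raised when a scenario is invalid or cannot be choreographed."""


@dataclass(frozen=True)
class ContactEvent:
    """A programmed two-cell contact: halo overlap on frames [start, end]."""

    cell_a: int
    cell_b: int
    start: int
    end: int
    turn_a: float  # radians, post-contact heading change of cell_a
    turn_b: float


@dataclass(frozen=True)
class Scenario:
    """Parameters of one synthetic movie.

    Defaults emulate the acquisition this package targets: 512 x 672 frames,
    cells of ~1-2 um nucleus inside a ~5 um microtubule halo at 0.21 um/px,
    moving a few pixels per frame.
    """

    n_cells: int
    n_frames: int
    frame_shape: tuple[int, int] = (512, 672)  # rows, cols
    cell_speed: float = 4.0  # pixels / frame
    nucleus_radius: float = 5.0
    halo_radius: float = 12.0
    contact_events: tuple = ()
    noise_sd: float = 0.0
    heading_jitter_sd: float = 0.0  # radians/frame, non-contact cells only
    seed: int = 0

    def __post_init__(self):
        events = tuple(
            e if isinstance(e, ContactEvent) else ContactEvent(*e)
            for e in self.contact_events
        )
        object.__setattr__(self, "contact_events", events)
        self._validate()

    def _validate(self) -> None:
        if self.n_cells < 0 or self.n_frames < 0:
            raise ScenarioError("n_cells and n_frames must be nonnegative")
        if not (self.halo_radius > self.nucleus_radius > 0):
            raise ScenarioError("need halo_radius > nucleus_radius > 0")
        if self.halo_radius < self.nucleus_radius + 3:
            raise ScenarioError(
                "need halo_radius >= nucleus_radius + 3 so contacts can keep "
                "halos overlapping while nuclei stay separate"
            )
        if self.cell_speed <= 0:
            raise ScenarioError("cell_speed must be positive")
        per_cell: dict[int, list[ContactEvent]] = {}
        for ev in self.contact_events:
            if ev.cell_a == ev.cell_b:
                raise ScenarioError("event cell ids must be distinct")
            for c in (ev.cell_a, ev.cell_b):
                if not (0 <= c < self.n_cells):
                    raise ScenarioError(f"event references unknown cell {c}")
                per_cell.setdefault(c, []).append(ev)
            if not (0 <= ev.start <= ev.end < self.n_frames):
                raise ScenarioError(
                    f"event interval [{ev.start}, {ev.end}] outside movie"
                )
        for c, evs in per_cell.items():
            evs = sorted(evs, key=lambda e: e.start)
            for prev, nxt in zip(evs, evs[1:]):
                if nxt.start <= prev.end:
                    raise ScenarioError(
                        f"overlapping contact events for cell {c}"
                    )
        # minimum speed so overlap boundaries stay frame-exact
        d_edge = 2.0 * self.halo_radius - 3.0
        need = (2.0 * self.halo_radius + _BOUNDARY_CLEARANCE) - d_edge
        for ev in self.contact_events:
            d = wrap_angle(ev.turn_b - ev.turn_a)
            rate = 2.0 * self.cell_speed * abs(math.cos(d / 4.0))
            if rate < need:
                raise ScenarioError(
                    "cell_speed too small for frame-exact contact "
                    f"boundaries: separation rate {rate:.2f} px/frame < "
                    f"{need:.2f} required for event "
                    f"({ev.cell_a},{ev.cell_b})"
                )


@dataclass
class GroundTruth:
    """Planted trajectories plus the programmed contacts that produced them.

    ``positions[cell, frame]`` is ``(x, y)`` in pixel coordinates
    (x = column, y = row).
    """

    positions: np.ndarray
    events: tuple[ContactEvent, ...] = ()

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def contact_frames(self) -> tuple[tuple[int, int], ...]:
        """Per event, the inclusive frame interval of programmed halo overlap."""
        return tuple((ev.start, ev.end) for ev in self.events)

    @property
    def programmed_turns(self) -> tuple[tuple[float, float], ...]:
        """Per event, the planted (turn_a, turn_b) in radians."""
        return tuple((ev.turn_a, ev.turn_b) for ev in self.events)


@dataclass
class _CellState:
    """Bookkeeping while choreographing one cell."""

    heading: float | None = None  # y-up angle; None = not yet constrained
    placed_from: int | None = None  # first frame with a committed position
    placed_to: int | None = None  # last frame with a committed position


def simulate_ground_truth(scenario: Scenario) -> GroundTruth:
    """Build exact trajectories realising a scenario's programmed contacts.

    Deterministic given ``scenario.seed``.  Raises :class:`ScenarioError`
    when the events cannot be choreographed (conflicting headings, cells
    that would leave the frame, or accidental contacts between cells that
    were not programmed to meet).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n, f = sc.n_cells, sc.n_frames
    pos = np.full((n, f, 2), np.nan)
    if n == 0 or f == 0:
        return GroundTruth(positions=pos, events=sc.contact_events)

    speed = sc.cell_speed
    d_edge = 2.0 * sc.halo_radius - 3.0
    states = {c: _CellState() for c in range(n)}
    event_cells = set()
    for ev in sc.contact_events:
        event_cells.update((ev.cell_a, ev.cell_b))

    for ev in sorted(sc.contact_events, key=lambda e: e.start):
        _choreograph_event(sc, ev, pos, states, rng, speed, d_edge)

    # extend every event cell forward to the end of the movie
    for c in sorted(event_cells):
        st = states[c]
        last = st.placed_to
        for t in range(last + 1, f):
            pos[c, t] = pos[c, last] + (t - last) * speed * unit_from_angle(
                st.heading
            )

    _place_free_cells(sc, pos, states, rng, event_cells)
    _fit_to_frame(sc, pos)
    _validate_truth(sc, pos)
    return GroundTruth(positions=pos, events=sc.contact_events)


def _choreograph_event(sc, ev, pos, states, rng, speed, d_edge) -> None:
    a, b = ev.cell_a, ev.cell_b
    st_a, st_b = states[a], states[b]
    d = wrap_angle(ev.turn_b - ev.turn_a)
    delta = math.pi - d / 2.0

    if st_a.heading is None and st_b.heading is None:
        phi_a = rng.uniform(0.0, 2.0 * math.pi)
        phi_b = phi_a + delta
    elif st_a.heading is None:
        phi_b = st_b.heading
        phi_a = phi_b - delta
    elif st_b.heading is None:
        phi_a = st_a.heading
        phi_b = phi_a + delta
    else:  # both constrained by earlier events; feasibility checked later
        phi_a, phi_b = st_a.heading, st_b.heading

    u_a, u_b = unit_from_angle(phi_a), unit_from_angle(phi_b)
    w_a = unit_from_angle(phi_a + ev.turn_a)
    w_b = unit_from_angle(phi_b + ev.turn_b)

    d_pre = speed * (u_b - u_a)
    d_post = speed * (w_b - w_a)
    if np.linalg.norm(d_pre) < 1e-9 or np.linalg.norm(d_post) < 1e-9:
        raise ScenarioError(
            f"event ({a},{b}) has parallel approach or exit headings; "
            "cells would never separate"
        )
    r_in = -d_edge * d_pre / np.linalg.norm(d_pre)
    r_out = d_edge * d_post / np.linalg.norm(d_post)

    # centre of the pivot: pinned by an already-placed participant, else free
    centre = None
    if st_a.placed_to is not None:
        entry_a = pos[a, st_a.placed_to] + (
            (ev.start - st_a.placed_to) * speed * unit_from_angle(st_a.heading)
        )
        centre = entry_a + r_in / 2.0
    if st_b.placed_to is not None:
        entry_b = pos[b, st_b.placed_to] + (
            (ev.start - st_b.placed_to) * speed * unit_from_angle(st_b.heading)
        )
        centre_b = entry_b - r_in / 2.0
        if centre is not None and np.linalg.norm(centre - centre_b) > 1e-6:
            raise ScenarioError(
                f"event ({a},{b}) is over-constrained by earlier events "
                "and cannot be choreographed"
            )
        centre = centre_b if centre is None else centre
    if centre is None:
        rows, cols = sc.frame_shape
        centre = np.array(
            [
                rng.uniform(0.3 * cols, 0.7 * cols),
                rng.uniform(0.3 * rows, 0.7 * rows),
            ]
        )

    # contact frames: rotate the relative vector from r_in to r_out
    c_frames = ev.end - ev.start
    phi_in, phi_out = angle_of(r_in), angle_of(r_out)
    dphi = wrap_angle(phi_out - phi_in)
    for j in range(c_frames + 1):
        frac = j / c_frames if c_frames else 0.0
        r = d_edge * unit_from_angle(phi_in + dphi * frac)
        pos[a, ev.start + j] = centre - r / 2.0
        pos[b, ev.start + j] = centre + r / 2.0

    # pre legs: straight back to the previous commitment (or movie start)
    for c, phi, rv in ((a, phi_a, -r_in / 2.0), (b, phi_b, r_in / 2.0)):
        st = states[c]
        entry = centre + rv
        back_to = 0 if st.placed_to is None else st.placed_to + 1
        u = unit_from_angle(phi)
        for t in range(back_to, ev.start):
            pos[c, t] = entry - (ev.start - t) * speed * u
        st.placed_from = 0 if st.placed_from is None else st.placed_from
        st.placed_to = ev.end
        st.heading = phi + (ev.turn_a if c == a else ev.turn_b)


def _place_free_cells(sc, pos, states, rng, event_cells) -> None:
    """Non-event cells travel in straight horizontal lanes near the top."""
    free = [c for c in range(sc.n_cells) if c not in event_cells]
    if not free:
        return
    lane_gap = 2.0 * sc.halo_radius + 8.0
    path = (sc.n_frames - 1) * sc.cell_speed
    for i, c in enumerate(free):
        y0 = -(i + 1) * lane_gap  # above the event region; fitted later
        x0 = -path / 2.0
        phi = 0.0
        p = np.array([x0, y0])
        for t in range(sc.n_frames):
            pos[c, t] = p
            if sc.heading_jitter_sd > 0:
                phi += rng.normal(0.0, sc.heading_jitter_sd)
            p = p + sc.cell_speed * unit_from_angle(phi)
        states[c].heading = phi


def _fit_to_frame(sc, pos) -> None:
    """Rigidly translate all trajectories to fit inside the frame."""
    rows, cols = sc.frame_shape
    margin = sc.halo_radius + 2.0
    lo = np.nanmin(pos.reshape(-1, 2), axis=0)
    hi = np.nanmax(pos.reshape(-1, 2), axis=0)
    span = hi - lo
    avail = np.array([cols - 1, rows - 1]) - 2.0 * margin
    if span[0] > avail[0] or span[1] > avail[1]:
        raise ScenarioError(
            f"trajectories span {span[0]:.0f} x {span[1]:.0f} px and do not "
            f"fit a {cols} x {rows} frame with a {margin:.0f} px border; "
            "enlarge frame_shape, lower cell_speed or shorten the movie"
        )
    shift = margin + (avail - span) / 2.0 - lo
    pos += shift


def _validate_truth(sc, pos) -> None:
    """Check the contact-geometry contract for every frame and pair."""
    programmed = {}
    for ev in sc.contact_events:
        key = frozenset((ev.cell_a, ev.cell_b))
        programmed.setdefault(key, []).append((ev.start, ev.end))
    n = sc.n_cells
    hr, nr = sc.halo_radius, sc.nucleus_radius
    max_step = 3.0 * sc.cell_speed + 1e-6
    step = np.linalg.norm(np.diff(pos, axis=1), axis=2)
    if step.size and np.nanmax(step) > max_step:
        raise ScenarioError(
            "a choreographed cell moves more than 3 x cell_speed in one "
            "frame; lengthen the contact or raise cell_speed"
        )
    for i in range(n):
        for j in range(i + 1, n):
            dist = np.linalg.norm(pos[i] - pos[j], axis=1)
            in_contact = np.zeros(sc.n_frames, dtype=bool)
            for s, e in programmed.get(frozenset((i, j)), []):
                in_contact[s : e + 1] = True
            bad = dist[in_contact]
            if bad.size and (
                np.any(bad > 2 * hr - 2 + 1e-9)
                or np.any(bad <= 2 * nr + 2)
            ):
                raise ScenarioError(
                    f"cells {i},{j} violate the contact distance band"
                )
            apart = dist[~in_contact]
            if apart.size and np.any(
                apart <= 2 * hr + _SEPARATION_CLEARANCE
            ):
                raise ScenarioError(
                    f"cells {i},{j} come within halo range outside their "
                    "programmed contacts; adjust the scenario"
                )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_disk(channel: np.ndarray, centre, radius: float, value: int) -> None:
    """Set pixels with centre distance <= radius to ``value`` (in place)."""
    rows, cols = channel.shape
    x, y = float(centre[0]), float(centre[1])
    r0 = max(int(math.floor(y - radius)), 0)
    r1 = min(int(math.ceil(y + radius)) + 1, rows)
    c0 = max(int(math.floor(x - radius)), 0)
    c1 = min(int(math.ceil(x + radius)) + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    channel[r0:r1, c0:c1][mask] = value


def render_stack(
    truth: GroundTruth,
    scenario: Scenario,
    blur_sigma: float = 0.0,
) -> FrameStack:
    """Render planted trajectories into an 8-bit RGB stack.

    Red channel: filled nucleus disks; green channel: filled halo disks;
    blue channel: unused (zeros), mirroring the acquisition format.  Additive
    Gaussian noise of ``scenario.noise_sd`` is applied after an optional
    Gaussian blur; intensities are clipped to [0, 255].
    """
    if truth.positions.shape[:2] != (scenario.n_cells, scenario.n_frames):
        raise ValueError("ground truth inconsistent with scenario")
    rows, cols = scenario.frame_shape
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    frames = np.zeros((scenario.n_frames, rows, cols, 3), dtype=np.uint8)
    for t in range(scenario.n_frames):
        red = np.full((rows, cols), float(BACKGROUND_LEVEL))
        green = np.full((rows, cols), float(BACKGROUND_LEVEL))
        for c in range(scenario.n_cells):
            p = truth.positions[c, t]
            if np.any(np.isnan(p)):
                continue
            _paint_disk(green, p, scenario.halo_radius, FOREGROUND_LEVEL)
            _paint_disk(red, p, scenario.nucleus_radius, FOREGROUND_LEVEL)
        if blur_sigma > 0:
            red = ndi.gaussian_filter(red, blur_sigma)
            green = ndi.gaussian_filter(green, blur_sigma)
        if scenario.noise_sd > 0:
            red = red + rng.normal(0.0, scenario.noise_sd, red.shape)
            green = green + rng.normal(0.0, scenario.noise_sd, green.shape)
        frames[t, ..., 0] = np.clip(red, 0, 255).astype(np.uint8)
        frames[t, ..., 1] = np.clip(green, 0, 255).astype(np.uint8)
    return FrameStack(frames=frames)


# ---------------------------------------------------------------------------
# ground-truth tables
# ---------------------------------------------------------------------------

def truth_to_table(truth: GroundTruth) -> pd.DataFrame:
    """One row per (cell, frame): positions plus contact annotations."""
    records = []
    for c in range(truth.n_cells):
        for t in range(truth.n_frames):
            in_contact, event_id = 0, -1
            for k, ev in enumerate(truth.events):
                if c in (ev.cell_a, ev.cell_b) and ev.start <= t <= ev.end:
                    in_contact, event_id = 1, k
                    break
            x, y = truth.positions[c, t]
            records.append(
                {
                    "cell_id": c,
                    "frame": t,
                    "x": x,
                    "y": y,
                    "in_contact": in_contact,
                    "event_id": event_id,
                }
            )
    return pd.DataFrame(
        records,
        columns=["cell_id", "frame", "x", "y", "in_contact", "event_id"],
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the ground-truth table as CSV (frames 0-based)."""
    truth_to_table(truth).to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    """Read a CSV written by :func:`write_ground_truth`.

    Trajectories round-trip losslessly; events are reconstructed from the
    contact annotations with turn angles unknown (NaN).
    """
    df = pd.read_csv(path)
    if df.empty:
        return GroundTruth(positions=np.zeros((0, 0, 2)))
    n_cells = int(df["cell_id"].max()) + 1
    n_frames = int(df["frame"].max()) + 1
    pos = np.full((n_cells, n_frames, 2), np.nan)
    pos[df["cell_id"], df["frame"], 0] = df["x"]
    pos[df["cell_id"], df["frame"], 1] = df["y"]
    events = []
    for eid, sub in df[df["event_id"] >= 0].groupby("event_id"):
        cells = sorted(sub["cell_id"].unique())
        events.append(
            ContactEvent(
                cell_a=int(cells[0]),
                cell_b=int(cells[-1]),
                start=int(sub["frame"].min()),
                end=int(sub["frame"].max()),
                turn_a=math.nan,
                turn_b=math.nan,
            )
        )
    return GroundTruth(positions=pos, events=tuple(events))


def planted_direction_change(truth: GroundTruth, event_index: int, cell: int,
                             s_frames: int) -> float:
    """Planted turn angle measured directly on the generator's waypoints.

    Endpoint displacements over ``s_frames`` before/after the programmed
    interval, identical in definition to the analysis-side angle.  Useful as
    an independent check that choreography realised the programmed turns.
    """
    ev = truth.events[event_index]
    if cell not in (ev.cell_a, ev.cell_b):
        raise ValueError("cell not part of the event")
    p = truth.positions[cell]
    u = p[ev.start] - p[ev.start - s_frames]
    w = p[ev.end + s_frames] - p[ev.end]
    return signed_angle(u, w)
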