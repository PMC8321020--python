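"""Selection and quantification of two-cell contact interactions.

An *interaction* is a clump instance with exactly two member tracks where at
least one cell completes a full entry and exit: its track covers the ``S``
frames before first contact (``tk0``) and the ``S`` frames after last
contact (``tkC``).  For each qualifying cell the analysis computes:

``theta_x``
    the signed change of direction, in (-pi, pi]: the angle from the
    pre-contact displacement ``u = x(tk0) - x(tk0 - S)`` to the post-contact
    displacement ``w = x(tkC + S) - x(tkC)``, positive counter-clockwise
    with the image viewed y-up.

``TC``
    the time in clump, ``tkC - tk0`` frames.

aligned coordinates
    a rigid transform taking the pre-contact path into a canonical frame:
    the contact entry point maps to the origin and the pre-contact
    displacement points along +x'.  The post-contact window is re-anchored
    at the contact exit point (movement within the clump is deliberately
    not analysed) and rotated by the same angle, so post paths emanate from
    the origin and the aligned post direction reads off ``theta_x``.

``exit_distance``
    how far the cell ends up from the origin of the aligned frame after the
    S post-contact frames (or, optionally, the cumulative path length).

The range of ``S`` of interest is 3-5 frames (30-50 s at a 10 s frame
interval); larger windows measure longer-term behaviour and are out of
scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import angle_of, signed_angle, to_cartesian

__all__ = [
    "AnalysisConfig",
    "AlignedTrack",
    "CellInteraction",
    "Interaction",
    "DegenerateDirectionError",
    "time_in_clump",
    "direction_change",
    "align_track",
    "exit_distance",
    "select_interactions",
    "interactions_to_dataframe",
]


class DegenerateDirectionError(ValueError):
    """A direction window with zero displacement: the angle is undefined."""


@dataclass
class AnalysisConfig:
    """Parameters of the interaction analysis."""

    S: int = 5  # frames before/after contact used for direction estimation
    s_range: tuple[int, int] = (3, 5)  # sweep range of interest
    exit_mode: str = "endpoint"  # or "path_length"

    def __post_init__(self):
        if self.S < 1:
            raise ValueError("S must be >= 1")
        lo, hi = self.s_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid s_range")
        if self.exit_mode not in ("endpoint", "path_length"):
            raise ValueError("exit_mode must be 'endpoint' or 'path_length'")


@dataclass
class AlignedTrack:
    """Pre/post windows of one cell in the canonical (x', y') frame.

    Points are y-up Cartesian.  ``pre[-1]`` is the origin (contact entry);
    ``post[0]`` is the origin (contact exit, re-anchored).
    """

    pre: np.ndarray  # (S+1, 2)
    post: np.ndarray  # (S+1, 2)
    rotation: float  # radians applied to both windows
    pre_anchor: np.ndarray  # image-coordinate point mapped to the pre origin
    post_anchor: np.ndarray


def time_in_clump(instance) -> int:
    """TC = tkC - tk0, in frames."""
    return instance.tkC - instance.tk0


def _window_positions(track, frames) -> np.ndarray:
    try:
        return np.array([track.positions[f] for f in frames], dtype=float)
    except KeyError as exc:
        raise KeyError(
            f"track {track.id} lacks a position at frame {exc.args[0]}"
        ) from None


def direction_change(track, instance, S: int) -> float:
    """Signed direction change theta_x of one cell across a clump instance.

    Requires positions at ``tk0 - S``, ``tk0``, ``tkC`` and ``tkC + S``.
    Raises :class:`DegenerateDirectionError` when either displacement is
    zero (the angle is undefined and the cell must be excluded from angle
    statistics).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    u = track.positions[instance.tk0] - track.positions[instance.tk0 - S]
    w = track.positions[instance.tkC + S] - track.positions[instance.tkC]
    if np.linalg.norm(u) < 1e-12 or np.linalg.norm(w) < 1e-12:
        raise DegenerateDirectionError(
            f"track {track.id}: zero displacement over the S={S} window"
        )
    return signed_angle(u, w)


def align_track(track, instance, S: int) -> AlignedTrack:
    """Rigidly map a cell's pre/post windows into the canonical frame.

    The transform translates the contact entry point ``x(tk0)`` to the
    origin and rotates so the pre-contact displacement lies along +x'
    (the cell enters travelling left to right).  The post window is first
    translated so ``x(tkC)`` sits at the origin, then rotated by the same
    angle.
    """
    u = track.positions[instance.tk0] - track.positions[instance.tk0 - S]
    if np.linalg.norm(u) < 1e-12:
        raise DegenerateDirectionError(
            f"track {track.id}: zero pre-contact displacement"
        )
    rotation = -angle_of(u)
    c, s = math.cos(rotation), math.sin(rotation)
    rot = np.array([[c, -s], [s, c]])

    pre_frames = range(instance.tk0 - S, instance.tk0 + 1)
    post_frames = range(instance.tkC, instance.tkC + S + 1)
    pre_img = _window_positions(track, pre_frames)
    post_img = _window_positions(track, post_frames)
    pre = to_cartesian(pre_img - pre_img[-1]) @ rot.T
    post = to_cartesian(post_img - post_img[0]) @ rot.T
    return AlignedTrack(
        pre=pre,
        post=post,
        rotation=rotation,
        pre_anchor=pre_img[-1].copy(),
        post_anchor=post_img[0].copy(),
    )


def exit_distance(aligned: AlignedTrack, mode: str = "endpoint") -> float:
    """Distance covered after leaving the clump, in the aligned frame.

    ``endpoint`` (default): Euclidean distance from the origin to the final
    post-window point.  ``path_length``: cumulative length of the post path.
    """
    if len(aligned.post) == 0:
        raise ValueError("aligned post window is empty")
    if mode == "endpoint":
        return float(np.linalg.norm(aligned.post[-1]))
    if mode == "path_length":
        return float(
            np.sum(np.linalg.norm(np.diff(aligned.post, axis=0), axis=1))
        )
    raise ValueError("mode must be 'endpoint' or 'path_length'")


@dataclass
class CellInteraction:
    """Per-cell measurements inside one interaction."""

    track_id: int
    theta: float | None  # radians; None when degenerate
    aligned: AlignedTrack | None
    exit_distance: float | None
    degenerate: bool = False


@dataclass
class Interaction:
    """A selected two-cell contact event with its measurements."""

    instance: object  # ClumpInstance with exactly two members
    cells: list[CellInteraction] = field(default_factory=list)
    dataset_id: str = ""
    group: str = ""
    S: int = 5

    @property
    def tc(self) -> int:
        return time_in_clump(self.instance)

    def tc_seconds(self, frame_interval: float) -> float:
        return self.tc * frame_interval


def select_interactions(
    instances,
    tracks,
    config: AnalysisConfig | None = None,
    dataset_id: str = "",
    group: str = "",
) -> list[Interaction]:
    """Apply the selection criteria and measure the qualifying cells.

    Criteria: (i) exactly two member tracks in the instance; (ii) full
    interaction — a cell is analysed only if its track covers every frame of
    ``[tk0 - S, tk0]`` and ``[tkC, tkC + S]``.  An instance is kept if at
    least one cell qualifies.  Cells with an undefined (zero-displacement)
    angle are kept in the row but flagged and excluded from angle
    statistics.
    """
    config = config or AnalysisConfig()
    S = config.S
    by_id = {tr.id: tr for tr in tracks}
    selected = []
    for inst in instances:
        if len(inst.members) != 2:
            continue
        cells = []
        for tid in sorted(inst.members):
            tr = by_id.get(tid)
            if tr is None or inst.tk0 - S < 0:
                continue
            needed = list(range(inst.tk0 - S, inst.tk0 + 1)) + list(
                range(inst.tkC, inst.tkC + S + 1)
            )
            if not tr.has_frames(needed):
                continue
            try:
                theta = direction_change(tr, inst, S)
                aligned = align_track(tr, inst, S)
                dist = exit_distance(aligned, config.exit_mode)
                cells.append(
                    CellInteraction(
                        track_id=tid,
                        theta=theta,
                        aligned=aligned,
                        exit_distance=dist,
                    )
                )
            except DegenerateDirectionError:
                cells.append(
                    CellInteraction(
                        track_id=tid,
                        theta=None,
                        aligned=None,
                        exit_distance=None,
                        degenerate=True,
                    )
                )
        if cells:
            selected.append(
                Interaction(
                    instance=inst,
                    cells=cells,
                    dataset_id=dataset_id,
                    group=group,
                    S=S,
                )
            )
    return selected


def interactions_to_dataframe(
    interactions, frame_interval: float = 10.0
) -> pd.DataFrame:
    """One row per analysed cell of each interaction."""
    records = []
    for it in interactions:
        inst = it.instance
        for cell in it.cells:
            records.append(
                {
                    "dataset_id": it.dataset_id,
                    "group": it.group,
                    "code": inst.code,
                    "tk0": inst.tk0,
                    "tkC": inst.tkC,
                    "TC_frames": it.tc,
                    "TC_seconds": it.tc_seconds(frame_interval),
                    "track_id": cell.track_id,
                    "theta_deg": (
                        math.degrees(cell.theta)
                        if cell.theta is not None
                        else np.nan
                    ),
                    "exit_distance_px": (
                        cell.exit_distance
                        if cell.exit_distance is not None
                        else np.nan
                    ),
                    "S": it.S,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "dataset_id",
            "group",
            "code",
            "tk0",
            "tkC",
            "TC_frames",
            "TC_seconds",
            "track_id",
            "theta_deg",
            "exit_distance_px",
            "S",
        ],
    )
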