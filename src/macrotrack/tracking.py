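"""Frame-to-frame linking of nucleus centroids with a keyhole gate.

A detection may continue a track if it falls inside the track's *keyhole*:
the union of a fallback circle around the last position and a wedge opened
along the last displacement (the track's predicted heading).  Conflicts are
resolved greedily by distance to the linearly predicted position, with
deterministic tie-breaking.  Unmatched detections seed new tracks; a track
that misses its detection for more than one consecutive frame is terminated
(a single missed frame is bridged by linear interpolation).

A plain nearest-neighbour circular gate is available as a fallback mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KeyholeParams",
    "Track",
    "keyhole_link",
    "compute_velocities",
    "tracks_to_dataframe",
]


@dataclass
class KeyholeParams:
    """Geometry of the linking gate.

    ``fallback_radius=None`` sets the radius adaptively to three times the
    median frame-to-frame nearest-neighbour displacement of the detections.
    """

    wedge_half_angle: float = 30.0  # degrees
    wedge_length_factor: float = 3.0  # multiple of the previous displacement
    fallback_radius: float | None = None  # pixels
    max_gap: int = 1  # missed frames tolerated before termination
    mode: str = "keyhole"  # or "nearest" (circle-only gate)

    def __post_init__(self):
        if not 0 < self.wedge_half_angle < 90:
            raise ValueError("wedge_half_angle must be in (0, 90) degrees")
        if self.wedge_length_factor <= 0:
            raise ValueError("wedge_length_factor must be positive")
        if self.fallback_radius is not None and self.fallback_radius <= 0:
            raise ValueError("fallback_radius must be positive")
        if self.mode not in ("keyhole", "nearest"):
            raise ValueError("mode must be 'keyhole' or 'nearest'")


@dataclass
class Track:
    """One cell's trajectory: per-frame positions, velocities, clump keys."""

    id: int
    positions: dict[int, np.ndarray] = field(default_factory=dict)
    velocities: dict[int, np.ndarray] = field(default_factory=dict)
    clump_membership: dict[int, tuple] = field(default_factory=dict)
    interpolated_frames: set[int] = field(default_factory=set)

    @property
    def frames(self) -> list[int]:
        return sorted(self.positions)

    @property
    def first_frame(self) -> int:
        return min(self.positions)

    @property
    def last_frame(self) -> int:
        return max(self.positions)

    def position(self, frame: int) -> np.ndarray:
        return self.positions[frame]

    def has_frames(self, frames) -> bool:
        return all(f in self.positions for f in frames)

    def __len__(self) -> int:
        return len(self.positions)


def compute_velocities(track: Track) -> Track:
    """Fill per-frame velocities as first differences (first frame: zero)."""
    frames = track.frames
    for i, f in enumerate(frames):
        if i and frames[i - 1] == f - 1:
            track.velocities[f] = track.positions[f] - track.positions[f - 1]
        else:
            track.velocities[f] = np.zeros(2)
    return track


def _estimate_fallback_radius(detections) -> float:
    """Three times the median nearest-neighbour step between frames."""
    steps = []
    for prev, curr in zip(detections, detections[1:]):
        if len(prev) == 0 or len(curr) == 0:
            continue
        prev = np.asarray(prev, dtype=float)
        curr = np.asarray(curr, dtype=float)
        d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
        steps.extend(d.min(axis=1))
    if not steps:
        return 10.0
    return max(3.0 * float(np.median(steps)), 3.0)


def _in_gate(delta: np.ndarray, last_disp: np.ndarray,
             params: KeyholeParams, radius: float) -> bool:
    dist = float(np.linalg.norm(delta))
    if dist <= radius:
        return True
    if params.mode != "keyhole":
        return False
    speed = float(np.linalg.norm(last_disp))
    if speed < 1e-9:
        return False
    if dist > params.wedge_length_factor * speed:
        return False
    cos_angle = float(np.dot(delta, last_disp)) / (dist * speed)
    return cos_angle >= math.cos(math.radians(params.wedge_half_angle))


def keyhole_link(detections, params: KeyholeParams | None = None) -> list[Track]:
    """Link per-frame centroid lists into tracks.

    ``detections`` is a sequence over frames; each element is a list/array of
    ``(x, y)`` positions (possibly empty).  Returns tracks with ids assigned
    from 1 in order of creation, velocities filled in.
    """
    if params is None:
        params = KeyholeParams()
    detections = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections]
    if len(detections) == 0:
        raise ValueError("need at least one frame of detections")
    radius = (
        params.fallback_radius
        if params.fallback_radius is not None
        else _estimate_fallback_radius(detections)
    )

    tracks: list[Track] = []

    def new_track(frame: int, point: np.ndarray) -> None:
        tracks.append(Track(id=len(tracks) + 1, positions={frame: point.copy()}))

    for p in detections[0]:
        new_track(0, p)

    for t in range(1, len(detections)):
        dets = detections[t]
        active = [
            tr for tr in tracks if tr.last_frame >= t - 1 - params.max_gap
        ]
        candidates = []
        for ai, tr in enumerate(active):
            last_f = tr.last_frame
            last_pos = tr.positions[last_f]
            prev = tr.positions.get(last_f - 1)
            last_disp = (
                last_pos - prev if prev is not None else np.zeros(2)
            )
            predicted = last_pos + last_disp
            for di, p in enumerate(dets):
                if _in_gate(p - last_pos, last_disp, params, radius):
                    d_pred = float(np.linalg.norm(p - predicted))
                    candidates.append((d_pred, di, ai))
        candidates.sort()  # distance, then detection index, then track order
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d_pred, di, ai in candidates:
            if di in used_dets or ai in used_tracks:
                continue
            used_dets.add(di)
            used_tracks.add(ai)
            tr = active[ai]
            if tr.last_frame == t - 2:  # bridge a single missed frame
                tr.positions[t - 1] = (tr.positions[t - 2] + dets[di]) / 2.0
                tr.interpolated_frames.add(t - 1)
            tr.positions[t] = dets[di].copy()
        for di, p in enumerate(dets):
            if di not in used_dets:
                new_track(t, p)

    for tr in tracks:
        compute_velocities(tr)
    return tracks


def tracks_to_dataframe(tracks) -> pd.DataFrame:
    """Long-format table: track_id, frame, x, y, dx, dy, clump_key."""
    records = []
    for tr in sorted(tracks, key=lambda t: t.id):
        for f in tr.frames:
            x, y = tr.positions[f]
            dx, dy = tr.velocities.get(f, (np.nan, np.nan))
            clump = tr.clump_membership.get(f)
            records.append(
                {
                    "track_id": tr.id,
                    "frame": f,
                    "x": x,
                    "y": y,
                    "dx": dx,
                    "dy": dy,
                    "clump_key": (
                        "-".join(str(i) for i in clump) if clump else ""
                    ),
                }
            )
    return pd.DataFrame(
        records,
        columns=["track_id", "frame", "x", "y", "dx", "dy", "clump_key"],
    )
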