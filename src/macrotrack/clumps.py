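"""Clump detection and evolving clump codes.

A *clump* is a green-channel connected component that contains the nuclei of
two or more tracked cells: the microtubule halos have merged while the
nuclei remain separate.  Membership is decided by the nucleus centroid
falling inside the green region (an area-overlap mode is available).  Each
membership set is named by a base-1000 *clump code*: member track ids are
concatenated in descending order, three decimal digits per id — tracks 2 and
1 form clump 2001, tracks 5, 3, 2, 1 form 5003002001.  A maximal contiguous
run of frames with constant membership is a :class:`ClumpInstance`; any
change of membership closes the current instance and opens a new one, and
the same pair meeting again later yields a fresh instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClumpObservation",
    "ClumpInstance",
    "encode_clump_code",
    "decode_clump_code",
    "find_clumps_in_frame",
    "build_clump_timeline",
    "annotate_tracks",
    "clump_table",
]


def encode_clump_code(member_track_ids) -> int:
    """Base-1000 clump code of a membership set.

    Ids are sorted descending and concatenated three decimal digits at a
    time, so ``{2, 1} -> 2001`` and ``{5, 3, 2, 1} -> 5003002001``.  The
    encoding only exists for ids below 1000; larger ids must use the tuple
    representation directly.
    """
    ids = sorted(set(int(i) for i in member_track_ids), reverse=True)
    if len(ids) < 2:
        raise ValueError("a clump has at least two member tracks")
    code = 0
    for r in ids:
        if not 1 <= r <= 999:
            raise ValueError(
                f"track id {r} outside [1, 999]: the numeric clump code is "
                "undefined; use the ordered id tuple instead"
            )
        code = code * 1000 + r
    return code


def decode_clump_code(code: int) -> set[int]:
    """Inverse of :func:`encode_clump_code`.

    Valid codes split into base-1000 digit groups that are strictly
    descending (all in [1, 999]); anything else raises ``ValueError``.
    """
    code = int(code)
    if code <= 0:
        raise ValueError("clump codes are positive integers")
    groups = []
    while code:
        groups.append(code % 1000)
        code //= 1000
    # groups run from the least significant id upward: strictly increasing
    if len(groups) < 2:
        raise ValueError("a clump code has at least two id groups")
    for lo, hi in zip(groups, groups[1:]):
        if not 1 <= lo < hi:
            raise ValueError("clump code id groups must be strictly descending")
    if groups[-1] < 1:
        raise ValueError("clump code id groups must lie in [1, 999]")
    return set(groups)


def members_key(member_track_ids) -> tuple[int, ...]:
    """Canonical (descending) tuple naming a membership set."""
    return tuple(sorted(set(int(i) for i in member_track_ids), reverse=True))


@dataclass(frozen=True)
class ClumpObservation:
    """One green region holding >= 2 nuclei, in one frame."""

    frame: int
    members: frozenset
    green_region_id: int

    @property
    def code(self) -> int:
        return encode_clump_code(self.members)


@dataclass(frozen=True)
class ClumpInstance:
    """Maximal contiguous run of frames with one fixed clump membership."""

    members: frozenset
    tk0: int  # first contact frame
    tkC: int  # last contact frame

    def __post_init__(self):
        if self.tk0 > self.tkC:
            raise ValueError("tk0 must not exceed tkC")
        if len(self.members) < 2:
            raise ValueError("a clump has at least two member tracks")

    @property
    def code(self) -> int:
        return encode_clump_code(self.members)

    @property
    def n_frames(self) -> int:
        """Inclusive frame count of the contact run (tkC - tk0 + 1)."""
        return self.tkC - self.tk0 + 1


def find_clumps_in_frame(
    seg,
    track_positions: dict,
    membership: str = "centroid",
    min_overlap_fraction: float = 0.5,
    tracks: dict | None = None,
) -> list[ClumpObservation]:
    """Group tracks by the green region their nucleus falls in.

    ``track_positions`` maps track id to the ``(x, y)`` position at
    ``seg.frame_index``.  With ``membership='centroid'`` (default) a track
    belongs to the green region under its nucleus centroid; a position on
    background simply belongs to no clump.  With ``membership='area'`` a
    track belongs to the green region covering at least
    ``min_overlap_fraction`` of its red region's pixels (requires the
    matching red label under the centroid).
    """
    green = seg.green_labels
    rows, cols = green.shape
    by_region: dict[int, set[int]] = {}
    for tid, (x, y) in track_positions.items():
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < rows and 0 <= c < cols):
            continue
        if membership == "centroid":
            label = int(green[r, c])
        elif membership == "area":
            red_label = int(seg.red_labels[r, c])
            if red_label == 0:
                continue
            pixels = green[seg.red_labels == red_label]
            counts = np.bincount(pixels)
            label = int(np.argmax(counts))
            if label == 0 or counts[label] < min_overlap_fraction * pixels.size:
                continue
        else:
            raise ValueError("membership must be 'centroid' or 'area'")
        if label > 0:
            by_region.setdefault(label, set()).add(int(tid))
    return [
        ClumpObservation(
            frame=seg.frame_index,
            members=frozenset(members),
            green_region_id=region,
        )
        for region, members in sorted(by_region.items())
        if len(members) >= 2
    ]


def build_clump_timeline(observations, bridge_gap: int = 0) -> list[ClumpInstance]:
    """Split per-frame observations into maximal constant-membership runs.

    ``bridge_gap=1`` merges runs of identical membership separated by a
    single missing frame (off by default: no smoothing is assumed).
    """
    frames_by_members: dict[frozenset, list[int]] = {}
    for obs in observations:
        frames_by_members.setdefault(obs.members, []).append(obs.frame)
    instances = []
    for members, frames in frames_by_members.items():
        frames = sorted(set(frames))
        start = prev = frames[0]
        for f in frames[1:]:
            if f - prev > 1 + bridge_gap:
                instances.append(
                    ClumpInstance(members=members, tk0=start, tkC=prev)
                )
                start = f
            prev = f
        instances.append(ClumpInstance(members=members, tk0=start, tkC=prev))
    instances.sort(key=lambda inst: (inst.tk0, members_key(inst.members)))
    return instances


def annotate_tracks(tracks, observations) -> None:
    """Record per-frame clump membership (as a descending id tuple) on tracks."""
    by_id = {tr.id: tr for tr in tracks}
    for obs in observations:
        key = members_key(obs.members)
        for tid in obs.members:
            tr = by_id.get(tid)
            if tr is not None:
                tr.clump_membership[obs.frame] = key


def clump_table(instances) -> pd.DataFrame:
    """Tabulate instances: code, member_ids, tk0, tkC, n_frames."""
    records = []
    for inst in instances:
        key = members_key(inst.members)
        try:
            code = str(inst.code)
        except ValueError:  # ids >= 1000 have no numeric code
            code = "-".join(str(i) for i in key)
        records.append(
            {
                "code": code,
                "member_ids": "-".join(str(i) for i in key),
                "tk0": inst.tk0,
                "tkC": inst.tkC,
                "n_frames": inst.n_frames,
            }
        )
    return pd.DataFrame(
        records, columns=["code", "member_ids", "tk0", "tkC", "n_frames"]
    )
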