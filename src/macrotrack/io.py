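"""Stack I/O, pipeline configuration, and the end-to-end driver.

The driver chains segmentation, tracking, clump detection and interaction
selection over one movie and writes the result tables.  All CSVs are
0-based in frame indices, stated in a '#' comment on the first line of each
file; the plain-text summary presents frame numbers 1-based for reading
alongside image viewers.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .clumps import (
    annotate_tracks,
    build_clump_timeline,
    clump_table,
    find_clumps_in_frame,
)
from .interactions import (
    AnalysisConfig,
    interactions_to_dataframe,
    select_interactions,
)
from .segmentation import SegmentationConfig, segment_frame
from .stack import DEFAULT_CHANNEL_MAP, FrameStack
from .synthgen import (
    ContactEvent,
    Scenario,
    render_stack,
    simulate_ground_truth,
    write_ground_truth,
)
from .tracking import KeyholeParams, keyhole_link, tracks_to_dataframe

__all__ = [
    "read_stack",
    "write_stack",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "write_csv",
]

logger = logging.getLogger("macrotrack")

_FRAME_COMMENT = "# frame indices are 0-based (internal convention)"


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as multi-page TIFF, one RGB page per frame."""
    tifffile.imwrite(str(path), stack.frames, photometric="rgb")


def read_stack(
    path,
    channel_map: dict | None = None,
    frame_interval: float = 10.0,
    pixel_size: float = 0.21,
) -> FrameStack:
    """Read a multi-page TIFF into a :class:`FrameStack`.

    Pages must share dimensions; a mismatching page raises an error naming
    it.  ``channel_map`` assigns channel roles (default red=0, green=1).
    """
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.pages
        if len(pages) == 0:
            raise ValueError(f"{path}: empty TIFF")
        shapes = [p.shape for p in pages]
        for i, shape in enumerate(shapes[1:], start=1):
            if shape != shapes[0]:
                raise ValueError(
                    f"{path}: page {i} has dimensions {shape}, "
                    f"expected {shapes[0]}"
                )
        frames = np.stack([p.asarray() for p in pages])
    if frames.ndim == 3:  # grayscale pages: add a channel axis
        frames = frames[..., None]
    return FrameStack(
        frames=frames,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        channel_map=dict(channel_map or DEFAULT_CHANNEL_MAP),
    )


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a table with the frame-convention comment as the first line."""
    with open(path, "w") as fh:
        fh.write(_FRAME_COMMENT + "\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class PipelineConfig:
    """Everything needed to run one movie end to end.

    Exactly one of ``input_path`` (a TIFF stack on disk) or ``scenario``
    (a synthetic movie to generate) must be provided.
    """

    output_dir: str
    input_path: str | None = None
    scenario: Scenario | None = None
    dataset_id: str = "dataset01"
    group: str = "control"
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    keyhole: KeyholeParams = field(default_factory=KeyholeParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    bridge_gap: int = 0
    clump_membership: str = "centroid"
    frame_interval: float = 10.0
    pixel_size: float = 0.21
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError(
                "provide exactly one of input_path or scenario"
            )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data.get("scenario") is not None:
            sc = dict(data["scenario"])
            sc["frame_shape"] = tuple(sc.get("frame_shape", (512, 672)))
            sc["contact_events"] = tuple(
                ContactEvent(**e) if isinstance(e, dict) else ContactEvent(*e)
                for e in sc.get("contact_events", ())
            )
            data["scenario"] = Scenario(**sc)
        if data.get("segmentation") is not None:
            data["segmentation"] = SegmentationConfig(**data["segmentation"])
        if data.get("keyhole") is not None:
            data["keyhole"] = KeyholeParams(**data["keyhole"])
        if data.get("analysis") is not None:
            a = dict(data["analysis"])
            if "s_range" in a:
                a["s_range"] = tuple(a["s_range"])
            data["analysis"] = AnalysisConfig(**a)
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory outputs of one pipeline run."""

    stack: FrameStack
    segmented: list
    tracks: list
    observations: list
    instances: list
    interactions: list
    tables: dict[str, pd.DataFrame]
    output_dir: Path
    stage_counts: dict[str, int]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Segment, track, detect clumps, select interactions, write tables.

    Deterministic under a fixed config (the only randomness is the
    scenario seed).  Writes tracks.csv, clumps.csv, interactions.csv,
    summary.txt and the resolved configuration into ``output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")

    if config.scenario is not None:
        logger.info("simulating scenario with %d cells", config.scenario.n_cells)
        truth = simulate_ground_truth(config.scenario)
        stack = render_stack(truth, config.scenario)
        stack.frame_interval = config.frame_interval
        stack.pixel_size = config.pixel_size
        write_ground_truth(truth, out / "ground_truth.csv")
    else:
        stack = read_stack(
            config.input_path,
            channel_map=config.channel_map,
            frame_interval=config.frame_interval,
            pixel_size=config.pixel_size,
        )
    logger.info("stack: %d frames of %s", stack.n_frames, stack.frame_shape)

    seg_cfg = config.segmentation
    # map channel roles onto the stack's channel order
    seg_cfg.red_channel = stack.channel_map.get("red", seg_cfg.red_channel)
    seg_cfg.green_channel = stack.channel_map.get(
        "green", seg_cfg.green_channel
    )
    segmented = [
        segment_frame(stack.frame(t), seg_cfg, frame_index=t)
        for t in range(stack.n_frames)
    ]
    n_red = sum(s.n_red_regions for s in segmented)
    n_green = sum(s.n_green_regions for s in segmented)
    logger.info("segmentation: %d red regions, %d green regions", n_red, n_green)

    detections = [
        [(x, y) for (_id, x, y) in s.red_centroids] for s in segmented
    ]
    tracks = keyhole_link(detections, config.keyhole)
    logger.info("tracking: %d tracks", len(tracks))

    observations = []
    by_id = {tr.id: tr for tr in tracks}
    for s in segmented:
        positions = {
            tid: tr.positions[s.frame_index]
            for tid, tr in by_id.items()
            if s.frame_index in tr.positions
        }
        observations.extend(
            find_clumps_in_frame(
                s, positions, membership=config.clump_membership
            )
        )
    annotate_tracks(tracks, observations)
    instances = build_clump_timeline(observations, bridge_gap=config.bridge_gap)
    logger.info(
        "clumps: %d observations, %d instances", len(observations), len(instances)
    )

    interactions = select_interactions(
        instances,
        tracks,
        config.analysis,
        dataset_id=config.dataset_id,
        group=config.group,
    )
    logger.info("interactions: %d selected", len(interactions))

    tables = {
        "tracks": tracks_to_dataframe(tracks),
        "clumps": clump_table(instances),
        "interactions": interactions_to_dataframe(
            interactions, frame_interval=config.frame_interval
        ),
    }
    for name, df in tables.items():
        write_csv(df, out / f"{name}.csv")

    stage_counts = {
        "frames": stack.n_frames,
        "red_regions": n_red,
        "green_regions": n_green,
        "tracks": len(tracks),
        "clump_observations": len(observations),
        "clump_instances": len(instances),
        "interactions": len(interactions),
    }
    _write_summary(out / "summary.txt", config, stage_counts, interactions)
    return PipelineResult(
        stack=stack,
        segmented=segmented,
        tracks=tracks,
        observations=observations,
        instances=instances,
        interactions=interactions,
        tables=tables,
        output_dir=out,
        stage_counts=stage_counts,
    )


def _write_summary(path, config, stage_counts, interactions) -> None:
    lines = [
        f"dataset: {config.dataset_id} (group: {config.group})",
        "stage counts:",
    ]
    lines += [f"  {k}: {v}" for k, v in stage_counts.items()]
    lines.append("interactions (frames 1-based in this report):")
    for it in interactions:
        inst = it.instance
        cells = ", ".join(
            f"T{c.track_id}"
            + (
                f" theta={np.degrees(c.theta):+.1f} deg"
                if c.theta is not None
                else " theta=undefined"
            )
            for c in it.cells
        )
        lines.append(
            f"  clump {inst.code}: frames {inst.tk0 + 1}-{inst.tkC + 1}, "
            f"TC={it.tc} frames ({it.tc_seconds(config.frame_interval):.0f} s); "
            f"{cells}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
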