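"""Per-frame segmentation: Otsu-derived hysteresis thresholding.

Each channel is binarised with a two-level hysteresis rule: connected
components of pixels at or above the *low* level are kept only if they
contain at least one pixel at or above the *high* level.  The high level is
the Otsu between-class-variance maximizer of the channel histogram; the low
level is a configurable fraction of it (a two-threshold, three-class Otsu
mode is available as an alternative way of deriving both levels from one
criterion).  Components below a minimum area are discarded, the rest are
labelled, and nucleus (red-channel) centroids provide the detections that
the tracker links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "OtsuResult",
    "SegmentationConfig",
    "SegmentedFrame",
    "otsu_level",
    "hysteresis_mask",
    "segment_frame",
    "region_centroids",
]

_STRUCTURES = {
    4: ndi.generate_binary_structure(2, 1),
    8: ndi.generate_binary_structure(2, 2),
}


class OtsuResult(NamedTuple):
    """Otsu threshold plus a flag for degenerate (single-valued) input."""

    level: int
    degenerate: bool


def otsu_level(histogram) -> OtsuResult:
    """Between-class-variance maximizing threshold of an intensity histogram.

    The returned level ``L`` splits intensities into background ``< L`` and
    foreground ``>= L``; among ties the lowest maximizing level is returned.
    A histogram with all mass in a single bin is degenerate: that intensity
    is returned with ``degenerate=True``.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 1:
        raise ValueError("histogram must be a 1-D array of counts")
    if np.any(h < 0):
        raise ValueError("histogram counts must be nonnegative")
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram must have positive total mass")
    nonzero = np.flatnonzero(h)
    if nonzero.size == 1:
        return OtsuResult(int(nonzero[0]), True)

    bins = np.arange(h.size, dtype=float)
    w0 = np.cumsum(h)  # mass of bins <= i
    m0 = np.cumsum(h * bins)  # first moment of bins <= i
    # cut at level L = i + 1: background bins <= i, foreground bins > i
    w0_, m0_ = w0[:-1], m0[:-1]
    w1_ = total - w0_
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0_ / w0_
        mu1 = (m0[-1] - m0_) / w1_
        sigma_b = w0_ * w1_ * (mu0 - mu1) ** 2
    sigma_b = np.where((w0_ > 0) & (w1_ > 0), sigma_b, 0.0)
    best = int(np.argmax(sigma_b)) + 1  # argmax takes the first (lowest) tie
    return OtsuResult(best, False)


def hysteresis_mask(channel, low: float, high: float,
                    connectivity: int = 8) -> np.ndarray:
    """Two-level hysteresis threshold.

    Returns the union of connected components of ``channel >= low`` that
    contain at least one pixel ``>= high``.
    """
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    channel = np.asarray(channel)
    labels, n = ndi.label(channel >= low, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.zeros(channel.shape, dtype=bool)
    seeds = np.unique(labels[channel >= high])
    seeds = seeds[seeds > 0]
    return np.isin(labels, seeds)


def region_centroids(label_image) -> list[tuple[int, float, float]]:
    """Centroid of every nonzero label as ``(region_id, x, y)``.

    Centroids are the plain means of member pixel coordinates, with
    ``x`` = column and ``y`` = row (0-based, pixel centres at integers).
    """
    label_image = np.asarray(label_image)
    ids = np.unique(label_image)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    centres = ndi.center_of_mass(
        np.ones(label_image.shape), label_image, ids
    )
    return [
        (int(i), float(col), float(row))
        for i, (row, col) in zip(ids, centres)
    ]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the per-frame segmentation."""

    low_fraction: float = 0.5  # low level = low_fraction * high level
    min_area: int = 20  # pixels; components below are discarded
    connectivity: int = 8  # 4 or 8
    otsu_mode: str = "two_class"  # or "three_class"
    red_channel: int = 0
    green_channel: int = 1

    def __post_init__(self):
        if not 0 < self.low_fraction <= 1:
            raise ValueError("low_fraction must be in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.otsu_mode not in ("two_class", "three_class"):
            raise ValueError("otsu_mode must be 'two_class' or 'three_class'")


@dataclass
class SegmentedFrame:
    """Labelled regions of one frame, plus nucleus centroids."""

    red_labels: np.ndarray
    green_labels: np.ndarray
    red_centroids: list = field(default_factory=list)
    frame_index: int = 0

    @property
    def n_red_regions(self) -> int:
        return int(self.red_labels.max())

    @property
    def n_green_regions(self) -> int:
        return int(self.green_labels.max())


def _channel_levels(channel: np.ndarray, config: SegmentationConfig):
    """Derive (low, high) hysteresis levels from the channel histogram."""
    hist = np.bincount(
        np.clip(channel, 0, 255).astype(np.uint8).ravel(), minlength=256
    )
    if config.otsu_mode == "three_class":
        from skimage.filters import threshold_multiotsu

        try:
            t1, t2 = threshold_multiotsu(
                hist=(hist, np.arange(256)), classes=3
            )
        except ValueError:  # fewer distinct values than classes
            return None
        # multiotsu thresholds bound classes as intensity > t; shift by one
        # level to match this module's foreground = intensity >= level rule
        return float(t1) + 1.0, float(t2) + 1.0
    res = otsu_level(hist)
    if res.degenerate:
        return None
    high = float(res.level)
    return config.low_fraction * high, high


def _segment_channel(channel: np.ndarray,
                     config: SegmentationConfig) -> np.ndarray:
    levels = _channel_levels(channel, config)
    if levels is None:  # flat channel: nothing to segment
        return np.zeros(channel.shape, dtype=np.int32)
    low, high = levels
    mask = hysteresis_mask(channel, low, high, config.connectivity)
    structure = _STRUCTURES[config.connectivity]
    labels, n = ndi.label(mask, structure=structure)
    if n and config.min_area > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < config.min_area)
        mask &= ~np.isin(labels, small[small > 0])
        labels, n = ndi.label(mask, structure=structure)
    return labels.astype(np.int32)


def segment_frame(
    frame: np.ndarray,
    config: SegmentationConfig | None = None,
    frame_index: int = 0,
) -> SegmentedFrame:
    """Segment the red and green channels of one frame.

    ``frame`` is a ``(rows, cols, channels)`` array; channel roles come from
    the config.  An empty segmentation (blank frame) is a valid result, not
    an error.
    """
    config = config or SegmentationConfig()
    frame = np.asarray(frame)
    if frame.ndim != 3:
        raise ValueError("frame must be (rows, cols, channels)")
    red = _segment_channel(frame[..., config.red_channel], config)
    green = _segment_channel(frame[..., config.green_channel], config)
    return SegmentedFrame(
        red_labels=red,
        green_labels=green,
        red_centroids=region_centroids(red),
        frame_index=frame_index,
    )
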