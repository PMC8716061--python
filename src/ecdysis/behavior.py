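"""Quantification of pupal ecdysis behavior from video.

Each frame is segmented into a single pupa mask (grayscale conversion,
low threshold, hole filling, Gaussian smoothing, re-threshold, small-blob
removal), the body midline is taken per anteroposterior row as the mean of
the left- and rightmost foreground pixels, and the midlines are stacked
into a time-space diagram (kymograph): lateral midline position as a
function of AP row (vertical, anterior at the top) and time (horizontal).
The time series of the diagram's midsection row carries the signature of
the motor programs — descending stripes for peristalsis, large midsection
excursions for swinging, length changes with a quiet midline for
stretch-compression — and its cycle structure yields the behavioral
period: the span of the largest run of full cycles divided by the cycle
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

__all__ = [
    "SegmentConfig",
    "segment_frame",
    "MidlineFrame",
    "midline",
    "TimeSpaceDiagram",
    "timespace",
    "cycle_period",
    "auto_cycles",
]


@dataclass(frozen=True)
class SegmentConfig:
    """Segmentation thresholds; min_area can be an absolute pixel count or a
    fraction of the frame's foreground (for videos at other resolutions)."""

    thresh1: float = 0.1
    gauss_sigma: float = 3.0
    thresh2: float = 0.5
    min_area: int = 10000
    min_area_frac: float | None = None


def segment_frame(frame: np.ndarray, cfg: SegmentConfig = SegmentConfig()) -> np.ndarray:
    """Binary pupa mask from an RGB or grayscale frame with [0,1] intensities.

    Steps: grayscale = channel mean; binarize at ``thresh1``; fill interior
    holes (4-connected background); Gaussian blur (sigma in pixels);
    re-binarize at ``thresh2`` (preserves the border position instead of
    dilating or eroding it); drop 8-connected components smaller than the
    area floor.  Raises if no component survives.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    gray = frame.mean(axis=-1) if frame.ndim == 3 else frame
    if gray.ndim != 2:
        raise ValueError("frame must be 2-D grayscale or 3-D RGB")
    mask = gray >= cfg.thresh1
    # 1-connectivity structure: holes are background regions not 4-connected
    # to the border
    mask = ndimage.binary_fill_holes(mask, structure=ndimage.generate_binary_structure(2, 1))
    blurred = ndimage.gaussian_filter(mask.astype(float), sigma=cfg.gauss_sigma)
    mask = blurred >= cfg.thresh2
    if cfg.min_area_frac is not None:
        floor = int(cfg.min_area_frac * max(int(mask.sum()), 1))
    else:
        floor = cfg.min_area
    # drop components with fewer than `floor` pixels (max_size is inclusive)
    mask = remove_small_objects(mask, max_size=max(floor - 1, 0), connectivity=2)
    if not mask.any():
        raise ValueError("no component survives the area filter")
    return mask


@dataclass
class MidlineFrame:
    """Per-AP-row lateral midline position for one frame (NaN where the
    pupa is absent)."""

    lr: np.ndarray  # px, length = image height
    ap_rows: np.ndarray
    frame_index: int = 0
    frame_time: float = 0.0


def midline(mask: np.ndarray, frame_index: int = 0, frame_time: float = 0.0) -> MidlineFrame:
    """Midline of a pupa mask: (leftmost + rightmost)/2 per AP row."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no midline")
    h, w = mask.shape
    lr = np.full(h, np.nan)
    has = mask.any(axis=1)
    left = mask.argmax(axis=1)
    right = w - 1 - mask[:, ::-1].argmax(axis=1)
    lr[has] = (left[has] + right[has]) / 2.0
    return MidlineFrame(lr=lr, ap_rows=np.arange(h), frame_index=frame_index,
                        frame_time=frame_time)


@dataclass
class TimeSpaceDiagram:
    """Kymograph of lateral midline position: AP row x frame, anterior at
    row 0."""

    lr: np.ndarray  # (n_rows, n_frames), NaN where the pupa is absent
    times: np.ndarray  # s
    midsection_row: int

    @property
    def midsection(self) -> np.ndarray:
        """Lateral position of the midsection row over time."""
        return self.lr[self.midsection_row]


def timespace(frames: Sequence[MidlineFrame]) -> TimeSpaceDiagram:
    """Stack per-frame midlines into a time-space diagram.

    The midsection row is the midpoint of the median body extent across
    frames (the frame-to-frame length changes of the stretch-compression
    pattern make a per-frame midpoint jumpy).  Frames in which the pupa was
    not found contribute NaN columns.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    n_rows = len(frames[0].lr)
    lr = np.column_stack([f.lr for f in frames])
    times = np.asarray([f.frame_time for f in frames], dtype=float)
    tops, bottoms = [], []
    for f in frames:
        idx = np.flatnonzero(np.isfinite(f.lr))
        if idx.size:
            tops.append(idx[0])
            bottoms.append(idx[-1])
    if not tops:
        raise ValueError("pupa absent from every frame")
    row = int(round((np.median(tops) + np.median(bottoms)) / 2.0))
    return TimeSpaceDiagram(lr=lr, times=times, midsection_row=min(row, n_rows - 1))


def cycle_period(t_start: float, t_end: float, n_cycles: int) -> float:
    """Behavioral period: duration of the largest span of full cycles
    divided by the number of cycles."""
    if t_end <= t_start:
        raise ValueError("t_end must be after t_start")
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    return (t_end - t_start) / n_cycles


def auto_cycles(
    midsection: np.ndarray,
    dt: float,
    smooth_window: float = 10.0,
) -> np.ndarray:
    """Candidate cycle boundaries: upward mean-crossings of the smoothed
    midsection series (an aid for placing the cycle markers, which the
    period metric itself leaves to the analyst).

    Returns boundary times in seconds relative to the first sample.
    """
    x = np.asarray(midsection, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 4:
        raise ValueError("midsection series too short")
    xi = np.interp(np.arange(len(x)), np.flatnonzero(ok), x[ok])
    k = max(1, int(round(smooth_window / dt)))
    pad = k // 2
    sm = np.convolve(np.pad(xi, pad, mode="reflect"), np.full(k, 1.0 / k), mode="same")
    sm = sm[pad : pad + len(xi)]
    centered = sm - np.mean(sm)
    up = np.flatnonzero((centered[1:] > 0) & (centered[:-1] <= 0)) + 1
    if len(up) < 2:
        raise ValueError("fewer than two mean crossings: no cycles to mark")
    return up * dt
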