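"""Signal conditioning for calcium fluorescence traces.

The raw fluorescence f(t) of each neuron drifts slowly as the tissue
settles, so every trace is first detrended by a two-point line through the
minima of the first and last edge windows, then min-max normalized to
[0, 1].  Activity onset is read off a box-smoothed copy of the normalized
trace as the first post-discard instant exceeding half the maximum.
Motoneuronal signals are side-averaged and combined into a single
right-minus-left difference signal, which cancels common-mode fluorescence
and doubles the oscillation amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MN_REGION, Experiment, Trace, check_common_grid

__all__ = [
    "DetrendResult",
    "detrend",
    "normalize",
    "preprocess_trace",
    "detect_onset",
    "side_average",
    "mn_difference",
]


@dataclass
class DetrendResult:
    """Detrended trace g(t) = f(t) - m*t with the line parameters kept."""

    trace: Trace
    slope: float
    t0: float
    t1: float
    edge_window: float


def detrend(trace: Trace, edge_window: float = 250.0) -> DetrendResult:
    """Remove the two-point linear trend anchored at the edge-window minima.

    t0 is the time of the minimum over the first ``edge_window`` seconds, t1
    over the last; the line through (t0, f(t0)) and (t1, f(t1)) with slope
    m = (f(t1)-f(t0))/(t1-t0) is subtracted as g(t) = f(t) - m*t.  Argmin
    ties break to the earliest sample.
    """
    if trace.span <= 2 * edge_window:
        raise ValueError(
            f"trace span {trace.span} s too short for edge windows of {edge_window} s"
        )
    t, v = trace.t, trace.v
    first = t <= t[0] + edge_window
    last = t >= t[-1] - edge_window
    i0 = int(np.argmin(v[first]))
    i1 = int(np.argmin(v[last])) + int(np.flatnonzero(last)[0])
    t0, t1 = float(t[i0]), float(t[i1])
    if t1 == t0:
        raise ValueError("degenerate edge windows: t0 == t1")
    m = float((v[i1] - v[i0]) / (t1 - t0))
    g = v - m * t
    return DetrendResult(
        trace=trace.with_values(g), slope=m, t0=t0, t1=t1, edge_window=edge_window
    )


def normalize(trace: Trace) -> Trace:
    """Map a trace affinely onto [0, 1]: h = (g - gmin) / (gmax - gmin)."""
    v = trace.v
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmax <= vmin:
        raise ValueError("cannot normalize a constant trace")
    return trace.with_values((v - vmin) / (vmax - vmin))


def preprocess_trace(trace: Trace, edge_window: float = 250.0) -> Trace:
    """Detrend then normalize: the standard conditioning applied before any
    frequency or coupling analysis."""
    return normalize(detrend(trace, edge_window=edge_window).trace)


def detect_onset(
    trace: Trace,
    smooth_window: float = 10.0,
    discard: float = 100.0,
    frac: float = 0.5,
) -> float | None:
    """Time of activity onset, or None if activity never starts.

    The trace is convolved with a centered rectangular kernel of duration
    ``smooth_window`` and unit area (reflect padding at the edges); onset is
    the earliest time after the ``discard`` window at which the smoothed
    series exceeds ``frac`` times the maximum of the original (post-discard)
    series.  The first 100 s are discarded because some neurons fluoresce
    transiently right after the start of the recording.
    """
    if not trace.is_uniform:
        raise ValueError("detect_onset requires a uniform grid")
    if smooth_window < trace.dt:
        raise ValueError("smooth_window must be at least one sample interval")
    v = trace.v
    k = max(1, int(round(smooth_window / trace.dt)))
    kernel = np.full(k, 1.0 / k)
    pad = k // 2
    padded = np.pad(v, pad_width=pad, mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="same")[pad : pad + len(v)]
    keep = trace.t > trace.t[0] + discard
    if not np.any(keep):
        return None
    threshold = frac * float(np.max(v[keep]))
    above = keep & (smoothed > threshold)
    if not np.any(above):
        return None
    return float(trace.t[np.flatnonzero(above)[0]])


def side_average(experiment: Experiment, side: str) -> Trace:
    """Pointwise mean of the motoneuron-region traces on one side."""
    traces = experiment.select(kind=MN_REGION, side=side)
    if not traces:
        raise ValueError(f"no motoneuron traces on side {side!r}")
    grid = traces[0].t
    for tr in traces[1:]:
        check_common_grid(traces[0], tr)
    mean = np.mean([tr.v for tr in traces], axis=0)
    return Trace(id=traces[0].id, t=grid, v=mean, dt=traces[0].dt)


def mn_difference(left: Trace, right: Trace) -> Trace:
    """Right-minus-left motoneuronal difference signal.

    Any common-mode component (shared noise, shared drift) cancels exactly;
    for antiphase oscillations the amplitude doubles.
    """
    check_common_grid(left, right)
    return right.with_values(right.v - left.v)
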