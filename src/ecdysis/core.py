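"""Domain types and trace I/O.

The package works on fluorescence time series recorded from identified
neurons (or neuron regions) of the abdominal CNS during fictive ecdysis.
Every series is carried as a :class:`Trace` — values on a time grid plus a
:class:`NeuronID` saying which cell it came from — and a recording session
is an :class:`Experiment`: a set of traces sharing one uniform grid, with
time zero at the ETH stimulation.

Traces are stored as delimited text (one time column, one column per ROI)
with a YAML sidecar mapping ROI names to neuron identities, so that a whole
experiment round-trips through :func:`write_traces` / :func:`read_traces`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CCAP_ALPHA",
    "CCAP_BETA",
    "MN_REGION",
    "NeuronID",
    "Trace",
    "Experiment",
    "read_traces",
    "write_traces",
    "resample_uniform",
    "save_results",
    "load_results",
]

CCAP_ALPHA = "ccap_alpha"
CCAP_BETA = "ccap_beta"
MN_REGION = "mn_region"

_KINDS = (CCAP_ALPHA, CCAP_BETA, MN_REGION)
_SIDES = ("L", "R")

#: default uniform sampling interval, seconds (midpoint of the 2-3 s frame
#: interval of the calcium recordings)
DEFAULT_DT = 2.5


@dataclass(frozen=True)
class NeuronID:
    """Identity of a recorded neuron or motoneuronal region.

    CCAP neurons carry an abdominal segment number (AN1-AN4); motoneuronal
    regions are side-averaged signals and carry no segment.
    """

    kind: str
    side: str
    segment: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {_KINDS}")
        if self.side not in _SIDES:
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.kind == MN_REGION:
            if self.segment is not None:
                raise ValueError("motoneuron regions carry no segment number")
        else:
            if self.segment is None:
                raise ValueError("CCAP neurons require a segment number (1-4)")
            if not 1 <= int(self.segment) <= 4:
                raise ValueError(f"segment must be in 1..4, got {self.segment}")

    @property
    def is_ccap(self) -> bool:
        return self.kind in (CCAP_ALPHA, CCAP_BETA)

    def __str__(self) -> str:
        if self.kind == MN_REGION:
            return f"MN-{self.side}"
        sub = "a" if self.kind == CCAP_ALPHA else "b"
        return f"{self.side}-AN{self.segment}-{sub}"

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "side": self.side}
        if self.segment is not None:
            d["segment"] = int(self.segment)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NeuronID":
        return cls(kind=d["kind"], side=d["side"], segment=d.get("segment"))


_UNIFORM_ATOL = 1e-9


@dataclass
class Trace:
    """One fluorescence time series on a strictly increasing time grid.

    ``dt`` is the nominal sampling interval; the grid is *uniform* when every
    consecutive difference equals ``dt`` to within 1e-9 s (required by the
    wavelet machinery; use :func:`resample_uniform` to enforce it).
    """

    id: NeuronID
    t: np.ndarray
    v: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.v.ndim != 1:
            raise ValueError("t and v must be 1-D arrays")
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have the same length")
        if len(self.t) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def is_uniform(self) -> bool:
        return bool(np.max(np.abs(np.diff(self.t) - self.dt)) < _UNIFORM_ATOL)

    def with_values(self, v: np.ndarray) -> "Trace":
        """Copy of this trace with new values on the same grid."""
        return replace(self, v=np.asarray(v, dtype=float))


@dataclass
class Experiment:
    """A set of traces from one recording, times relative to ETH stimulation."""

    traces: list[Trace]
    t0_eth: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("an experiment needs at least one trace")

    def select(self, kind: str | None = None, side: str | None = None) -> list[Trace]:
        out = self.traces
        if kind is not None:
            out = [tr for tr in out if tr.id.kind == kind]
        if side is not None:
            out = [tr for tr in out if tr.id.side == side]
        return list(out)

    @property
    def ccap_alpha(self) -> list[Trace]:
        return self.select(kind=CCAP_ALPHA)

    @property
    def mn_regions(self) -> list[Trace]:
        return self.select(kind=MN_REGION)

    def common_grid(self) -> np.ndarray:
        t = self.traces[0].t
        for tr in self.traces[1:]:
            if len(tr.t) != len(t) or np.max(np.abs(tr.t - t)) > _UNIFORM_ATOL:
                raise ValueError("traces are not on a common time grid")
        return t


def check_common_grid(a: Trace, b: Trace) -> None:
    if len(a.t) != len(b.t) or np.max(np.abs(a.t - b.t)) > _UNIFORM_ATOL:
        raise ValueError("traces are not on a common time grid")


# ---------------------------------------------------------------------------
# I/O


def _load_metadata(metadata: Mapping[str, NeuronID] | str | Path) -> dict[str, NeuronID]:
    if isinstance(metadata, (str, Path)):
        with open(metadata) as fh:
            raw = yaml.safe_load(fh)
        return {name: NeuronID.from_dict(d) for name, d in raw.items()}
    return dict(metadata)


def read_traces(
    path: str | Path,
    metadata: Mapping[str, NeuronID] | str | Path,
    time_column: str = "t",
    t0_eth: float = 0.0,
    label: str = "",
) -> Experiment:
    """Read an experiment from a delimited-text file (comma or tab).

    The file must contain a time column (seconds) and one value column per
    ROI; ``metadata`` maps each ROI column name to a :class:`NeuronID`
    (either directly or via a YAML sidecar file). Rows containing NaN are
    rejected, as is any non-monotone time column.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if time_column not in df.columns:
        raise ValueError(f"missing time column {time_column!r} in {path}")
    if df.isna().any().any():
        raise ValueError(f"{path} contains NaN entries")
    t = df[time_column].to_numpy(dtype=float)
    if len(t) < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("time column must be strictly increasing")
    value_cols = [c for c in df.columns if c != time_column]
    if not value_cols:
        raise ValueError("no value columns found")
    meta = _load_metadata(metadata)
    missing = [c for c in value_cols if c not in meta]
    if missing:
        raise ValueError(f"columns without metadata mapping: {missing}")
    dt = float(np.median(np.diff(t)))
    traces = [
        Trace(id=meta[c], t=t, v=df[c].to_numpy(dtype=float), dt=dt) for c in value_cols
    ]
    return Experiment(traces=traces, t0_eth=t0_eth, label=label)


def write_traces(
    experiment: Experiment,
    path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str = ",",
) -> None:
    """Write an experiment as delimited text plus a YAML metadata sidecar.

    Inverse of :func:`read_traces` (lossless to float formatting, which uses
    17 significant digits).
    """
    t = experiment.common_grid()
    data = {"t": t}
    meta: dict[str, dict] = {}
    for tr in experiment.traces:
        name = str(tr.id)
        data[name] = tr.v
        meta[name] = tr.id.to_dict()
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".meta.yaml")
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def resample_uniform(trace: Trace, dt: float = DEFAULT_DT) -> Trace:
    """Linear interpolation of a trace onto a uniform grid of step ``dt``.

    The grid starts at the first original sample and never extrapolates past
    the last one. Imaging runs at one frame every 2-3 s, so the canonical
    internal step is 2.5 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if trace.span < 2 * dt:
        raise ValueError(f"dt={dt} too large for trace spanning {trace.span} s")
    n = int(np.floor(trace.span / dt + _UNIFORM_ATOL)) + 1
    t_new = trace.t[0] + dt * np.arange(n)
    v_new = np.interp(t_new, trace.t, trace.v)
    return Trace(id=trace.id, t=t_new, v=v_new, dt=float(dt))


def save_results(obj: dict, path: str | Path) -> None:
    """Write an analysis result (fits, periods, correlations) as JSON."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, NeuronID):
            return o.to_dict()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def load_results(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
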