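"""Pairwise coordination statistics between neurons.

Three families of measures are implemented:

* CCAP-CCAP coordination — Pearson correlations between neuron pairs in
  the time domain, or in the time-frequency domain using either the band
  amplitude |W| (oscillation envelope, phase-blind) or the band real part
  Re W (envelope and phase together).  Pairs are grouped anatomically as
  contralateral (C: same segment, opposite sides), ipsilateral (I1-I3 by
  segmental distance 0-2, same side) and other (O: opposite sides,
  different segments).
* Left-right motoneuron coordination — sliding-window Pearson correlation
  and the amplitude-weighted circular mean of the instantaneous wavelet
  phase difference at the dominant oscillatory period.
* CCAP-motoneuron coupling — correlation of each CCAP trace with the
  instantaneous oscillation amplitude of the motoneuronal difference
  signal, tested one-tailed (Mann-Whitney U) against a null of
  cross-experiment correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import CCAP_ALPHA, Experiment, NeuronID, Trace, check_common_grid
from . import preprocess, timefreq

__all__ = [
    "PairClass",
    "classify_pair",
    "pearson",
    "group_correlations",
    "sliding_correlation",
    "PhaseDiffResult",
    "phase_difference",
    "mn_amplitude",
    "ccap_mn_correlations",
    "cross_experiment_null",
    "mw_u_test",
]


@dataclass(frozen=True)
class PairClass:
    """Anatomical category of a CCAP neuron pair."""

    category: Literal["contralateral", "ipsilateral", "other"]
    seg_distance: int | None = None  # ipsilateral subgroups only

    @property
    def group(self) -> str:
        """Short label: C, I1..I4 or O.

        I1 holds same-side same-segment pairs (the alpha and beta neuron of
        one hemisegment), I2/I3 pairs one/two segments apart; I4 extends the
        scheme to the three-segments-apart pairs that exist between AN1 and
        AN4.
        """
        if self.category == "contralateral":
            return "C"
        if self.category == "other":
            return "O"
        return f"I{self.seg_distance + 1}"


def classify_pair(a: NeuronID, b: NeuronID) -> PairClass:
    """Anatomical classification of a CCAP pair.

    Same-side pairs are ipsilateral regardless of subtype, so the two CCAP
    neurons of one hemisegment (alpha and beta) fall in I1.
    """
    if a == b:
        raise ValueError("cannot classify a neuron against itself")
    if not (a.is_ccap and b.is_ccap):
        raise ValueError("pair classification applies to CCAP neurons only")
    if a.side == b.side:
        return PairClass("ipsilateral", abs(a.segment - b.segment))
    if a.segment == b.segment:
        return PairClass("contralateral")
    return PairClass("other")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series")
    return float(stats.pearsonr(x, y).statistic)


def _domain_series(
    traces: Sequence[Trace],
    domain: str,
    band: tuple[float, float],
    n_periods: int,
    sigma: float,
) -> list[np.ndarray]:
    if domain == "time":
        return [tr.v for tr in traces]
    # edge (zero-padding) artifacts are not offset-invariant: restrict the
    # band series to the cone interior of the slowest period in the band
    inside = timefreq.coi_interior(traces[0].t, band[1], sigma)
    if not np.any(inside):
        raise ValueError("trace too short for the requested band")
    series = []
    for tr in traces:
        sg = timefreq.cwt_morlet(tr, band[0], band[1], n_periods=n_periods, sigma=sigma)
        idx = sg.band_indices(band)
        if domain == "tf_amplitude":
            series.append(np.mean(np.abs(sg.W[idx]), axis=0)[inside])
        elif domain == "tf_amp_phase":
            series.append(np.mean(np.real(sg.W[idx]), axis=0)[inside])
        else:
            raise ValueError(f"unknown domain {domain!r}")
    return series


def group_correlations(
    experiment: Experiment,
    domain: Literal["time", "tf_amplitude", "tf_amp_phase"] = "time",
    band: tuple[float, float] = timefreq.CCAP_BAND,
    n_periods: int = 64,
    sigma: float = 3.0,
) -> dict[str, list[float]]:
    """Pairwise CCAP correlations grouped anatomically.

    Returns a map from group label (C, I1, I2, I3, O) to the list of
    Pearson r of all pairs in that group, in the requested domain:
    ``time`` correlates the preprocessed traces directly, ``tf_amplitude``
    the band-mean wavelet amplitude (phase-blind envelope), and
    ``tf_amp_phase`` the band-mean real part of the wavelet transform.
    """
    traces = [tr for tr in experiment.traces if tr.id.is_ccap]
    if len(traces) < 2:
        raise ValueError("need at least two CCAP traces")
    series = _domain_series(traces, domain, band, n_periods, sigma)
    out: dict[str, list[float]] = {}
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            cls = classify_pair(traces[i].id, traces[j].id)
            out.setdefault(cls.group, []).append(pearson(series[i], series[j]))
    return out


def sliding_correlation(left: Trace, right: Trace, window: float = 100.0) -> np.ndarray:
    """Pearson r of L vs R within a centered sliding window, per sample.

    Windows in which either side has zero variance yield NaN.  The window
    (default 100 s) is chosen longer than one motoneuron oscillation but
    shorter than an oscillation episode, so r(t) is near -1 while the two
    sides alternate and drifts positive between episodes.
    """
    check_common_grid(left, right)
    k = int(round(window / left.dt))
    if k < 3:
        raise ValueError("window must cover at least 3 samples")
    n = len(left)
    if k > n:
        raise ValueError("window exceeds the trace span")
    half = k // 2
    r = np.full(n, np.nan)
    x, y = left.v, right.v
    for m in range(n):
        lo, hi = max(0, m - half), min(n, m - half + k)
        xs, ys = x[lo:hi], y[lo:hi]
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue
        r[m] = np.corrcoef(xs, ys)[0, 1]
    return r


@dataclass
class PhaseDiffResult:
    """Instantaneous and mean L-R phase difference at one period."""

    times: np.ndarray
    dphi: np.ndarray  # radians, per time (left minus right)
    amplitude: np.ndarray  # mean |W| of the two sides, per time
    angle_deg: float  # circular mean angle, degrees in [0, 360)
    length: float  # mean-vector length (amplitude units)


def phase_difference(
    left: Trace, right: Trace, period: float, sigma: float = 3.0
) -> PhaseDiffResult:
    """Amplitude-weighted circular mean of the L-R wavelet phase difference.

    Both traces are transformed at the single scale of ``period``; each
    instant contributes a vector of angle arg W_L - arg W_R (left-minus-
    right convention) and length (|W_L| + |W_R|)/2, and the reported angle
    is that of the vector mean.  Instants outside the cone of influence are
    excluded.
    """
    check_common_grid(left, right)
    WL = timefreq.cwt_single_scale(left, period, sigma)
    WR = timefreq.cwt_single_scale(right, period, sigma)
    inside = timefreq.coi_interior(left.t, period, sigma)
    if not np.any(inside):
        raise ValueError("trace too short: cone-of-influence interior is empty")
    dphi = np.angle(WL[inside]) - np.angle(WR[inside])
    amp = (np.abs(WL[inside]) + np.abs(WR[inside])) / 2.0
    mv = np.mean(amp * np.exp(1j * dphi))
    if np.abs(mv) == 0:
        raise ValueError("zero mean vector: phase difference undefined")
    return PhaseDiffResult(
        times=left.t[inside],
        dphi=dphi,
        amplitude=amp,
        angle_deg=float(np.degrees(np.angle(mv)) % 360.0),
        length=float(np.abs(mv)),
    )


def mn_amplitude(diff: Trace, period: float, sigma: float = 3.0) -> np.ndarray:
    """Instantaneous oscillation amplitude |W(t)| of the motoneuronal
    difference signal at its primary oscillatory period."""
    return np.abs(timefreq.cwt_single_scale(diff, period, sigma))


def ccap_mn_correlations(
    experiment: Experiment,
    drop_pre_ecdysis: bool = False,
    period: float | None = None,
    null_rs: Sequence[float] | None = None,
    band: tuple[float, float] = timefreq.MN_BAND,
    sigma: float = 3.0,
) -> tuple[list[float], float | None]:
    """Correlation of each alpha-CCAP trace with the motoneuronal
    oscillation amplitude; optionally a one-tailed p-value against a null.

    The motoneuronal amplitude is |W| of the R-L difference signal at its
    dominant period in the 25-50 s band (or at ``period`` if given).  With
    ``drop_pre_ecdysis`` both series are trimmed to start at the earlier of
    the motoneuron onset and the median alpha onset, removing the shared
    silent stretch that would otherwise inflate the correlation.  If
    ``null_rs`` (correlations of CCAP traces against motoneuron amplitude
    from *different* experiments) is supplied, returns the one-tailed
    Mann-Whitney p-value of within > null.
    """
    alphas = experiment.select(kind=CCAP_ALPHA)
    if not alphas:
        raise ValueError("no alpha CCAP traces in experiment")
    left = preprocess.side_average(experiment, "L")
    right = preprocess.side_average(experiment, "R")
    diff = preprocess.mn_difference(left, right)
    if period is None:
        sg = timefreq.cwt_morlet(diff, band[0], band[1], sigma=sigma)
        period = timefreq.dominant_period(timefreq.mean_spectrum(sg))
    amp = mn_amplitude(diff, period, sigma)
    start_idx = 0
    if drop_pre_ecdysis:
        amp_trace = diff.with_values(amp)
        mn_onset = preprocess.detect_onset(preprocess.normalize(amp_trace))
        alpha_onsets = [preprocess.detect_onset(tr) for tr in alphas]
        alpha_onsets = [o for o in alpha_onsets if o is not None]
        candidates = [o for o in (mn_onset, np.median(alpha_onsets) if alpha_onsets else None) if o is not None]
        if not candidates:
            raise ValueError("no detectable onset; cannot trim pre-ecdysis phase")
        start_idx = int(np.searchsorted(diff.t, min(candidates)))
    rs = [pearson(tr.v[start_idx:], amp[start_idx:]) for tr in alphas]
    p = mw_u_test(rs, null_rs) if null_rs is not None else None
    return rs, p


def cross_experiment_null(
    experiments: Sequence[Experiment],
    band: tuple[float, float] = timefreq.MN_BAND,
    sigma: float = 3.0,
) -> list[float]:
    """Null correlations: alpha traces of one experiment against the
    motoneuron amplitude of every *other* experiment, truncated to the
    shorter length."""
    amps = []
    for exp in experiments:
        left = preprocess.side_average(exp, "L")
        right = preprocess.side_average(exp, "R")
        diff = preprocess.mn_difference(left, right)
        sg = timefreq.cwt_morlet(diff, band[0], band[1], sigma=sigma)
        period = timefreq.dominant_period(timefreq.mean_spectrum(sg))
        amps.append(mn_amplitude(diff, period, sigma))
    null = []
    for i, exp in enumerate(experiments):
        for j, amp in enumerate(amps):
            if i == j:
                continue
            for tr in exp.select(kind=CCAP_ALPHA):
                n = min(len(tr.v), len(amp))
                null.append(pearson(tr.v[:n], amp[:n]))
    return null


def mw_u_test(
    within: Sequence[float],
    null: Sequence[float],
    alternative: str = "greater",
) -> float:
    """One-tailed Mann-Whitney U p-value for within-experiment correlations
    exceeding the cross-experiment null."""
    within = np.asarray(within, dtype=float)
    null = np.asarray(null, dtype=float)
    if within.size == 0 or null.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(
        stats.mannwhitneyu(within, null, alternative=alternative, method="auto").pvalue
    )
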