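r"""Continuous wavelet transform with the complex Morlet, scaleograms, and
dominant-period extraction.

The CWT of a trace f is

.. math::

    W(t, s) = \frac{1}{\sqrt{s}} \int f(u)\, \overline{\psi\!\left(\frac{u-t}{s}\right)} du

with the zero-mean complex Morlet of parameter :math:`\sigma` (default 3)

.. math::

    \psi_\sigma(x) = c_\sigma\, \pi^{-1/4} e^{-x^2/2}
        \left(e^{i \sigma x} - \kappa_\sigma\right),

where :math:`\kappa_\sigma = e^{-\sigma^2/2}` makes the wavelet zero-mean
and :math:`c_\sigma = (1 + e^{-\sigma^2} - 2 e^{-\frac{3}{4}\sigma^2})^{-1/2}`
restores unit energy; at :math:`\sigma = 3` these corrections are small but
not negligible (:math:`\kappa \approx 0.011`) and are included exactly.

Scales are labeled by their *Fourier period* — the period of the pure
sinusoid to which a scale-s daughter wavelet responds maximally,

.. math::

    T = \frac{4 \pi s}{\sigma + \sqrt{2 + \sigma^2}},

so the dominant period read off a scaleogram of a clean oscillation is the
oscillation's true period.  At :math:`\sigma = 3` the wavelet carries about
half an oscillation cycle per envelope standard deviation: time resolution
is sharp (the envelope sd is roughly T/2, so oscillation episodes are
localized to within a period), at the price of a relative frequency
resolution of about :math:`1/\sigma`.

The scaleogram is the squared magnitude :math:`X = |W|^2` over a log-spaced
period grid.  Signals are zero-padded by the convolution; a cone-of-
influence mask flags the region within :math:`\sqrt{2} s` (the envelope
e-folding distance) of either edge, and time-averaged spectra are
restricted to the cone interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .core import Trace

__all__ = [
    "Scaleogram",
    "Spectrum",
    "scale_for_period",
    "morlet_kernel",
    "cwt_morlet",
    "cwt_single_scale",
    "mean_spectrum",
    "average_spectra",
    "dominant_period",
    "passes_peak_criterion",
    "CCAP_BAND",
    "MN_BAND",
]

#: analysis band for the slow CCAP rhythm, seconds
CCAP_BAND = (50.0, 200.0)
#: analysis band for the fast motoneuronal rhythm, seconds
MN_BAND = (25.0, 50.0)


class Spectrum(NamedTuple):
    """Time-averaged wavelet power per period."""

    periods: np.ndarray
    power: np.ndarray


@dataclass
class Scaleogram:
    """Complex wavelet coefficients over a (period x time) grid."""

    W: np.ndarray  # complex, shape (n_periods, n_times)
    periods: np.ndarray  # seconds, strictly increasing
    times: np.ndarray  # seconds
    sigma: float
    coi: np.ndarray  # bool, True where inside the cone of influence

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.W) ** 2

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        idx = np.flatnonzero((self.periods >= lo) & (self.periods <= hi))
        if idx.size == 0:
            raise ValueError(f"band {band} outside the period grid")
        return idx


def scale_for_period(period: float, sigma: float = 3.0) -> float:
    """Wavelet scale whose peak sinusoidal response has the given period."""
    return period * (sigma + np.sqrt(2.0 + sigma**2)) / (4.0 * np.pi)


def _coi_efold(period: float | np.ndarray, sigma: float) -> float | np.ndarray:
    """Edge-artifact decay distance for a period: sqrt(2) times the scale."""
    return np.sqrt(2.0) * scale_for_period(period, sigma)


def morlet_kernel(period: float, dt: float, sigma: float = 3.0) -> np.ndarray:
    """Sampled daughter wavelet for one Fourier period, ready for convolution.

    Returned with the 1/sqrt(s) scale normalization and the dt factor of the
    discretized integral folded in; support is truncated at four envelope
    standard deviations.
    """
    s = scale_for_period(period, sigma)
    half = int(np.ceil(4.0 * s / dt))
    x = (np.arange(-half, half + 1) * dt) / s
    kappa = np.exp(-0.5 * sigma**2)
    c = (1.0 + np.exp(-(sigma**2)) - 2.0 * np.exp(-0.75 * sigma**2)) ** -0.5
    psi = c * np.pi**-0.25 * np.exp(-0.5 * x**2) * (np.exp(1j * sigma * x) - kappa)
    psi -= psi.mean()  # exact zero mean on the sampled grid
    return psi / np.sqrt(s) * dt


def _require_uniform(trace: Trace) -> None:
    if not trace.is_uniform:
        raise ValueError("CWT requires a uniform time grid (resample first)")


def cwt_morlet(
    trace: Trace,
    period_min: float,
    period_max: float,
    n_periods: int = 64,
    sigma: float = 3.0,
) -> Scaleogram:
    """Morlet scaleogram of a trace over a log-spaced period grid.

    ``period_min`` must be at least four sampling intervals (shorter periods
    are not resolvable on the imaging grid).
    """
    _require_uniform(trace)
    if period_min < 4 * trace.dt:
        raise ValueError(
            f"period_min={period_min} below the admissible 4*dt={4 * trace.dt}"
        )
    if not period_min < period_max:
        raise ValueError("period_min must be < period_max")
    periods = np.geomspace(period_min, period_max, n_periods)
    n = len(trace)
    W = np.empty((n_periods, n), dtype=complex)
    for i, T in enumerate(periods):
        kernel = morlet_kernel(T, trace.dt, sigma)
        # W(t) = sum_u f(u) conj(psi((u-t)/s)) dt  ==  (f * k)(t), k(x) = conj(psi(-x/s))
        W[i] = fftconvolve(trace.v, np.conj(kernel[::-1]), mode="same")
    rel = trace.t - trace.t[0]
    efold = _coi_efold(periods, sigma)
    coi = (rel[None, :] >= efold[:, None]) & ((rel[-1] - rel)[None, :] >= efold[:, None])
    return Scaleogram(W=W, periods=periods, times=trace.t.copy(), sigma=sigma, coi=coi)


def cwt_single_scale(trace: Trace, period: float, sigma: float = 3.0) -> np.ndarray:
    """Complex wavelet coefficients at one period, on the trace's grid."""
    _require_uniform(trace)
    if period < 4 * trace.dt:
        raise ValueError(f"period {period} below the admissible 4*dt={4 * trace.dt}")
    kernel = morlet_kernel(period, trace.dt, sigma)
    return fftconvolve(trace.v, np.conj(kernel[::-1]), mode="same")


def coi_interior(trace_t: np.ndarray, period: float, sigma: float = 3.0) -> np.ndarray:
    """Boolean mask of times free of edge artifacts at one period."""
    rel = trace_t - trace_t[0]
    efold = _coi_efold(period, sigma)
    return (rel >= efold) & (rel[-1] - rel >= efold)


def mean_spectrum(sg: Scaleogram) -> Spectrum:
    """Time-average of wavelet power per period, cone interior only.

    Periods whose cone interior is empty get NaN power; if no period has any
    interior samples the scaleogram is too short for its grid and an error
    is raised.
    """
    X = sg.power
    counts = sg.coi.sum(axis=1)
    if not np.any(counts > 0):
        raise ValueError("cone-of-influence interior is empty at every period")
    power = np.full(len(sg.periods), np.nan)
    rows = counts > 0
    masked = np.where(sg.coi, X, 0.0)
    power[rows] = masked[rows].sum(axis=1) / counts[rows]
    return Spectrum(periods=sg.periods.copy(), power=power)


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Arithmetic mean of per-trace spectra (all on the same period grid)."""
    if not spectra:
        raise ValueError("no spectra to average")
    periods = spectra[0].periods
    for sp in spectra[1:]:
        if len(sp.periods) != len(periods) or np.max(np.abs(sp.periods - periods)) > 1e-9:
            raise ValueError("spectra are not on a common period grid")
    return Spectrum(periods=periods.copy(), power=np.mean([sp.power for sp in spectra], axis=0))


def dominant_period(spectrum: Spectrum) -> float:
    """Period of the global spectral maximum; ties break to the smaller period."""
    power = spectrum.power
    finite = np.isfinite(power)
    if not np.any(finite) or np.nanmax(power) <= 0:
        raise ValueError("spectrum has no positive power")
    vmax = np.nanmax(power)
    idx = np.flatnonzero(finite & (power == vmax))[0]
    return float(spectrum.periods[idx])


def passes_peak_criterion(spectrum: Spectrum, ratio: float = 0.8) -> bool:
    """Whether the spectral peak at T* is a clear, isolated peak.

    Accepts iff on each side of the interval [T*/2, 2 T*] the spectral
    minimum falls below ``ratio`` times the peak power.  A side that the
    period grid does not reach (or that holds only cone-empty NaN values)
    cannot be evaluated and counts as a rejection — only unambiguous peaks
    survive.
    """
    t_star = dominant_period(spectrum)
    peak = np.nanmax(spectrum.power)
    for side in (spectrum.periods < t_star / 2, spectrum.periods > 2 * t_star):
        vals = spectrum.power[side]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0 or np.min(vals) >= ratio * peak:
            return False
    return True
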