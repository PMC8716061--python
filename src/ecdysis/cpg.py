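r"""Stochastic conductance-based half-center oscillator with CCAP gating.

Two endogenously bursting model cells with fast, non-delayed reciprocal
inhibition; a depolarizing "CCAP" current gated by the oscillation
probability p(t) switches bursting on and off, an Ornstein-Uhlenbeck
current adds stochasticity, and a slow first-order variable f turns each
cell's voltage into a simulated calcium-fluorescence readout.

Per cell i (with partner j), all voltages in volts, conductances in nS,
currents in nA, capacitance in nF, time in seconds:

.. math::

    C \dot V_i = -(I_{Na} + I_K + I_L + I_{Syn} + I_{CCAP} + I_X) \\
    I_{Na} = g_{Na} (V_i - E_{Na}) n_i^3 h_i, \quad
        n_i = s(-150 (V_i + 0.0305)) \\
    I_K = g_K (V_i - E_K) m_i^2, \qquad
    I_L = g_L (V_i - E_L) \\
    I_{Syn} = g_{Syn} (V_i - E_{Syn})\, s(-1000 (V_j + 0.0225)) \\
    I_{CCAP} = g_{CCAP} (V_i - E_{CCAP})\, p(t) \\
    dI_X = -\frac{I_X}{\tau_X} dt + \sigma_X\, dW_t \\
    \dot h_i = (s(500 (V_i + 0.0333)) - h_i)/\tau_{Na} \\
    \dot m_i = (s(-83 (V_i + V_{shift})) - m_i)/\tau_K \\
    \dot f_i = (s(-100 (V_i + 0.04)) - f_i)/\tau_f

with the decreasing sigmoid :math:`s(x) = 1/(1+e^x)`.  Sodium activation n
is instantaneous; m is the slow potassium recovery variable whose time
constant :math:`\tau_K` (tens of seconds) sets the burst period — the
period grows linearly with :math:`\tau_K` — and :math:`\tau_f` sets the
fluorescence decay without feeding back into the voltage dynamics.

Integration is Euler-Maruyama at ``dt_sim`` = 0.05 ms (the fastest
timescale, C/g_Na = 2.5 ms, is then resolved by 50 steps); the OU noise
uses its exact Gaussian discretization, with :math:`\sigma_X` the
volatility of the Wiener term (units nA s^-1/2, stationary sd
:math:`\sigma_X \sqrt{\tau_X/2}`).  p(t) is zero-order-held from the
observation grid, and fluorescence is reported decimated to ``dt_obs``
(default 2.5 s) to mirror the imaging frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import MN_REGION, NeuronID, Trace
from . import timefreq

__all__ = [
    "CPGParams",
    "SimResult",
    "sigmoid",
    "simulate",
    "burst_period",
    "tune_tau_K",
    "ExpDecayFit",
    "fit_exp_decay",
    "estimate_tau_f",
]


@dataclass(frozen=True)
class CPGParams:
    """Full parameter set; the defaults are the hand-fitted values shared by
    all experiments, with tau_K and tau_f the two per-experiment knobs."""

    C: float = 0.5  # nF
    tau_Na: float = 0.055  # s
    g_Na: float = 200.0  # nS
    g_K: float = 45.0  # nS
    g_L: float = 10.0  # nS
    g_Syn: float = 0.5  # nS
    g_CCAP: float = 1.0  # nS
    E_Na: float = 0.045  # V
    E_K: float = -0.07  # V
    E_L: float = -0.046  # V
    E_Syn: float = -0.0625  # V
    E_CCAP: float = 0.0  # V
    V_shift: float = 0.022  # V
    tau_X: float = 0.001  # s
    sigma_X: float = 0.03  # nA s^-1/2 (Wiener-term volatility)
    tau_K: float = 55.2  # s, sets burst period
    tau_f: float = 3.2  # s, fluorescence decay

    def __post_init__(self):
        for name in ("C", "tau_Na", "tau_X", "tau_K", "tau_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_Na", "g_K", "g_L", "g_Syn", "g_CCAP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimResult:
    """Voltage on a fine grid plus fluorescence decimated to the imaging grid."""

    t_v: np.ndarray  # seconds, fine recording grid
    V: np.ndarray  # volts, shape (len(t_v), 2)
    I_X: np.ndarray  # nA, shape (len(t_v), 2)
    t_obs: np.ndarray  # seconds, observation (imaging) grid
    f: np.ndarray  # fluorescence a.u., shape (len(t_obs), 2)
    seed: int
    dt_sim: float
    params: CPGParams

    def fluorescence_traces(self) -> tuple[Trace, Trace]:
        """The two simulated fluorescence series as motoneuron-region traces."""
        dt = float(self.t_obs[1] - self.t_obs[0])
        return (
            Trace(NeuronID(MN_REGION, "L"), self.t_obs, self.f[:, 0], dt),
            Trace(NeuronID(MN_REGION, "R"), self.t_obs, self.f[:, 1], dt),
        )


def sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    """Decreasing logistic s(x) = 1/(1+exp(x)), overflow-safe."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    ex = np.exp(-x[pos])
    out[pos] = ex / (1.0 + ex)
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    if out.ndim == 0:
        return float(out)
    return out


@njit(cache=True)
def _sig(x):
    if x > 0.0:
        e = np.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=True)
def _integrate(
    p_arr, n_steps, dt, obs_every, v_every, seed, use_noise,
    C, tau_Na, g_Na, g_K, g_L, g_Syn, g_C,
    E_Na, E_K, E_L, E_Syn, E_C, V_shift, tau_X, sigma_X, tau_K, tau_f,
):
    np.random.seed(seed)
    V = np.empty(2)
    h = np.empty(2)
    m = np.empty(2)
    f = np.empty(2)
    IX = np.zeros(2)
    V[0] = E_L + 0.001  # antisymmetric kick selects a locked state deterministically
    V[1] = E_L - 0.001
    for i in range(2):
        h[i] = _sig(500.0 * (V[i] + 0.0333))
        m[i] = _sig(-83.0 * (V[i] + V_shift))
        f[i] = _sig(-100.0 * (V[i] + 0.04))
    # exact OU discretization over one step
    ou_a = np.exp(-dt / tau_X)
    ou_b = sigma_X * np.sqrt(tau_X / 2.0 * (1.0 - ou_a * ou_a))
    n_v = n_steps // v_every
    n_obs = n_steps // obs_every
    Vrec = np.empty((n_v, 2))
    IXrec = np.empty((n_v, 2))
    frec = np.empty((n_obs, 2))
    kv = 0
    ko = 0
    ok = True
    Vn = np.empty(2)
    for step in range(n_steps):
        p = p_arr[min(step // obs_every, len(p_arr) - 1)]
        for i in range(2):
            j = 1 - i
            n_gate = _sig(-150.0 * (V[i] + 0.0305))
            I_Na = g_Na * (V[i] - E_Na) * n_gate * n_gate * n_gate * h[i]
            I_K = g_K * (V[i] - E_K) * m[i] * m[i]
            I_L = g_L * (V[i] - E_L)
            I_Syn = g_Syn * (V[i] - E_Syn) * _sig(-1000.0 * (V[j] + 0.0225))
            I_C = g_C * (V[i] - E_C) * p
            Vn[i] = V[i] + dt * (-(I_Na + I_K + I_L + I_Syn + I_C + IX[i]) / C)
            h[i] += dt * (_sig(500.0 * (V[i] + 0.0333)) - h[i]) / tau_Na
            m[i] += dt * (_sig(-83.0 * (V[i] + V_shift)) - m[i]) / tau_K
            f[i] += dt * (_sig(-100.0 * (V[i] + 0.04)) - f[i]) / tau_f
            if use_noise:
                IX[i] = ou_a * IX[i] + ou_b * np.random.standard_normal()
        V[0] = Vn[0]
        V[1] = Vn[1]
        if (step + 1) % v_every == 0 and kv < n_v:
            Vrec[kv, 0] = V[0]
            Vrec[kv, 1] = V[1]
            IXrec[kv, 0] = IX[0]
            IXrec[kv, 1] = IX[1]
            kv += 1
            if not (np.isfinite(V[0]) and np.isfinite(V[1])):
                ok = False
                break
        if (step + 1) % obs_every == 0 and ko < n_obs:
            frec[ko, 0] = f[0]
            frec[ko, 1] = f[1]
            ko += 1
    return Vrec, IXrec, frec, kv, ko, ok


def simulate(
    params: CPGParams,
    p_of_t: float | np.ndarray,
    duration: float,
    dt_sim: float = 5e-5,
    dt_obs: float = 2.5,
    dt_v: float = 0.01,
    seed: int = 0,
) -> SimResult:
    """Euler-Maruyama integration of the two-cell CPG.

    ``p_of_t`` is either a constant in [0, 1] or a series on the
    observation grid (one value per ``dt_obs``), held constant between
    observation samples.  Identical seeds give bit-identical results.
    """
    if dt_sim > 1e-4:
        raise ValueError("dt_sim must be <= 1e-4 s to resolve the spike dynamics")
    n_steps = int(round(duration / dt_sim))
    obs_every = max(1, int(round(dt_obs / dt_sim)))
    v_every = max(1, int(round(dt_v / dt_sim)))
    n_obs_needed = n_steps // obs_every + 1
    if np.isscalar(p_of_t):
        p_arr = np.full(n_obs_needed, float(p_of_t))
    else:
        p_arr = np.asarray(p_of_t, dtype=float)
        if len(p_arr) < n_obs_needed - 1:
            raise ValueError(
                f"p_of_t has {len(p_arr)} samples but {n_obs_needed - 1} observation "
                "intervals are needed"
            )
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p(t) must lie in [0, 1]")
    use_noise = params.sigma_X > 0
    Vrec, IXrec, frec, kv, ko, ok = _integrate(
        p_arr, n_steps, dt_sim, obs_every, v_every, int(seed), use_noise,
        params.C, params.tau_Na, params.g_Na, params.g_K, params.g_L,
        params.g_Syn, params.g_CCAP, params.E_Na, params.E_K, params.E_L,
        params.E_Syn, params.E_CCAP, params.V_shift, params.tau_X,
        params.sigma_X, params.tau_K, params.tau_f,
    )
    if not ok:
        raise FloatingPointError(
            f"integration diverged near t={kv * dt_v:.3f} s; "
            "reduce dt_sim or check parameters"
        )
    t_v = dt_v * np.arange(1, kv + 1)
    t_obs = dt_obs * np.arange(1, ko + 1)
    return SimResult(
        t_v=t_v, V=Vrec[:kv], I_X=IXrec[:kv], t_obs=t_obs, f=frec[:ko],
        seed=int(seed), dt_sim=dt_sim, params=params,
    )


def burst_period(
    sim: SimResult,
    band: tuple[float, float] | None = None,
    n_periods: int = 96,
    sigma: float = 3.0,
) -> float:
    """Dominant period of the fluorescence difference f1 - f2.

    Measured on the observation grid with the same wavelet machinery used
    for the experimental motoneuron signals.  Raises if the simulation did
    not oscillate (e.g. p = 0 quiescence).
    """
    left, right = sim.fluorescence_traces()
    d = right.v - left.v
    # quiescence check on the second half (initial-condition transients decay)
    if len(d) < 8 or float(np.ptp(d[len(d) // 2 :])) < 0.02:
        raise ValueError("no oscillation detected in the simulated fluorescence")
    dt = float(sim.t_obs[1] - sim.t_obs[0])
    span = float(sim.t_obs[-1] - sim.t_obs[0])
    if band is None:
        band = (4 * dt, span / 3.0)
    diff = Trace(left.id, sim.t_obs, d, dt)
    sg = timefreq.cwt_morlet(diff, band[0], band[1], n_periods=n_periods, sigma=sigma)
    return timefreq.dominant_period(timefreq.mean_spectrum(sg))


def tune_tau_K(
    target_period: float,
    params: CPGParams | None = None,
    tol: float = 0.1,
    bounds: tuple[float, float] = (20.0, 200.0),
    dt_sim: float = 5e-5,
    max_iter: int = 12,
) -> float:
    """Find tau_K whose noiseless p=1 burst period matches a target.

    Bisection over ``bounds`` (the period is monotone, close to linear, in
    tau_K); returns the first tau_K with relative period error <= ``tol``.
    """
    if params is None:
        params = CPGParams()
    duration = max(400.0, 10.0 * target_period)

    def period_at(tau_K: float) -> float:
        p = CPGParams(**{**params.__dict__, "tau_K": tau_K, "sigma_X": 0.0})
        return burst_period(simulate(p, 1.0, duration, dt_sim=dt_sim, seed=0))

    lo, hi = bounds
    p_lo, p_hi = period_at(lo), period_at(hi)
    if not p_lo <= target_period <= p_hi:
        raise ValueError(
            f"target period {target_period} s outside achievable range "
            f"[{p_lo:.1f}, {p_hi:.1f}] s for tau_K in {bounds}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = period_at(mid)
        if abs(p_mid - target_period) / target_period <= tol:
            return mid
        if p_mid < target_period:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class ExpDecayFit(NamedTuple):
    a: float
    b: float
    tau: float


def fit_exp_decay(segment: np.ndarray, dt: float, window: float = 15.0) -> ExpDecayFit:
    """Least-squares fit of a*exp(-t/tau) + b over the first 15 s of a segment."""
    segment = np.asarray(segment, dtype=float)
    if (len(segment) - 1) * dt < window:
        raise ValueError(f"segment must span at least {window} s")
    n = int(round(window / dt)) + 1
    seg = segment[:n]
    t = dt * np.arange(n)
    if np.ptp(seg) < 1e-12:
        raise ValueError("near-constant segment: tau is unidentifiable")
    a0 = seg[0] - seg[-1]
    b0 = seg[-1]
    tau0 = window / 3.0
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau, b: a * np.exp(-tt / tau) + b,
            t, seg, p0=[a0, tau0, b0],
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - curve_fit non-convergence
        raise ValueError(f"exponential fit did not converge: {exc}") from exc
    a, tau, b = popt
    return ExpDecayFit(a=float(a), b=float(b), tau=float(tau))


def estimate_tau_f(trace: Trace, quality: float = 5.0, window: float = 15.0) -> float:
    """Mean fluorescence decay constant from post-peak segments.

    Peaks are detected on the trace, gated by signal-to-noise ratio
    (prominence over a robust noise estimate from first differences), and
    an exponential is fitted to the 15 s following each qualifying peak;
    the estimate is the mean tau over qualifying segments.
    """
    v = trace.v
    dt = trace.dt
    noise_sd = float(np.median(np.abs(np.diff(v)))) / (0.6745 * np.sqrt(2.0))
    min_prom = max(0.1 * float(np.ptp(v)), 5 * noise_sd if noise_sd > 0 else 0.0)
    peaks, props = find_peaks(v, prominence=min_prom, distance=max(1, int(window / dt)))
    taus = []
    n_win = int(round(window / dt)) + 1
    for pk, prom in zip(peaks, props["prominences"]):
        if noise_sd > 0 and prom / noise_sd < quality:
            continue
        if pk + n_win > len(v):
            continue
        seg = v[pk : pk + n_win]
        try:
            fit = fit_exp_decay(seg, dt, window=window)
        except ValueError:
            continue
        pred = fit.a * np.exp(-dt * np.arange(len(seg)) / fit.tau) + fit.b
        ss_res = float(np.sum((seg - pred) ** 2))
        ss_tot = float(np.sum((seg - np.mean(seg)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if fit.a > 0 and 0 < fit.tau < 10 * window and r2 >= 0.8:
            taus.append(fit.tau)
    if not taus:
        raise ValueError("no qualifying decay segments found")
    return float(np.mean(taus))
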