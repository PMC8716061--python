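"""Synthetic experiments and pupal videos with recorded ground truth.

The generators emulate the statistical structure of the fictive-ecdysis
recordings so that every downstream stage can be exercised and validated
without the (undeposited) raw data:

* ``gen_ccap`` — eight alpha-CCAP traces that switch on around 19 min
  after the ETH stimulus and burst slowly (period band 50-200 s).  All
  neurons share one burst envelope, delayed per neuron by its onset, but
  carry independent uniformly random phases: amplitudes are correlated
  across the population while phases are not, which is the empirical
  signature the coupling analysis must reproduce.  Carriers are half-wave
  rectified (calcium fluorescence cannot go below baseline), and beta
  traces, when requested, are first-order low-pass filtered copies of
  their alpha partners.
* ``gen_mn`` — two motoneuron-region traces oscillating near 33 s in
  antiphase, gated by a logistic function of the CCAP traces; the gate
  state, weights and target phase difference are recorded as ground truth.
* ``gen_pupa_video`` — a bending/peristalsing capsule "pupa" rendered as
  an image sequence with its true centerline saved per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    CCAP_ALPHA,
    CCAP_BETA,
    MN_REGION,
    Experiment,
    NeuronID,
    Trace,
)

__all__ = ["SynthParams", "GroundTruth", "gen_ccap", "gen_mn", "gen_experiment",
           "gen_pupa_video", "PupaVideo"]

#: default burst envelope: Gaussian bumps (center after onset, width, height)
#: sketching an ecdysis episode followed by two waning post-ecdysis episodes
DEFAULT_ENVELOPE = ((350.0, 140.0, 1.0), (1150.0, 180.0, 0.75), (1950.0, 220.0, 0.55))

#: default gating weights: heterogeneous, with half the population silent —
#: the redundancy regime in which only a subset of CCAP neurons is needed
DEFAULT_W_TRUE = (9.0, 0.0, 7.0, 0.0, 6.0, 5.0, 0.0, 4.0)


@dataclass
class SynthParams:
    """Generation parameters; the defaults are the study conditions.

    Onset statistics (mean 1150 s, sd 60 s after the stimulus) and the two
    period bands (CCAP carrier 166 s, motoneuron 33 s) match the recorded
    populations; ``burst_envelope`` centers are expressed relative to each
    neuron's onset.
    """

    n_ccap: int = 8
    onset_mean: float = 1150.0  # s after ETH
    onset_sd: float = 60.0  # s
    ccap_period: float = 166.0  # s
    mn_period: float = 33.0  # s
    burst_envelope: tuple = DEFAULT_ENVELOPE
    onset_seg_frac: float = 0.7  # fraction of onset variance from the segment gradient
    exp_onset_sd: float = 110.0  # s, across-experiment onset shift
    exp_env_jitter: float = 0.25  # relative across-experiment envelope jitter
    beta_true: float = -2.5
    w_true: tuple = DEFAULT_W_TRUE
    phase_jitter_sd: float = 10.0  # degrees, L-R antiphase jitter
    common_phase: bool = False  # share one carrier phase across neurons
    noise_sd: float = 0.05  # a.u.
    mn_amp: float = 1.0  # a.u., motoneuron oscillation amplitude
    duration: float = 3600.0  # s
    dt: float = 2.5  # s
    include_beta: bool = False  # also generate beta (low-passed) partners
    beta_tau: float = 50.0  # s, beta-neuron low-pass time constant
    seed: int = 0

    def __post_init__(self):
        if self.n_ccap < 1:
            raise ValueError("n_ccap must be >= 1")
        if len(self.w_true) != self.n_ccap:
            raise ValueError("w_true must have length n_ccap")
        if any(w < 0 for w in self.w_true):
            raise ValueError("true weights must be nonnegative")
        if not 0 < self.mn_period < self.ccap_period:
            raise ValueError("need 0 < mn_period < ccap_period")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    onsets: np.ndarray | None = None  # s, per CCAP neuron
    phases: np.ndarray | None = None  # rad, per CCAP neuron
    beta_true: float | None = None
    w_true: np.ndarray | None = None
    y_true: np.ndarray | None = None  # {0,1} gate state on the trace grid
    p_true: np.ndarray | None = None
    phase_diff_true: float | None = None  # degrees
    tau_decay_true: float | None = None  # s (beta-neuron filter)


def _alpha_ids(n: int) -> list[NeuronID]:
    ids = []
    for k in range(n):
        side = "L" if k % 2 == 0 else "R"
        segment = k // 2 % 4 + 1
        ids.append(NeuronID(CCAP_ALPHA, side, segment))
    return ids


def _envelope(t: np.ndarray, onset: float, bumps: Sequence[tuple]) -> np.ndarray:
    env = np.zeros_like(t)
    for center, width, height in bumps:
        env += height * np.exp(-0.5 * ((t - onset - center) / width) ** 2)
    return env


def gen_ccap(params: SynthParams) -> tuple[list[Trace], GroundTruth]:
    """Generate the alpha (and optionally beta) CCAP population.

    Each alpha trace is the shared burst envelope, delayed by the neuron's
    onset, times a half-wave-rectified sinusoid with an independent random
    phase, plus Gaussian noise, clipped at zero.  Beta traces are obtained
    from the alphas by a first-order low-pass filter (time constant
    ``beta_tau``), mirroring their smoothed appearance in recordings.
    """
    rng = np.random.default_rng(params.seed)
    t = params.dt * np.arange(int(round(params.duration / params.dt)))
    ids = _alpha_ids(params.n_ccap)
    # Each preparation has its own timeline: the whole experiment shifts by
    # an across-experiment onset offset and the episode envelope is jittered,
    # so different seeds are temporally misaligned (as real experiments are).
    exp_shift = params.exp_onset_sd * rng.standard_normal()
    bumps = []
    for center, width, height in params.burst_envelope:
        j = params.exp_env_jitter
        bumps.append((
            center * (1.0 + j * rng.standard_normal()),
            width * np.exp(0.5 * j * rng.standard_normal()),
            height * np.exp(0.5 * j * rng.standard_normal()),
        ))
    # Onsets stagger along the AP axis (activity recruits segment by
    # segment) plus per-neuron jitter; the split keeps the population onset
    # sd at onset_sd while giving same-segment pairs closer onsets than
    # segmentally distant ones.
    segs = np.array([i.segment for i in ids], dtype=float)
    seg_var = np.var(segs) if np.var(segs) > 0 else 1.0
    gradient = params.onset_sd * np.sqrt(params.onset_seg_frac / seg_var)
    within_sd = params.onset_sd * np.sqrt(1.0 - params.onset_seg_frac)
    onsets = (
        params.onset_mean
        + exp_shift
        + gradient * (segs - segs.mean())
        + within_sd * rng.standard_normal(params.n_ccap)
    )
    phases = rng.uniform(0, 2 * np.pi, params.n_ccap)
    if params.common_phase:
        phases = np.full(params.n_ccap, phases[0])
    traces = []
    for k in range(params.n_ccap):
        carrier = np.sin(2 * np.pi * t / params.ccap_period + phases[k])
        v = _envelope(t, onsets[k], bumps) * np.maximum(carrier, 0.0)
        v = v + params.noise_sd * rng.standard_normal(len(t))
        traces.append(Trace(ids[k], t, np.clip(v, 0.0, None), params.dt))
    if params.include_beta:
        alpha = np.exp(-params.dt / params.beta_tau)
        for k in range(params.n_ccap):
            src = traces[k]
            filt = np.empty_like(src.v)
            filt[0] = src.v[0]
            for n in range(1, len(filt)):
                filt[n] = alpha * filt[n - 1] + (1 - alpha) * src.v[n]
            bid = NeuronID(CCAP_BETA, src.id.side, src.id.segment)
            traces.append(Trace(bid, t, filt, params.dt))
    gt = GroundTruth(
        onsets=onsets,
        phases=phases,
        tau_decay_true=params.beta_tau if params.include_beta else None,
    )
    return traces, gt


def gen_mn(
    ccap_traces: Sequence[Trace], params: SynthParams
) -> tuple[Trace, Trace, GroundTruth]:
    """Generate the gated left/right motoneuron-region traces.

    The oscillation gate is p(t) = logistic(beta_true + sum w_i f_i(t))
    over the *alpha* traces; wherever p >= 0.5 both regions oscillate at
    the motoneuron period, the right side shifted by 180 degrees plus a
    random jitter drawn once per experiment.
    """
    alphas = [tr for tr in ccap_traces if tr.id.kind == CCAP_ALPHA]
    if len(alphas) != params.n_ccap:
        raise ValueError("ccap_traces must contain n_ccap alpha traces")
    t = alphas[0].t
    for tr in alphas[1:]:
        if len(tr.t) != len(t) or np.max(np.abs(tr.t - t)) > 1e-9:
            raise ValueError("CCAP traces are not on a common grid")
    rng = np.random.default_rng(params.seed + 1)
    F = np.column_stack([tr.v for tr in alphas])
    z = params.beta_true + F @ np.asarray(params.w_true, dtype=float)
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    y = (p >= 0.5).astype(int)
    jitter = np.radians(params.phase_jitter_sd) * rng.standard_normal()
    phase_L = 2 * np.pi * t / params.mn_period
    phase_R = phase_L + np.pi + jitter
    osc = lambda ph: params.mn_amp * (0.5 + 0.5 * np.sin(ph))
    vL = y * osc(phase_L) + params.noise_sd * rng.standard_normal(len(t))
    vR = y * osc(phase_R) + params.noise_sd * rng.standard_normal(len(t))
    left = Trace(NeuronID(MN_REGION, "L"), t, np.clip(vL, 0.0, None), params.dt)
    right = Trace(NeuronID(MN_REGION, "R"), t, np.clip(vR, 0.0, None), params.dt)
    gt = GroundTruth(
        beta_true=params.beta_true,
        w_true=np.asarray(params.w_true, dtype=float),
        y_true=y,
        p_true=p,
        phase_diff_true=float((180.0 + np.degrees(jitter)) % 360.0),
    )
    return left, right, gt


def gen_experiment(params: SynthParams) -> tuple[Experiment, GroundTruth]:
    """Full synthetic experiment: CCAP population plus gated motoneurons."""
    ccap, gt_c = gen_ccap(params)
    left, right, gt_m = gen_mn(ccap, params)
    gt_m.onsets = gt_c.onsets
    gt_m.phases = gt_c.phases
    gt_m.tau_decay_true = gt_c.tau_decay_true
    exp = Experiment(traces=list(ccap) + [left, right], label=f"synthetic seed={params.seed}")
    return exp, gt_m


# ---------------------------------------------------------------------------
# synthetic pupa video


@dataclass
class PupaVideo:
    """Rendered frames plus the scripted ground-truth centerline."""

    frames: np.ndarray  # float in [0,1], shape (n_frames, H, W)
    times: np.ndarray  # s
    centerline: np.ndarray  # px, shape (n_frames, H); NaN outside the body
    fps: float

    def write_frames(self, directory: str | Path) -> list[Path]:
        """Save frames as numbered 8-bit PNGs."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, frame in enumerate(self.frames):
            path = directory / f"frame_{i:05d}.png"
            iio.imwrite(path, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
            paths.append(path)
        return paths


_PHASES = ("peristalsis", "swinging", "stretch_compression")


def gen_pupa_video(
    script: Sequence[tuple[str, float, float]],
    size: tuple[int, int] = (160, 120),
    fps: float = 1.0,
    amplitude: float = 15.0,
    body_radius: float = 18.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> PupaVideo:
    """Render a synthetic pupa executing a scripted motor sequence.

    ``script`` is a list of (phase, duration_s, period_s) entries with
    phase one of ``peristalsis`` (a lateral bump traveling anterior to
    posterior), ``swinging`` (the whole midsection bending side to side
    sinusoidally) and ``stretch_compression`` (body length modulation with
    a near-straight midline).  The body is a filled white capsule on black,
    anterior at row 0, with light Gaussian pixel noise; the true centerline
    is recorded for every frame.
    """
    if not script:
        raise ValueError("script must contain at least one phase")
    for phase, dur, per in script:
        if phase not in _PHASES:
            raise ValueError(f"unknown phase {phase!r}; expected one of {_PHASES}")
        if dur <= 0 or per <= 0:
            raise ValueError("durations and periods must be positive")
    H, W = size
    rng = np.random.default_rng(seed)
    r0, r1 = int(0.12 * H), int(0.88 * H)  # body extent along the AP axis
    length0 = r1 - r0
    cx = W / 2.0
    rows = np.arange(H)
    cols = np.arange(W)

    frame_times = []
    t_abs = 0.0
    segments = []
    for phase, dur, per in script:
        n = int(round(dur * fps))
        for k in range(n):
            segments.append((phase, t_abs, per))
            frame_times.append(t_abs)
            t_abs += 1.0 / fps
    # phase-local time for motion formulas
    local = []
    start = {}
    for phase, tf, per in segments:
        key = (phase, per)
        start.setdefault(key, tf)
        local.append(tf - start[key])

    frames = np.zeros((len(segments), H, W))
    centerline = np.full((len(segments), H), np.nan)
    for idx, ((phase, tf, per), tl) in enumerate(zip(segments, local)):
        length = length0
        if phase == "stretch_compression":
            length = length0 * (1.0 - 0.15 * (0.5 + 0.5 * np.sin(2 * np.pi * tl / per)))
        top = r0
        bottom = r0 + length
        inside = (rows >= top) & (rows <= bottom)
        frac = np.zeros(H)
        frac[inside] = (rows[inside] - top) / max(bottom - top, 1)
        offset = np.zeros(H)
        if phase == "swinging":
            bend = np.sin(np.pi * frac)  # maximal at the midsection
            offset = amplitude * np.sin(2 * np.pi * tl / per) * bend
        elif phase == "peristalsis":
            bump_pos = top + (tl / per % 1.0) * (bottom - top)
            offset = amplitude * np.exp(-0.5 * ((rows - bump_pos) / (0.12 * length0)) ** 2)
        center = cx + offset
        # capsule half-width: constant mid-body, circular caps at the ends
        hw = np.zeros(H)
        mid = inside & (rows >= top + body_radius) & (rows <= bottom - body_radius)
        hw[mid] = body_radius
        for cap_center in (top + body_radius, bottom - body_radius):
            capzone = inside & (np.abs(rows - cap_center) <= body_radius) & ~mid
            d = rows[capzone] - cap_center
            hw[capzone] = np.sqrt(np.maximum(body_radius**2 - d**2, 0.0))
        img = (np.abs(cols[None, :] - center[:, None]) <= hw[:, None]) & inside[:, None]
        frame = img.astype(float)
        if noise_sd > 0:
            frame = np.clip(frame + noise_sd * rng.standard_normal(frame.shape), 0, 1)
        frames[idx] = frame
        body = inside & (hw > 0)
        centerline[idx, body] = center[body]
    return PupaVideo(
        frames=frames,
        times=np.asarray(frame_times),
        centerline=centerline,
        fps=fps,
    )
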