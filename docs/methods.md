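# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data tests do and do not establish.

## Signal conditioning

Raw fluorescence f(t) is detrended with a two-point line: t₀ and t₁ are the
times of the minima over the first and last edge window (default 250 s),
m = (f(t₁)−f(t₀))/(t₁−t₀), and g(t) = f(t) − m·t. Normalization maps g
affinely to [0, 1]. Argmin ties break to the earliest sample, so the
operation is deterministic. The trend model deliberately has one degree of
freedom — it compensates slow tissue drift, not photobleaching kinetics.

Onset detection convolves the normalized trace with a **centered**
rectangular kernel (10 s, unit area, reflect padding) and returns the first
time after a 100-s discard window at which the smoothed series exceeds half
the maximum of the post-discard original. A causal kernel would bias onsets
late by half the window; centering was chosen and is configurable. The
maximum is taken over the post-discard portion because early-recording
fluorescence artifacts are precisely what the discard rule exists for.

Motoneuron analysis uses the side-averaged left and right regional signals
and their difference d = R − L, which cancels common-mode fluorescence
exactly and doubles the antiphase oscillation amplitude.

## Wavelet analysis

The CWT uses the zero-mean complex Morlet with σ = 3,

ψ_σ(x) = c_σ π^(−1/4) e^(−x²/2) (e^(iσx) − κ_σ),  κ_σ = e^(−σ²/2),

with the admissibility corrections κ_σ and c_σ kept exactly (κ ≈ 0.011 at
σ = 3). Scales are labeled by their **Fourier period**
T = 4πs/(σ + √(2+σ²)), the period of the sinusoid to which a scale-s
daughter responds maximally, so dominant periods read off a scaleogram are
unbiased for clean oscillations (the tests verify < 2 % on pure sines;
the residual is grid spacing). At σ = 3 the wavelet carries roughly half a
carrier cycle per envelope standard deviation: time resolution ≈ T/2
(oscillation episodes are localized to within one period — essential for
tracking when the motoneuron rhythm switches on and off), frequency
resolution ≈ 1/σ ≈ 33 % (broad spectral peaks; the argmax is still sharp).

A convention note: the textbook scale–period shorthand T ≈ s/σ treats the
σ of e^(iσx) as a frequency in cycles rather than radians; taken literally
it mislabels true periods by 2π and would be inconsistent with both the
period-recovery requirements and the reported rhythm bands. This package
therefore uses the exact Fourier-period mapping above. The sampled kernel
is additionally re-centered to exact zero mean on the discrete grid so
additive offsets contribute nothing away from the edges.

Signals are zero-padded by the convolution; a cone of influence excludes
times within √2·s (the envelope e-folding distance) of either edge, and
time-averaged spectra use only the cone interior. Per-period rows whose
interior is empty carry NaN and are ignored by the dominant-period search;
ties break to the smaller period. The clear-peak rule accepts a spectrum
only if, on each side of [T*/2, 2T*] around the peak T*, the spectral
minimum drops below 80 % of the peak; a side the grid cannot evaluate
counts as a rejection, so the rule must be applied on a grid wide enough
to cover both sides (the examples use 25–600 s for the CCAP band).

## Coupling statistics

CCAP pairs are classed anatomically: contralateral C (same segment,
opposite sides), ipsilateral I1–I3 (same side; same segment, one or two
segments apart — I1 arises for the α/β pair of one hemisegment), and other
O. The eight α neurons also produce same-side pairs three segments apart
(AN1–AN4); these are labeled I4, a natural extension of the scheme.

Time-frequency correlations use the band mean (50–200 s, arithmetic mean
over log-spaced periods) of |W| — the phase-blind envelope — or of Re W,
which retains the phase. Both series are restricted to the cone interior
of the slowest band period, which also makes the correlations exactly
invariant to positive affine rescaling of the traces (edge regions are
not, because zero padding breaks offset invariance there).

The L–R phase difference at a period T is measured at that single scale:
Δφ(t) = arg W_L − arg W_R (left-minus-right convention; only the sign of
reported angles depends on it), each instant weighted by the mean
amplitude (|W_L|+|W_R|)/2, and the reported angle is that of the vector
mean over the cone interior. The sliding L–R correlation uses a centered
100-s window stepped per sample; zero-variance windows yield NaN.

CCAP→motoneuron coupling correlates each α trace with the instantaneous
amplitude |W(t)| of d = R−L at its dominant period. Significance is
assessed with a one-tailed Mann–Whitney U test against a null of
cross-experiment correlations (traces of one experiment against the
amplitude of another, truncated to the common length — truncation rather
than resampling preserves the series' autocorrelation). The standard U
test is used as implemented in scipy; degenerate single-tie comparisons
return the conservative p = 1.

## Logistic gating model

The motoneuronal oscillation state y(t) ∈ {0,1} is obtained by
thresholding the oscillation amplitude at a configurable fraction of its
maximum (default 0.5, mirroring the half-max onset convention; an Otsu
option is provided). The threshold value is the one deliberately exposed
tunable of this stage, and the synthetic tests report sensitivity through
the ground-truth comparison.

The gate p(t) = 1/(1+exp(−β−Σ wᵢfᵢ)) is fitted by maximum likelihood with
wᵢ ≥ 0 (CCAP drive is depolarizing) using box-constrained L-BFGS-B on
(β, w) with the analytic gradient. Five fixed-seed starts guard against
the flat directions created by strongly collinear CCAP columns; the best
likelihood is kept, so fits are deterministic. β is clipped to [−20, 20]
so complete separation and constant-y inputs stay finite (the latter are
flagged `degenerate`). Weights below 10⁻⁶ are reported as exact zeros; a
zero weight marks a neuron redundant given the others, not a neuron
without influence. The single-weight variant shares one w across neurons
(k = 2 parameters) and is compared to the multi-weight variant (k = n+1)
by AIC = 2k − 2 log L.

## Conductance-based CPG

The simulator integrates the two-cell half-center model of the README:
instantaneous Na⁺ activation n³h kinetics with
inactivation time constant τ_Na = 55 ms, a slow K⁺ recovery variable m
(τ_K, tens of seconds — the burst-period dial), leak, fast reciprocal
inhibition gated at −22.5 mV on the partner's voltage, a CCAP current
g_CCAP (V − E_CCAP) p(t), an OU noise current, and an observation-only
fluorescence variable f (τ_f) that does not feed back into V (verified by
test). Voltages are integrated in volts, conductances in nS, currents in
nA, capacitance in nF.

Numerics: Euler–Maruyama at dt = 0.05 ms (≥ 50 steps per fastest
timescale C/g_Na = 2.5 ms; halving dt changes the burst period by < 1 %,
measured on burst-onset intervals). The OU noise uses its exact Gaussian
one-step discretization with σ_X interpreted as the Wiener-term volatility
(units nA·s^(−1/2)), giving stationary sd σ_X√(τ_X/2); the interpretation
is configurable because the published units are ambiguous. Initial
conditions: V = E_L ± 1 mV (an antisymmetric kick that selects a locked
state deterministically when σ_X = 0), gating variables at their
voltage-clamped steady states, I_X = 0. p(t) is zero-order-held from the
2.5-s observation grid; f is reported decimated to that grid to mirror
imaging.

**Phase locking.** With the published parameters the deterministic system
(p ≡ 1, σ_X = 0) locks at ≈ ±80° of burst-onset lag, not 180°: a state
started exactly in antiphase drifts away, and an independent adaptive-step
integration (LSODA, rtol 10⁻⁸) reproduces the same lock, so this is a
property of the equations, not of the integrator. The mechanism is that
the interspike voltage troughs (≈ −34 mV) lie below the synaptic threshold
(−22.5 mV), so inhibition arrives as spike-locked pulses — the regime in
which this half-center family is known to stabilize phase-locked states
other than antiphase. Bursts still alternate strictly (burst duration
≈ 6 s of a 33-s cycle), the period is linear in τ_K (R² > 0.99 over
τ_K ∈ [40, 140] s), p = 0 gives quiescence, and the measured f₁/f₂ phase
difference at the dominant period is ≈ 90°.

τ_K tuning is automated by bisection over [20, 200] s on noiseless p = 1
runs. τ_f is estimated from data by detecting fluorescence peaks, gating
them by SNR (prominence over a robust first-difference noise estimate) and
an R² ≥ 0.8 goodness gate, fitting a·e^(−t/τ)+b over the 15 s after each
peak, and averaging. Round-trip accuracy is within 15 % across the
τ_f ∈ [3.2, 11.2] s range when fluorescence is observed at 1 Hz; at the
2.5-s imaging interval a 3.2-s decay spans barely one sample, so decay
estimation uses the finer observation grid of the simulator. The residual
bias is physical: after a burst the slow K⁺ recovery keeps shifting the
fluorescence baseline, so the tail of a 15-s window bends away from a pure
exponential.

## Behavior pipeline

Frames (intensities in [0, 1]) are converted to grayscale by channel mean,
thresholded at 0.1, hole-filled (4-connected background), blurred with a
Gaussian of σ = 3 px, re-thresholded at 0.5 (which preserves border
positions rather than dilating or eroding), and filtered by discarding
8-connected components below a minimum area (10 000 px at the reference
resolution, also expressible as a fraction of the foreground for other
resolutions). Strict idempotence of the segmentation fails only at convex
corners, where blur+threshold shaves a sub-percent fringe per pass.

The midline is the per-row mean of the left- and rightmost foreground
pixels (rows without foreground are missing); image row 0 is anterior, and
columns index the left-right axis. The time-space diagram stacks midlines
per frame; its midsection row is the midpoint of the **median** body
extent across frames, because stretch-compression changes the body length
frame to frame. The cycle-period metric is deliberately marker-driven —
(t_end − t_start)/n_cycles over the largest span of full cycles — matching
how behavioral recordings are quantified by hand; `auto_cycles` (upward
mean-crossings of the 10-s-smoothed midsection) is an aid for placing the
markers, and its cycle count is the number of detected crossings.

## Synthetic data: what it emulates, and what it does not

`gen_ccap` builds each α trace as a shared envelope of Gaussian burst
episodes — delayed per neuron by its onset — multiplied by a half-wave-
rectified sinusoid (period 166 s) with an independent uniform phase, plus
clipped Gaussian noise. Rectification reflects that the calcium indicator
cannot report below baseline; the shared-envelope/independent-phase
construction directly implements the empirical "co-active but not
phase-locked" structure, so envelope correlations are high while
amplitude+phase correlations collapse. Onsets combine an across-experiment
shift (sd 110 s), a segmental gradient along AN1→AN4 (70 % of the
within-experiment onset variance; activity recruits segment by segment)
and per-neuron jitter, keeping the population onset sd at 60 s around a
1150-s mean; the gradient is what gives same-segment pairs closer onsets
than segmentally distant ones. β traces are first-order low-passed copies
of their α partners (time constant 50 s, a free parameter as no
quantitative filter is established).

`gen_mn` gates a 33-s antiphase pair by p(t) of the true logistic model
over the α traces (defaults β = −2.5, w = (9,0,7,0,6,5,0,4): heterogeneous
with half the population silent — the redundancy regime). The gate
threshold sits just above the noise floor of the summed drive, which makes
the on-state track whole burst episodes; brief dips of the rectified-sine
sum still produce short gate flickers, which is why ground-truth
comparisons of amplitude-derived binary states plateau around 95 %
accuracy rather than 100 %.

What passing these tests shows: the pipeline recovers periods, phases,
envelopes, gate states and decay constants from data with the *statistical
structure* of the recordings, at realistic sampling and noise. What it
does not show: robustness to motion artifacts, indicator nonlinearity and
bleaching beyond a linear trend, cell-to-cell waveform diversity, or real
behavioral segmentation under uneven illumination — none of which the
generator models.

Problem sizes used throughout the tests and the acceptance script: 8 CCAP
neurons, 3600-s experiments at dt = 2.5 s, 600-s CPG runs at dt = 0.05 ms,
and 300-frame videos at 1 fps — small enough to run the whole suite in a
few minutes on one CPU while keeping ≥ 10 cycles of every rhythm analyzed.

## Known limitations

- The binarization threshold of the oscillation amplitude is not an
  established constant; results downstream of `binarize` should be read
  against its documented default (0.5 of maximum).
- The Mann–Whitney null requires several experiments with genuinely
  different timelines; with few or well-aligned experiments the null
  correlations are high and the test loses power (visible in the trimmed
  pre-ecdysis variant on synthetic data).
- The CPG reproduces period, gating, quiescence and alternation, but its
  deterministic left-right lock is ±80°, not the 180° of the recorded
  motoneurons; matching the observed mean phase difference would require
  modifying the published synaptic parameters (e.g. a sub-threshold
  synaptic activation), which this package deliberately does not do.
- `estimate_tau_f` assumes post-peak decays toward a slowly varying
  baseline; for decay constants approaching the sampling interval it needs
  a finer observation grid than the 2.5-s imaging frame time.
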