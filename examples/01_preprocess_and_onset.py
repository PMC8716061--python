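"""Condition a raw calcium trace and find its activity onset.

Generates one synthetic experiment, takes a single alpha-CCAP trace,
detrends and normalizes it, and detects the onset of activity relative to
the ETH stimulus.
"""

import numpy as np

from ecdysis import preprocess, synthetic

params = synthetic.SynthParams(seed=1)
experiment, truth = synthetic.gen_experiment(params)
raw = experiment.ccap_alpha[0]

result = preprocess.detrend(raw)
conditioned = preprocess.normalize(result.trace)
onset = preprocess.detect_onset(conditioned)

print(f"trace {raw.id}: {len(raw)} samples at dt = {raw.dt} s")
print(f"detrend anchors t0 = {result.t0:.0f} s, t1 = {result.t1:.0f} s, "
      f"slope m = {result.slope:.2e} a.u./s")
print(f"normalized range: [{conditioned.v.min():.2f}, {conditioned.v.max():.2f}]")
print(f"detected onset: {onset:.0f} s after stimulation "
      f"(generator onset for this neuron: {truth.onsets[0]:.0f} s)")
# The detected onset marks the half-maximum crossing of the smoothed trace,
# i.e. when the first calcium burst rises, a little after the generative
# onset at which the envelope starts growing from zero.
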