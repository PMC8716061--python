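"""Coordination statistics: pair classes, envelope-versus-phase contrast,
left-right sliding correlation and the mean phase difference.
"""

import numpy as np

from ecdysis import coupling, preprocess, synthetic, timefreq as tf
from ecdysis.core import Experiment

experiment, _ = synthetic.gen_experiment(synthetic.SynthParams(seed=1))
conditioned = Experiment(
    traces=[preprocess.preprocess_trace(tr) for tr in experiment.traces]
)
ccap = Experiment(traces=[tr for tr in conditioned.traces if tr.id.is_ccap])

for domain in ("time", "tf_amplitude", "tf_amp_phase"):
    groups = coupling.group_correlations(ccap, domain)
    med = {g: np.median(rs) for g, rs in sorted(groups.items())}
    print(f"{domain:>13}: " + "  ".join(f"{g}={m:+.2f}" for g, m in med.items()))
# Amplitude (envelope) correlations are high because all neurons share the
# burst envelope; adding the phase (tf_amp_phase) collapses them because
# carrier phases are independent - neurons are co-active but not in step.

left = preprocess.side_average(conditioned, "L")
right = preprocess.side_average(conditioned, "R")
r = coupling.sliding_correlation(left, right, window=100.0)
print(f"\nsliding L-R correlation: min {np.nanmin(r):+.2f} (oscillation episodes), "
      f"max {np.nanmax(r):+.2f}")

diff = preprocess.mn_difference(left, right)
period = tf.dominant_period(tf.mean_spectrum(tf.cwt_morlet(diff, *tf.MN_BAND)))
res = coupling.phase_difference(left, right, period)
print(f"mean L-R phase difference at {period:.1f} s: {res.angle_deg:.1f} deg "
      f"(antiphase alternation)")
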