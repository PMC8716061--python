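"""Fit the CCAP-to-motoneuron logistic gating model and compare the
multi-weight and single-weight variants by AIC.
"""

import numpy as np

from ecdysis import coupling, logistic, preprocess, synthetic, timefreq as tf

experiment, truth = synthetic.gen_experiment(synthetic.SynthParams(seed=1))

left = preprocess.side_average(experiment, "L")
right = preprocess.side_average(experiment, "R")
diff = preprocess.mn_difference(left, right)
period = tf.dominant_period(tf.mean_spectrum(tf.cwt_morlet(diff, *tf.MN_BAND)))
amplitude = coupling.mn_amplitude(diff, period)
state = logistic.binarize(amplitude, source_period=period)

F = np.column_stack(
    [preprocess.preprocess_trace(tr).v for tr in experiment.ccap_alpha]
)
multi = logistic.fit_logistic(F, state.y, mode="multi")
single = logistic.fit_logistic(F, state.y, mode="single")

p = logistic.predict_p(multi, F)
accuracy = np.mean((p >= 0.5) == truth.y_true)

print(f"binarization threshold: {state.threshold:.3f} a.u. at period {period:.1f} s")
print(f"multi-weight fit : loglik {multi.loglik:8.1f}  AIC {multi.aic:8.1f}  "
      f"active neurons {logistic.count_active(multi)}/8")
print(f"single-weight fit: loglik {single.loglik:8.1f}  AIC {single.aic:8.1f}")
print(f"classification accuracy of thresholded p(t) vs ground truth: {accuracy:.3f}")
print(f"fitted weights: {np.array2string(multi.w, precision=2)}")
print(f"true weights  : {np.array2string(truth.w_true, precision=2)}")
# A lower AIC for the multi-weight model says the neurons do not contribute
# interchangeably; zero weights flag neurons whose activity is redundant
# given the others - not neurons without influence.
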