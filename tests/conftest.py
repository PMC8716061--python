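import numpy as np
import pytest

from ecdysis.core import MN_REGION, NeuronID, Trace


def make_trace(v, dt=2.5, kind=MN_REGION, side="L", segment=None, t0=0.0):
    t = t0 + dt * np.arange(len(v))
    return Trace(NeuronID(kind, side, segment), t, np.asarray(v, dtype=float), dt)


def sine_trace(period, span, dt=2.5, amplitude=1.0, phase=0.0, side="L"):
    t = dt * np.arange(int(round(span / dt)))
    v = amplitude * np.sin(2 * np.pi * t / period + phase)
    return Trace(NeuronID(MN_REGION, side), t, v, dt)


@pytest.fixture(scope="session")
def synth_experiment():
    """One default synthetic experiment with its ground truth."""
    from ecdysis import synthetic

    return synthetic.gen_experiment(synthetic.SynthParams(seed=1))


@pytest.fixture(scope="session")
def preprocessed_experiment(synth_experiment):
    from ecdysis import preprocess
    from ecdysis.core import Experiment

    exp, gt = synth_experiment
    traces = [preprocess.preprocess_trace(tr) for tr in exp.traces]
    return Experiment(traces=traces, label=exp.label), gt
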