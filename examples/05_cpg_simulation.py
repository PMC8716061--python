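"""Simulate the two-cell conductance-based CPG driven by a fitted gate.

Runs the stochastic half-center model with full drive, measures its burst
period and left-right phase relationship, and tunes the slow potassium time
constant to a target period.
"""

import numpy as np

from ecdysis import coupling, cpg

params = cpg.CPGParams(sigma_X=0.0)  # deterministic run
sim = cpg.simulate(params, p_of_t=1.0, duration=600.0, seed=1)
period = cpg.burst_period(sim)
left, right = sim.fluorescence_traces()
phase = coupling.phase_difference(left, right, period)

print(f"tau_K = {params.tau_K} s -> burst period {period:.1f} s")
print(f"voltage range: [{sim.V.min() * 1e3:.0f}, {sim.V.max() * 1e3:.0f}] mV; "
      f"fluorescence range: [{sim.f.min():.2f}, {sim.f.max():.2f}]")
print(f"f1-f2 phase difference at the burst period: {phase.angle_deg:.0f} deg")
# The two cells burst in strict alternation, but with these published
# parameters the deterministic lock sits near +-80 deg of onset lag rather
# than 180 deg: inhibition here is spike-pulsatile (the synaptic threshold
# lies above the interspike troughs), a regime known to stabilize
# non-antiphase locked states in this half-center model.

quiet = cpg.simulate(params, p_of_t=0.0, duration=60.0, seed=1)
print(f"without CCAP drive (p=0) the cells stay below "
      f"{quiet.V[quiet.t_v > 10].max() * 1e3:.0f} mV: no spikes")

tau = cpg.tune_tau_K(33.0)
check = cpg.burst_period(cpg.simulate(
    cpg.CPGParams(sigma_X=0.0, tau_K=tau), 1.0, 400.0, seed=0))
print(f"tuning for a 33 s motoneuron period gives tau_K = {tau:.1f} s "
      f"(realized period {check:.1f} s)")
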