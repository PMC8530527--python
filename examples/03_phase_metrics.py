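"""Spike-phase statistics: response interval, vector strength and gain.

Simulates the adapting sensor with and without strong CD inhibition and
summarizes the pooled evoked spike phases.  Strong inhibition narrows
the 0.1-0.9 phase-quantile interval (raises vector strength) and pulls
the median toward the stimulus peak at pi/2, so the surviving spikes
report the peak.
"""

import numpy as np

from reafference import (
    ADAPTING_SENSOR,
    SimulationGrid,
    calibrate_inhibition,
    phase_quantiles,
    response_gain,
    simulate_session_mc,
    vector_strength,
)

grid = SimulationGrid(stimulus_frequency=20.0)
k2_strong = calibrate_inhibition(ADAPTING_SENSOR, grid, 0.1)

for name, k2 in [("no CD (k2=1)", 1.0), ("strong CD (R_S=0.1)", k2_strong)]:
    ses = simulate_session_mc(ADAPTING_SENSOR, grid, 1000, seed=3, k2=k2)
    phases = ses.spike_phases()
    n_per_sweep = phases.size / (~ses.burn_in).sum()
    q10, q50, q90 = phase_quantiles(phases - np.pi / 2)  # centered on the peak
    vs = vector_strength(phases)
    print(f"{name}:")
    print(f"  spikes/sweep={n_per_sweep:.2f}  VS={vs:.3f}  "
          f"gain={response_gain(n_per_sweep, vs):.2f}")
    print(f"  median phase={q50 + np.pi/2:.2f} rad (stimulus peak at "
          f"{np.pi/2:.2f});  interval width={q90 - q10:.2f} rad")

# Under strong CD the interval narrows and the median sits at the peak:
# single spikes become reliable reports of peak stimulation.
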