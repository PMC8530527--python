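"""Population coding: interspike intervals of a model fish's lateral line.

Simulates 30 heterogeneous sensors per fish for a single 1-s swim bout at
three calibrated inhibition levels and pools within-fish ISIs across
fish.  Without CD the pooled feedback is dense and the stimulus period is
invisible in the ISIs; strong CD (R_S = 0.1) sparsifies the feedback into
spikes near the stimulus peaks, moving ISI mass onto integer multiples of
the 50-ms period.
"""

import numpy as np

from reafference import PopulationConfig, run_population

config = PopulationConfig(n_fish=200)  # 30 sensors, levels (1.0, 0.5, 0.1)
results = run_population(config, seed=5)
period = config.grid.period

print(f"{config.n_sensors} sensors x {config.n_fish} fish, stimulus period "
      f"{1000 * period:.0f} ms")
for level in config.inhibition_levels:
    pop, isis, peaks = results[level]
    med_phase = np.median(pop.pooled_phases())
    sub_cycle = np.mean(isis.isis < 0.5 * period)
    near_period = np.mean(np.abs(isis.isis - period) <= 0.1 * period)
    print(f"R_S = {level}:")
    print(f"  total spikes={pop.total_spikes}  median phase={med_phase:.2f} rad")
    print(f"  ISI mass: {sub_cycle:.3f} below half a period, {near_period:.3f} "
          f"within 10% of one period")
    print(f"  fraction at integer multiples of the period: "
          f"{peaks.integer_multiple_fraction:.3f}")

# Only the strongly inhibited population puts ISI mass at n x 50 ms and has
# a median spike phase near the stimulus peak (pi/2 ~ 1.57 rad): the CD
# turns dense, phase-ambiguous reafference into sparse peak reports, while
# 0.5 R_S barely changes the ISI structure relative to no inhibition.
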