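"""Measure EPSCs, PPR, latency and failures on one simulated connection.

Simulates 100 baseline sweeps of the default pyramidal-to-FS connection
(paired pulses 60 ms apart every 10 s) and measures each evoked response:
amplitude relative to the pre-stimulus holding current, onset latency from
the presynaptic AP peak, failure flags, and the sweep-wise paired-pulse
ratio.  Expected values: amplitude ~63 pA, latency ~0.98 ms, PPR ~1.03.
"""

import numpy as np

from pairclamp import (
    FS_SYNAPSE,
    ModulationScenario,
    PairProtocol,
    measure_connection,
    ppr,
    simulate_paired_recording,
)

protocol = PairProtocol(n_sweeps_baseline=100, n_sweeps_agonist=0)
rec, truth = simulate_paired_recording(FS_SYNAPSE, ModulationScenario(), protocol, seed=1)
events = measure_connection(rec)

amps = [a.amplitude for a, _ in events if not a.is_failure]
lats = [a.latency for a, _ in events if not a.is_failure]
ratios = [ppr(a, b) for a, b in events if not (a.is_failure or b.is_failure)]
failures = np.mean([a.is_failure for a, _ in events])

print(f"sweeps analysed:        {len(events)}")
print(f"first-pulse amplitude:  {np.mean(amps):.1f} +- {np.std(amps):.1f} pA")
print(f"synaptic latency:       {np.mean(lats):.3f} +- {np.std(lats):.3f} ms")
print(f"paired-pulse ratio:     {np.mean(ratios):.3f} +- {np.std(ratios):.3f}")
print(f"failure rate:           {failures:.3f}")
print(f"(generator: n_sites={truth.synapse.n_sites}, p={truth.synapse.release_prob_baseline}, "
      f"q={truth.synapse.quantal_amp} pA)")
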