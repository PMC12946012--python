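"""Simulate a small interneuron cohort and extract intrinsic features.

Generates a few fast-spiking (FS) and non-fast-spiking (non-FS) cells with
the calibrated default phenotypes, runs the current-step protocol (800 ms
steps from -100 pA in +20 pA increments) and prints the headline features.
FS cells should show narrower spikes, faster membranes, lower input
resistance, smaller sag and lower rheobase than non-FS cells.
"""

import numpy as np

from pairclamp import extract_features, simulate_step_cohort

for cell_class in ("FS", "nonFS"):
    recs, _ = simulate_step_cohort(5, cell_class, seed=1)
    feats = [extract_features(r) for r in recs]
    mean = lambda k: np.nanmean([f[k] for f in feats])
    print(f"\n{cell_class} (n=5):")
    print(f"  AP half-width  {mean('ap_halfwidth'):6.3f} ms")
    print(f"  membrane tau   {mean('tau'):6.2f} ms")
    print(f"  input resist.  {mean('rin'):6.1f} MOhm")
    print(f"  sag ratio      {mean('sag_ratio'):6.3f}")
    print(f"  rheobase       {mean('rheobase'):6.1f} pA")
    print(f"  max upstroke   {mean('max_upstroke'):6.0f} mV/ms")
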