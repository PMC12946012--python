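"""Leak-potassium block: inward holding-current shift and Rin increase.

A voltage-clamped cell (leak reversal near E_K) is simulated through a
leak-block scenario (conductance scaled to 86.5% at t = 200 s).  The
analysis bins the baseline-subtracted holding current in 10 s bins and
monitors input resistance from the per-sweep -5 mV test pulse.  The
holding current shifts inward by (V_hold - E_leak) * delta_g and Rin rises
by 1/leak_scale — the classical signature of K+-leak channel closure.
"""

from pairclamp import (
    CLAMPED_RAT_CELL,
    FS_SYNAPSE,
    LEAK_BLOCK_SCENARIO,
    PairProtocol,
    analyze_intrinsic,
    holding_current_shift,
    simulate_paired_recording,
)

protocol = PairProtocol()  # 20 baseline + 26 agonist sweeps
rec, truth = simulate_paired_recording(
    FS_SYNAPSE, LEAK_BLOCK_SCENARIO, protocol, seed=2, cell=CLAMPED_RAT_CELL
)
s = analyze_intrinsic(rec, onset=200.0)

predicted = holding_current_shift(CLAMPED_RAT_CELL, LEAK_BLOCK_SCENARIO, rec.holding_potential)
print(f"holding current: {s.holding_baseline_mean:.1f} -> {s.holding_agonist_mean:.1f} pA "
      f"({s.holding_category}, p = {s.holding_p:.1e})")
print(f"predicted ohmic shift: {predicted:+.1f} pA")
print(f"input resistance: {s.rin_baseline:.1f} -> {s.rin_agonist:.1f} MOhm "
      f"(ratio {s.rin_ratio:.3f}, {s.rin_category})")
print(f"expected ratio 1/leak_scale = {1/LEAK_BLOCK_SCENARIO.leak_scale:.3f}")
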