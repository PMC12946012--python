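"""Calibrate the default generator parameter sets against the extraction code.

The published group means are targets for what the *extraction* reports on
simulated cohorts, not for the raw generator parameters: the single
exponential tau fit compromises with the sag rebound, the measured spike
threshold sits below the render base, and the sweep-mean paired-pulse ratio
carries a Jensen term from the stochastic first-pulse quantal count.  This
script closes the loop: it simulates, extracts, and nudges the parameters
until the extracted cohort means land on the targets, then prints the
calibrated values to paste into ``pairclamp.params``.

Run:  python scripts/calibrate_defaults.py
"""

from __future__ import annotations

import dataclasses

import numpy as np

from pairclamp import features
from pairclamp.params import (
    FS_NEURON,
    FS_SYNAPSE,
    NONFS_NEURON,
    ModulationScenario,
    PairProtocol,
    StepProtocol,
)
from pairclamp.simulate import simulate_current_steps, simulate_paired_recording
from pairclamp.synapse import measure_connection, ppr

# extracted-feature targets per class: tau (ms), sag ratio, AP half-width (ms)
NEURON_TARGETS = {
    "FS": {"tau": 4.03, "sag_ratio": 0.161, "ap_halfwidth": 0.18},
    "nonFS": {"tau": 6.65, "sag_ratio": 0.337, "ap_halfwidth": 0.43},
}
PPR_TARGET = 1.03

N_CELLS = 8
N_SWEEPS_PPR = 1500


def cohort_means(params, n=N_CELLS, seed0=100):
    proto = StepProtocol()
    vals = {"tau": [], "sag_ratio": [], "ap_halfwidth": []}
    for i in range(n):
        rec = simulate_current_steps(params, proto, seed=seed0 + i)
        f = features.extract_features(rec)
        for k in vals:
            vals[k].append(f[k])
    return {k: float(np.nanmean(v)) for k, v in vals.items()}


def calibrate_neuron(params, targets, rounds=4):
    for it in range(rounds):
        m = cohort_means(params)
        print(f"  iter {it}: {m}")
        g_total = params.leak_conductance + params.sag_conductance
        # sag ratio ~ g_sag fraction (attenuated by tau_sag/tau_m); rescale
        new_gsag = params.sag_conductance * targets["sag_ratio"] / max(m["sag_ratio"], 1e-6)
        new_gsag = min(new_gsag, 0.8 * g_total)
        new_g = g_total - new_gsag
        hw_factor = m["ap_halfwidth"] / targets["ap_halfwidth"]
        params = dataclasses.replace(
            params,
            membrane_capacitance=params.membrane_capacitance
            * targets["tau"]
            / max(m["tau"], 1e-6),
            sag_conductance=new_gsag,
            leak_conductance=new_g,
            spike_upstroke_gain=params.spike_upstroke_gain * hw_factor,
            spike_repolarization_gain=params.spike_repolarization_gain * hw_factor,
        )
    print(f"  final: {cohort_means(params)}")
    return params


def measured_ppr(syn, n_sweeps=N_SWEEPS_PPR, seed=7):
    proto = PairProtocol(n_sweeps_baseline=n_sweeps, n_sweeps_agonist=0)
    rec, _ = simulate_paired_recording(syn, ModulationScenario(), proto, seed=seed)
    pairs = measure_connection(rec)
    ratios = [
        ppr(a, b) for a, b in pairs if not (a.is_failure or b.is_failure)
    ]
    amps = [a.amplitude for a, _ in pairs if not a.is_failure]
    lats = [a.latency for a, _ in pairs if not a.is_failure]
    return float(np.mean(ratios)), float(np.mean(amps)), float(np.mean(lats))


def calibrate_synapse(syn, rounds=4):
    for it in range(rounds):
        m_ppr, m_amp, m_lat = measured_ppr(syn, seed=7 + it)
        print(f"  iter {it}: ppr={m_ppr:.4f} amp={m_amp:.1f} lat={m_lat:.3f} f={syn.facilitation_increment:.4f}")
        # sensitivity of the mean ratio to the facilitation increment ~ 1/p
        step = (PPR_TARGET - m_ppr) * syn.release_prob_baseline
        syn = dataclasses.replace(
            syn, facilitation_increment=max(0.0, syn.facilitation_increment + step)
        )
    m_ppr, m_amp, m_lat = measured_ppr(syn, seed=99)
    print(f"  final: ppr={m_ppr:.4f} amp={m_amp:.1f} lat={m_lat:.3f}")
    return syn


def cohort_halfwidth(cell_class, seed):
    """Jittered-cohort mean half-width under the study conditions."""
    from pairclamp.simulate import simulate_step_cohort

    recs, _ = simulate_step_cohort(12, cell_class, seed=seed)
    return float(
        np.nanmean([features.extract_features(r)["ap_halfwidth"] for r in recs])
    )


def trim_gains_on_cohort(params, cell_class, target_hw, rounds=2):
    """Final stage: land the *jittered-cohort* mean half-width on target.

    Between-cell jitter couples nonlinearly into the measured width (the
    render base and measured threshold move with the jittered excitability
    parameters), so the expectation over cohorts is re-centred here using
    several cohorts per iteration.
    """
    import pairclamp.params as P

    for it in range(rounds):
        # temporarily install the candidate as the class default
        old = P._DEFAULT_NEURONS[cell_class]
        P._DEFAULT_NEURONS[cell_class] = params
        try:
            hw = np.mean([cohort_halfwidth(cell_class, s) for s in (11, 12, 13)])
        finally:
            P._DEFAULT_NEURONS[cell_class] = old
        print(f"  cohort iter {it}: hw={hw:.4f}")
        factor = hw / target_hw
        params = dataclasses.replace(
            params,
            spike_upstroke_gain=params.spike_upstroke_gain * factor,
            spike_repolarization_gain=params.spike_repolarization_gain * factor,
        )
    return params


def main():
    print("FS neuron:")
    fs = calibrate_neuron(FS_NEURON, NEURON_TARGETS["FS"])
    print("non-FS neuron:")
    nonfs = calibrate_neuron(NONFS_NEURON, NEURON_TARGETS["nonFS"])
    print("FS cohort gain trim:")
    fs = trim_gains_on_cohort(fs, "FS", NEURON_TARGETS["FS"]["ap_halfwidth"])
    print("non-FS cohort gain trim:")
    nonfs = trim_gains_on_cohort(nonfs, "nonFS", NEURON_TARGETS["nonFS"]["ap_halfwidth"])
    print("FS synapse:")
    syn = calibrate_synapse(FS_SYNAPSE)

    for name, p in (("FS_NEURON", fs), ("NONFS_NEURON", nonfs)):
        print(f"\n{name}:")
        for f in (
            "membrane_capacitance",
            "leak_conductance",
            "sag_conductance",
            "spike_upstroke_gain",
            "spike_repolarization_gain",
        ):
            print(f"  {f} = {getattr(p, f):.4f}")
    print("\nFS_SYNAPSE:")
    print(f"  facilitation_increment = {syn.facilitation_increment:.4f}")


if __name__ == "__main__":
    main()
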