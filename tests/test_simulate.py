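"""Generator correctness: equilibria, Ohmic deflections, release statistics.

The release-model checks use an independent Monte-Carlo oracle written here
(plain numpy binomial draws of the two-pulse recursion) rather than the
simulator's own sampling path.
"""

import dataclasses

import numpy as np
import pytest

from pairclamp import (
    FS_NEURON,
    FS_SYNAPSE,
    GroundTruth,
    ModulationScenario,
    NeuronParams,
    PairProtocol,
    PairedRecording,
    StepProtocol,
    SynapseParams,
    expected_ppr_of_means,
    measure_connection,
    ppr,
    read_container,
    read_ground_truth,
    simulate_current_steps,
    simulate_paired_recording,
    write_container,
    write_ground_truth,
)

QUIET = dataclasses.replace(FS_NEURON, noise_sd=0.0)


def test_zero_current_rests_at_leak_reversal():
    proto = StepProtocol(start_current=0.0, increment=20.0, n_steps=1, pre_duration=20.0, post_duration=20.0)
    rec = simulate_current_steps(QUIET, proto, seed=0)
    assert np.max(np.abs(rec.voltage - QUIET.leak_reversal)) < 0.02


def test_passive_deflection_obeys_ohms_law():
    # Rin = 100 MOhm (g = 10 nS, no sag): -100 pA -> -10 mV steady state
    cell = dataclasses.replace(
        QUIET, leak_conductance=10.0, sag_conductance=0.0, membrane_capacitance=100.0
    )
    proto = StepProtocol(n_steps=1)  # single -100 pA step
    rec = simulate_current_steps(cell, proto, seed=0)
    i_off = int(proto.pre_duration + proto.step_duration * rec.sampling_rate)
    steady = rec.voltage[0][
        int((proto.pre_duration + 700) * rec.sampling_rate) : int(
            (proto.pre_duration + 800) * rec.sampling_rate
        )
    ].mean()
    assert steady - cell.leak_reversal == pytest.approx(-10.0, abs=0.05)


def test_simulation_is_bit_reproducible():
    proto = StepProtocol(n_steps=5)
    a = simulate_current_steps(FS_NEURON, proto, seed=11)
    b = simulate_current_steps(FS_NEURON, proto, seed=11)
    assert np.array_equal(a.voltage, b.voltage)

    pair_proto = PairProtocol(n_sweeps_baseline=5, n_sweeps_agonist=0)
    r1, g1 = simulate_paired_recording(FS_SYNAPSE, ModulationScenario(), pair_proto, seed=3)
    r2, g2 = simulate_paired_recording(FS_SYNAPSE, ModulationScenario(), pair_proto, seed=3)
    assert np.array_equal(r1.current, r2.current)
    assert np.array_equal(g1.released_quanta, g2.released_quanta)


def test_invalid_simulation_parameters_raise():
    from pairclamp import InvalidParameterError

    with pytest.raises(InvalidParameterError):
        StepProtocol(sampling_rate=0.0)
    with pytest.raises(InvalidParameterError):
        simulate_current_steps(
            dataclasses.replace(FS_NEURON), StepProtocol(sampling_rate=-1.0), seed=0
        )


def test_grid_rheobase_matches_one_picoamp_threshold_scan():
    """The smallest spiking 20 pA step brackets the 1 pA-resolution rheobase."""
    from pairclamp.features import detect_and_measure

    rec = simulate_current_steps(QUIET, StepProtocol(), seed=0)
    counts = [len(ev) for ev in detect_and_measure(rec)]
    first = next(i for i, c in enumerate(counts) if c > 0)
    grid_rheobase = rec.injected_current[first]
    assert counts[first - 1] == 0

    def spikes_at(current: float) -> bool:
        proto = StepProtocol(start_current=current, n_steps=1)
        out = simulate_current_steps(QUIET, proto, seed=0)
        return out.voltage.max() > 0.0  # spike waveforms overshoot 0 mV

    # brute-force scan of the 20 pA bracket below the first spiking step
    scan = np.arange(grid_rheobase - 20.0, grid_rheobase + 1.0, 1.0)
    spiking = [c for c in scan if spikes_at(c)]
    oracle = min(spiking)
    assert grid_rheobase - 20.0 < oracle <= grid_rheobase


# --------------------------------------------------------------------------
# Release model
# --------------------------------------------------------------------------


def test_deterministic_release_yields_n_times_q():
    syn = SynapseParams(
        n_sites=10,
        release_prob_baseline=1.0,
        quantal_amp=6.0,
        facilitation_increment=0.0,
        depression_fraction=0.0,
        latency_sd=0.0,
        noise_sd_current=0.0,
    )
    proto = PairProtocol(n_sweeps_baseline=5, n_sweeps_agonist=0)
    rec, truth = simulate_paired_recording(syn, ModulationScenario(), proto, seed=0)
    events = measure_connection(rec)
    for first, _ in events:
        assert not first.is_failure
        assert first.amplitude == pytest.approx(60.0, rel=0.01)
    assert np.all(truth.released_quanta[:, 0] == 10)


def test_zero_release_probability_gives_only_failures():
    syn = dataclasses.replace(
        FS_SYNAPSE, release_prob_baseline=0.0, facilitation_increment=0.0
    )
    proto = PairProtocol(n_sweeps_baseline=10, n_sweeps_agonist=0)
    rec, truth = simulate_paired_recording(syn, ModulationScenario(), proto, seed=0)
    events = measure_connection(rec)
    assert all(first.is_failure and second.is_failure for first, second in events)
    assert np.all(truth.released_quanta == 0)


def _mc_oracle_ppr(syn: SynapseParams, interval: float, n_draws: int, seed: int) -> float:
    """Independent Monte-Carlo of the two-pulse recursion (mean of ratios)."""
    rng = np.random.default_rng(seed)
    p1 = syn.release_prob_baseline
    p2 = min(1.0, p1 + syn.facilitation_increment)
    avail = 1.0 - syn.depression_fraction * np.exp(-interval / syn.recovery_time_constant)
    k1 = rng.binomial(syn.n_sites, p1, size=n_draws)
    k2 = rng.binomial(k1, min(1.0, p2 * avail)) + rng.binomial(syn.n_sites - k1, p2)
    ok = (k1 > 0) & (k2 > 0)
    return float(np.mean(k2[ok] / k1[ok]))


def test_depressing_regime_ppr_matches_monte_carlo_oracle():
    syn = SynapseParams(
        n_sites=12,
        release_prob_baseline=0.5,
        quantal_amp=8.0,
        facilitation_increment=0.0,
        depression_fraction=0.5,
        recovery_time_constant=200.0,
        latency_sd=0.05,
        noise_sd_current=0.0,
    )
    proto = PairProtocol(n_sweeps_baseline=500, n_sweeps_agonist=0)
    rec, _ = simulate_paired_recording(syn, ModulationScenario(), proto, seed=21)
    ratios = np.array(
        [ppr(a, b) for a, b in measure_connection(rec) if not (a.is_failure or b.is_failure)]
    )
    oracle = _mc_oracle_ppr(syn, proto.interpulse_interval, n_draws=1_000_000, seed=99)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - oracle) < 3.0 * se
    # a depressing synapse sits below unity on average
    assert oracle < 1.0


def test_first_pulse_statistics_match_binomial_law():
    # mean amplitude n*p*q; failure probability (1-p)^n
    syn = SynapseParams(
        n_sites=5,
        release_prob_baseline=0.15,
        quantal_amp=30.0,
        facilitation_increment=0.0,
        depression_fraction=0.0,
        noise_sd_current=1.0,
    )
    proto = PairProtocol(n_sweeps_baseline=600, n_sweeps_agonist=0)
    rec, truth = simulate_paired_recording(syn, ModulationScenario(), proto, seed=4)
    events = measure_connection(rec)
    firsts = [a for a, _ in events]
    fail_rate = np.mean([a.is_failure for a in firsts])
    expected_fail = (1.0 - 0.15) ** 5
    assert fail_rate == pytest.approx(expected_fail, abs=3 * np.sqrt(expected_fail * (1 - expected_fail) / 600))
    mean_quanta = truth.released_quanta[:, 0].mean()
    assert mean_quanta == pytest.approx(5 * 0.15, abs=3 * np.sqrt(5 * 0.15 * 0.85 / 600))


def test_presynaptic_scaling_lowers_expected_ppr_postsynaptic_does_not():
    base = expected_ppr_of_means(FS_SYNAPSE)
    scaled_p = dataclasses.replace(
        FS_SYNAPSE,
        release_prob_baseline=min(1.0, FS_SYNAPSE.release_prob_baseline * 1.3),
    )
    assert expected_ppr_of_means(scaled_p) < base
    # quantal scaling multiplies both pulses: the expectation is exactly invariant
    scaled_q = dataclasses.replace(FS_SYNAPSE, quantal_amp=FS_SYNAPSE.quantal_amp * 1.3)
    assert expected_ppr_of_means(scaled_q) == pytest.approx(base, rel=1e-12)


def test_washout_restores_baseline_release():
    mod = ModulationScenario(
        mechanism="postsynaptic_q_scale", scale_factor=1.5, onset_time=400.0, washout_time=800.0
    )
    proto = PairProtocol(n_sweeps_baseline=40, n_sweeps_agonist=40, n_sweeps_washout=40)
    rec, _ = simulate_paired_recording(FS_SYNAPSE, mod, proto, seed=6)
    events = measure_connection(rec)
    by_epoch = {}
    for first, _ in events:
        if not first.is_failure:
            by_epoch.setdefault(first.epoch, []).append(first.amplitude)
    base = np.array(by_epoch["baseline"])
    wash = np.array(by_epoch["washout"])
    agon = np.array(by_epoch["agonist"])
    se = np.sqrt(base.var(ddof=1) / len(base) + wash.var(ddof=1) / len(wash))
    assert abs(base.mean() - wash.mean()) < 3.0 * se
    assert agon.mean() > base.mean() * 1.3  # modulation clearly visible meanwhile


def test_sweep_csv_roundtrip_rebuilds_a_recording(tmp_path):
    from pairclamp.recordings import steps_from_sweep_csvs, sweep_to_csv

    proto = StepProtocol(n_steps=3, step_duration=100.0, pre_duration=20.0, post_duration=20.0)
    rec = simulate_current_steps(FS_NEURON, proto, seed=2, cell_id="c0")
    paths = []
    for s in range(rec.n_sweeps):
        p = tmp_path / f"sweep{s}.csv"
        sweep_to_csv(p, rec.time, rec.voltage[s], "voltage_mv")
        paths.append(p)
    rebuilt = steps_from_sweep_csvs(
        "c0", paths, rec.injected_current, rec.step_onset, rec.step_offset
    )
    assert rebuilt.sampling_rate == pytest.approx(rec.sampling_rate, rel=1e-6)
    assert np.allclose(rebuilt.voltage, rec.voltage, atol=1e-9)


def test_hdf5_container_roundtrip(tmp_path):
    proto = StepProtocol(n_steps=3, step_duration=100.0, pre_duration=20.0, post_duration=20.0)
    cell = simulate_current_steps(FS_NEURON, proto, seed=1, cell_id="c0")
    pair_proto = PairProtocol(n_sweeps_baseline=4, n_sweeps_agonist=0)
    pair, truth = simulate_paired_recording(
        FS_SYNAPSE, ModulationScenario(), pair_proto, seed=1, pair_id="p0"
    )
    path = tmp_path / "container.h5"
    write_container(path, cells=[cell], pairs=[pair])
    write_ground_truth(tmp_path / "gt.json", [truth])

    cells, pairs = read_container(path)
    assert np.array_equal(cells[0].voltage, cell.voltage)
    assert cells[0].sampling_rate == cell.sampling_rate
    assert np.array_equal(pairs[0].current, pair.current)
    assert [e.label for e in pairs[0].epochs] == [e.label for e in pair.epochs]
    truths = read_ground_truth(tmp_path / "gt.json")
    assert truths["p0"].synapse == truth.synapse
    assert np.array_equal(truths["p0"].released_quanta, truth.released_quanta)
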