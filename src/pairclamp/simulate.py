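"""Synthetic generator for current-step and paired-recording experiments.

Current-clamp side: an exponential integrate-and-fire neuron with
spike-triggered adaptation and a slow sag conductance is integrated with
forward Euler, vectorized across the sweeps of the step family.  Spike
waveforms are stylized (asymmetric pseudo-Gaussian rise/decay with prescribed
peak dV/dt), rendered into the trace at each threshold crossing, followed by
a hard reset and an absolute refractory period.

Voltage-clamp side: evoked EPSCs follow a binomial quantal release model with
facilitation and site depression between the paired pulses; waveforms are
difference-of-exponentials scaled by the released quanta with per-event
latency jitter.  Holding level, input-resistance test pulse, access
resistance and band-limited recording noise complete the sweep.

All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np
from scipy import signal as _signal

from .exceptions import InvalidParameterError
from .params import (
    FS,
    ModulationScenario,
    NeuronParams,
    PairProtocol,
    StepProtocol,
    SynapseParams,
    apply_modulation_effect,
    default_synapse_params,
    sample_neuron_params,
    sample_synapse_params,
)
from .recordings import CurrentStepRecording, Epoch, GroundTruth, PairedRecording

#: spike is declared once V exceeds threshold by this many slope factors
_SPIKE_CUT_FACTORS = 5.0
#: rendered waveform extends this many sigmas either side of the apex
_RENDER_SIGMAS = 3.5
#: default noise bandwidth, mimicking the recording low-pass filter
_NOISE_CUTOFF_KHZ = 5.0


def band_limited_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sd: float,
    sampling_rate: float,
    cutoff: float = _NOISE_CUTOFF_KHZ,
) -> np.ndarray:
    """Gaussian noise low-pass filtered to ``cutoff`` and rescaled to ``sd``."""
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    wn = min(0.99, cutoff / (sampling_rate / 2.0))
    b, a = _signal.butter(2, wn)
    filtered = _signal.lfilter(b, a, white, axis=-1)
    scale = float(filtered.std())
    if scale > 0:
        filtered *= sd / scale
    return filtered


# --------------------------------------------------------------------------
# Current-step simulation
# --------------------------------------------------------------------------


def _render_spike(
    trace: np.ndarray,
    i0: int,
    base: float,
    amp: float,
    reset: float,
    up_gain: float,
    down_gain: float,
    dt: float,
) -> int:
    """Write one stylized spike starting at sample ``i0``; return last sample.

    Rise: pseudo-Gaussian from ``base`` to ``base + amp`` with peak slope
    ``up_gain``.  Decay: pseudo-Gaussian from the apex down to ``reset`` with
    peak slope ``down_gain`` (so the repolarization runs smoothly into the
    post-spike reset without a sampling discontinuity).
    """
    sigma_r = 0.6065 * amp / up_gain
    span = amp + base - reset
    sigma_d = 0.6065 * span / down_gain
    n_rise = max(2, int(round(_RENDER_SIGMAS * sigma_r / dt)))
    n_decay = max(2, int(round(_RENDER_SIGMAS * sigma_d / dt)))
    i_pk = i0 + n_rise
    i_end = min(i_pk + n_decay, trace.shape[0] - 1)
    t = (np.arange(i0, i_end + 1) - i_pk) * dt
    rise = base + amp * np.exp(-0.5 * (t / sigma_r) ** 2)
    decay = reset + span * np.exp(-0.5 * (t / sigma_d) ** 2)
    trace[i0 : i_end + 1] = np.where(t <= 0, rise, decay)
    return i_end


def simulate_current_steps(
    params: NeuronParams, protocol: StepProtocol, seed: int, cell_id: str = "cell"
) -> CurrentStepRecording:
    """Simulate the voltage responses of one cell to the full step family.

    Deterministic given ``seed``; the measurement noise is additive and
    band-limited, so it never feeds back into the dynamics (rheobase and
    spike times are noise-free properties of the parameters).
    """
    if protocol.sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be > 0")
    if params.membrane_capacitance <= 0:
        raise InvalidParameterError("membrane_capacitance must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / protocol.sampling_rate
    n_samples = int(round(protocol.sweep_duration * protocol.sampling_rate))
    onset = int(round(protocol.pre_duration * protocol.sampling_rate))
    offset = int(round((protocol.pre_duration + protocol.step_duration) * protocol.sampling_rate))
    currents = protocol.currents
    n_sweeps = len(currents)

    C = params.membrane_capacitance
    g = params.leak_conductance
    e_l = params.leak_reversal
    v_t = params.spike_threshold
    d_t = params.spike_threshold_slope_factor
    v_cut = v_t + _SPIKE_CUT_FACTORS * d_t
    g_sag = params.sag_conductance
    tau_sag = params.sag_time_constant
    tau_w = params.adaptation_time_constant
    refr_samples = max(1, int(round(params.refractory_period / dt)))

    V = np.full(n_sweeps, e_l)
    w_sag = np.zeros(n_sweeps)
    w_adapt = np.zeros(n_sweeps)
    refr_until = np.zeros(n_sweeps, dtype=int)
    out = np.empty((n_sweeps, n_samples))
    spikes: list[tuple[int, int]] = []  # (sweep, sample index of threshold cut)
    spike_order = np.zeros(n_sweeps, dtype=int)
    spike_meta: list[tuple[int, int, float, int]] = []  # sweep, i0, base, order

    for i in range(n_samples):
        out[:, i] = V
        i_in = currents if onset <= i < offset else 0.0
        active = i >= refr_until
        drive = np.clip((V - v_t) / d_t, -60.0, 8.0)
        i_exp = g * d_t * np.exp(drive)
        dv = (-g * (V - e_l) + i_exp + w_sag - w_adapt + i_in) / C
        V = np.where(active, V + dt * dv, V)
        w_sag += dt * (g_sag * (e_l - V) - w_sag) / tau_sag
        w_adapt -= dt * w_adapt / tau_w
        crossed = active & (V >= v_cut)
        if crossed.any():
            for s in np.nonzero(crossed)[0]:
                spike_meta.append((s, i, float(out[s, i]), spike_order[s]))
                spike_order[s] += 1
            V[crossed] = params.reset_potential
            w_adapt[crossed] += params.adaptation_increment
            refr_until[crossed] = i + refr_samples

    # Render the stylized waveforms on top of the integrated trajectory.
    for s, i0, base, order in spike_meta:
        base = max(base, v_cut)  # overshoot of the Euler step is not the base
        amp = params.spike_amplitude - order * params.amp_adaptation_per_spike
        _render_spike(
            out[s],
            i0,
            base,
            amp,
            params.reset_potential,
            params.spike_upstroke_gain,
            params.spike_repolarization_gain,
            dt,
        )

    out += band_limited_noise(rng, out.shape, params.noise_sd, protocol.sampling_rate)
    return CurrentStepRecording(
        cell_id=cell_id,
        sampling_rate=protocol.sampling_rate,
        step_onset=protocol.pre_duration,
        step_offset=protocol.pre_duration + protocol.step_duration,
        injected_current=currents,
        voltage=out,
        cell_class=params.cell_class,
    )


def simulate_step_cohort(
    n_cells: int,
    cell_class: str,
    seed: int,
    protocol: StepProtocol = StepProtocol(),
    jitter: bool = True,
) -> tuple[list[CurrentStepRecording], list[NeuronParams]]:
    """Simulate a cohort of cells of one class with between-cell variability."""
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(n_cells)
    recs, plist = [], []
    for i in range(n_cells):
        if jitter:
            p = sample_neuron_params(cell_class, param_rng)
        else:
            from .params import default_neuron_params

            p = default_neuron_params(cell_class)
        rec = simulate_current_steps(
            p, protocol, int(child_seeds[i] % (2**31)), cell_id=f"{cell_class}_{i:03d}"
        )
        recs.append(rec)
        plist.append(p)
    return recs, plist


# --------------------------------------------------------------------------
# Paired-recording simulation
# --------------------------------------------------------------------------


def _epsc_template(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials normalized to unit peak; zero for t < 0."""
    tt = np.maximum(t, 0.0)
    raw = np.exp(-tt / decay_tau) - np.exp(-tt / rise_tau)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    out = raw / peak
    out[t < 0] = 0.0
    return out


def _draw_paired_release(
    rng: np.random.Generator,
    n_sites: int,
    p1: float,
    p2: float,
    depression_fraction: float,
    recovery_time_constant: float,
    interval: float,
) -> tuple[int, int]:
    """One sweep of the two-pulse binomial release recursion."""
    k1 = int(rng.binomial(n_sites, p1)) if n_sites else 0
    avail = 1.0 - depression_fraction * np.exp(-interval / recovery_time_constant)
    k2_dep = int(rng.binomial(k1, min(1.0, p2 * avail))) if k1 else 0
    k2_fresh = int(rng.binomial(n_sites - k1, min(1.0, p2))) if n_sites - k1 else 0
    return k1, k2_dep + k2_fresh


def expected_ppr_of_means(syn: SynapseParams, interval: float = 60.0) -> float:
    """Closed-form E[A2]/E[A1] of the release recursion (not the sweep mean).

    The sweep-averaged mean of ratios sits slightly above this because the
    first-pulse quantal count appears in the denominator (Jensen's
    inequality); tests account for that with a Monte-Carlo oracle.
    """
    p1 = syn.release_prob_baseline
    p2 = min(1.0, p1 + syn.facilitation_increment)
    avail = 1.0 - syn.depression_fraction * np.exp(-interval / syn.recovery_time_constant)
    e2 = p1 * min(1.0, p2 * avail) + (1.0 - p1) * p2
    return e2 / p1


def simulate_paired_recording(
    syn: SynapseParams,
    mod: ModulationScenario,
    protocol: PairProtocol,
    seed: int,
    cell: Optional[NeuronParams] = None,
    pair_id: str = "pair",
    access_baseline: float = 15.0,
    access_step: Optional[tuple[int, float]] = None,
) -> tuple[PairedRecording, GroundTruth]:
    """Simulate one connection across baseline / agonist / washout epochs.

    ``cell`` provides the postsynaptic clamped cell (leak conductance and
    reversal govern the holding current and the test-pulse response); when
    omitted, a passive clamped cell with the default FS leak is used.
    ``access_step`` optionally injects a step increase (sweep index, MOhm)
    into the access-resistance series to exercise the QC rule.
    """
    from .params import CLAMPED_RAT_CELL

    if cell is None:
        cell = CLAMPED_RAT_CELL
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate
    dt = 1.0 / fs
    n_samples = int(round(protocol.sweep_duration * fs))
    n_sweeps = protocol.n_sweeps
    t_ms = np.arange(n_samples) * dt
    sweep_starts = np.arange(n_sweeps) * protocol.sweep_period
    stim1, stim2 = protocol.stim_times
    interval = protocol.interpulse_interval
    v_hold = protocol.holding_potential

    # epochs follow the scenario timing
    total_s = n_sweeps * protocol.sweep_period
    epochs: list[Epoch]
    if mod.mechanism == "none":
        epochs = [Epoch("baseline", 0.0, total_s)]
    else:
        epochs = [Epoch("baseline", 0.0, mod.onset_time)]
        end_agonist = mod.washout_time if mod.washout_time is not None else total_s
        epochs.append(Epoch("agonist", mod.onset_time, min(end_agonist, total_s)))
        if mod.washout_time is not None and mod.washout_time < total_s:
            epochs.append(Epoch("washout", mod.washout_time, total_s))

    g0 = cell.leak_conductance
    current = np.empty((n_sweeps, n_samples))
    quanta = np.zeros((n_sweeps, 2), dtype=int)
    latencies = np.empty((n_sweeps, 2))

    tp_start, tp_dur = protocol.test_pulse_start, protocol.test_pulse_duration
    tp_end = tp_start + tp_dur
    tau_clamp = cell.membrane_capacitance / max(g0, 1e-9)

    for i in range(n_sweeps):
        active = mod.active(sweep_starts[i])
        p_eff = syn.release_prob_baseline
        q_eff = syn.quantal_amp
        g_eff = g0
        if active:
            if mod.mechanism in ("presynaptic_p_scale", "mixed"):
                p_eff = min(1.0, p_eff * mod.scale_factor)
            if mod.mechanism == "postsynaptic_q_scale":
                q_eff = q_eff * mod.scale_factor
            if mod.mechanism in ("leak_block", "mixed"):
                g_eff = g0 * mod.leak_scale
        p2_eff = min(1.0, p_eff + syn.facilitation_increment)
        k1, k2 = _draw_paired_release(
            rng,
            syn.n_sites,
            p_eff,
            p2_eff,
            syn.depression_fraction,
            syn.recovery_time_constant,
            interval,
        )
        quanta[i] = (k1, k2)

        trace = np.full(n_samples, cell.holding_bias + g_eff * (v_hold - cell.leak_reversal))
        # input-resistance test pulse with capacitive edge transients
        in_pulse = (t_ms >= tp_start) & (t_ms < tp_end)
        trace[in_pulse] += protocol.test_pulse_amp * g_eff * (
            1.0 - np.exp(-(t_ms[in_pulse] - tp_start) / tau_clamp)
        )
        cap_amp = protocol.test_pulse_amp / max(access_baseline, 1.0) * 1000.0  # pA
        trace += cap_amp * np.exp(-np.maximum(t_ms - tp_start, 0.0) / 0.3) * (t_ms >= tp_start)
        trace -= cap_amp * np.exp(-np.maximum(t_ms - tp_end, 0.0) / 0.3) * (t_ms >= tp_end)

        for pulse, (stim, k) in enumerate(zip((stim1, stim2), (k1, k2))):
            lat = rng.normal(syn.latency_mean, syn.latency_sd)
            lat = max(lat, 0.3)
            latencies[i, pulse] = lat
            if k > 0:
                onset = stim + lat
                trace -= k * q_eff * _epsc_template(t_ms - onset, syn.rise_tau, syn.decay_tau)

        current[i] = trace

    current += band_limited_noise(rng, current.shape, syn.noise_sd_current, fs)

    access = access_baseline + np.cumsum(rng.normal(0.0, 0.08, n_sweeps))
    if access_step is not None:
        idx, delta = access_step
        access[idx:] += delta

    stim_times = np.tile([stim1, stim2], (n_sweeps, 1))
    rec = PairedRecording(
        pair_id=pair_id,
        sampling_rate=fs,
        holding_potential=v_hold,
        current=current,
        stim_times=stim_times,
        presyn_peak_times=stim_times.copy(),  # AP peak defines the stimulus time
        sweep_start_times=sweep_starts,
        access_resistance=access,
        epochs=epochs,
        test_pulse_window=(tp_start, tp_end),
        test_pulse_amp=protocol.test_pulse_amp,
        holding_window=(0.0, tp_start),
    )
    truth = GroundTruth(
        pair_id=pair_id,
        synapse=syn,
        scenario=mod,
        neuron=cell,
        released_quanta=quanta,
        true_category=mod.true_category,
    )
    return rec, truth


def simulate_connection_cohort(
    n_connections: int,
    cell_class: str,
    scenario_factory: Callable[[int, np.random.Generator], ModulationScenario],
    seed: int,
    protocol: PairProtocol = PairProtocol(),
    cell: Optional[NeuronParams] = None,
    jitter: bool = True,
) -> list[tuple[PairedRecording, GroundTruth]]:
    """Simulate a cohort of connections; scenarios come from the factory."""
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(n_connections)
    out = []
    for i in range(n_connections):
        syn = (
            sample_synapse_params(cell_class, param_rng)
            if jitter
            else default_synapse_params(cell_class)
        )
        mod = scenario_factory(i, param_rng)
        rec, truth = simulate_paired_recording(
            syn,
            mod,
            protocol,
            int(child_seeds[i] % (2**31)),
            cell=cell,
            pair_id=f"{cell_class}_pair_{i:03d}",
        )
        out.append((rec, truth))
    return out
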