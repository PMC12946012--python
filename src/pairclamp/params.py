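"""Parameter sets for the synthetic paired-recording generator.

Two kinds of neurons are generated, matching the two electrophysiological
interneuron classes seen in cortical layer 2/3: fast-spiking (FS) cells with
narrow spikes, fast membrane time constant, low input resistance and small
sag, and a heterogeneous non-fast-spiking (non-FS) group with the opposite
phenotype.  The default parameter sets are calibrated (see
``scripts/calibrate_defaults.py``) so that the *extracted* features of
simulated cohorts land on the published FS / non-FS group means.

Units used throughout the package: mV, ms, pA, nS, pF, MOhm, kHz.
With these units the membrane equation ``C dV/dt = -g (V - E) + I`` is
dimensionally consistent without conversion factors, and ``Rin [MOhm] =
1000 / g [nS]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import InvalidParameterError

FS = "FS"
NONFS = "nonFS"

MECHANISMS = ("none", "presynaptic_p_scale", "postsynaptic_q_scale", "leak_block", "mixed")


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the adaptive integrate-and-fire neuron with sag.

    The subthreshold model is an exponential integrate-and-fire cell with a
    spike-triggered adaptation current (increment ``adaptation_increment``,
    time constant ``adaptation_time_constant``) and a slow conductance
    ``sag_conductance`` whose current ``w = g_sag (E_L - V)`` relaxes with
    ``sag_time_constant`` — it rebounds hyperpolarizing steps (the classical
    "sag") and equivalently limits the depolarizing steady state, so the
    hyperpolarizing input resistance is ``1/(g + g_sag)``.

    Spike shapes are stylized: once threshold is crossed, an asymmetric
    pseudo-Gaussian waveform with peak rise slope ``spike_upstroke_gain`` and
    peak decay slope ``spike_repolarization_gain`` (mV/ms) and amplitude
    ``spike_amplitude`` is rendered into the trace.
    """

    cell_class: str = FS
    membrane_capacitance: float = 80.16  # pF
    leak_conductance: float = 9.183  # nS
    leak_reversal: float = -63.12  # mV; also the resting potential
    spike_threshold: float = -55.8  # mV (rheobase-setting threshold V_T)
    spike_threshold_slope_factor: float = 1.0  # mV (Delta_T)
    adaptation_increment: float = 10.0  # pA per spike
    adaptation_time_constant: float = 120.0  # ms
    spike_upstroke_gain: float = 893.1  # mV/ms
    spike_repolarization_gain: float = 701.4  # mV/ms
    spike_amplitude: float = 96.51  # mV, threshold to peak
    amp_adaptation_per_spike: float = 0.003  # mV lost per successive spike
    reset_potential: float = -61.0  # mV
    refractory_period: float = 1.5  # ms
    sag_conductance: float = 3.867  # nS
    sag_time_constant: float = 30.0  # ms
    noise_sd: float = 0.25  # mV
    holding_bias: float = 0.0  # pA, only used for voltage-clamped cells

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0:
            raise InvalidParameterError("membrane_capacitance must be > 0")
        if self.leak_conductance <= 0:
            raise InvalidParameterError("leak_conductance must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.sag_conductance < 0:
            raise InvalidParameterError("sag_conductance must be >= 0")
        if self.spike_amplitude <= 0:
            raise InvalidParameterError("spike_amplitude must be > 0")
        if self.spike_upstroke_gain <= 0 or self.spike_repolarization_gain <= 0:
            raise InvalidParameterError("spike slope gains must be > 0")

    @property
    def input_resistance(self) -> float:
        """Hyperpolarizing-step input resistance in MOhm, ``1/(g + g_sag)``."""
        return 1000.0 / (self.leak_conductance + self.sag_conductance)

    @property
    def membrane_tau(self) -> float:
        """Fast membrane time constant ``C/g`` in ms."""
        return self.membrane_capacitance / self.leak_conductance


@dataclass(frozen=True)
class SynapseParams:
    """Binomial quantal release model with paired-pulse dynamics.

    ``n_sites`` independent sites each release with probability
    ``release_prob_baseline`` on the first pulse.  For the second pulse
    (``interpulse_interval`` later) release probability is incremented by
    ``facilitation_increment`` and sites that released are only partially
    recovered: availability ``1 - depression_fraction *
    exp(-dt / recovery_time_constant)``.  The evoked EPSC is a
    difference-of-exponentials scaled by the released quanta.
    """

    n_sites: int = 30
    release_prob_baseline: float = 0.55
    quantal_amp: float = 3.8  # pA
    facilitation_increment: float = 0.089
    recovery_time_constant: float = 200.0  # ms
    depression_fraction: float = 0.35
    latency_mean: float = 0.98  # ms, presynaptic AP peak -> EPSC onset
    latency_sd: float = 0.21  # ms
    rise_tau: float = 0.1  # ms
    decay_tau: float = 3.0  # ms
    noise_sd_current: float = 1.5  # pA, after recording-bandwidth filtering

    def __post_init__(self) -> None:
        if not 0.0 <= self.release_prob_baseline <= 1.0:
            raise InvalidParameterError("release_prob_baseline must be in [0, 1]")
        if self.quantal_amp <= 0:
            raise InvalidParameterError("quantal_amp must be > 0")
        if self.rise_tau >= self.decay_tau:
            raise InvalidParameterError("rise_tau must be < decay_tau")
        if self.latency_sd < 0:
            raise InvalidParameterError("latency_sd must be >= 0")
        if not 0.0 <= self.depression_fraction <= 1.0:
            raise InvalidParameterError("depression_fraction must be in [0, 1]")
        if self.n_sites < 0:
            raise InvalidParameterError("n_sites must be >= 0")


@dataclass(frozen=True)
class ModulationScenario:
    """Pharmacological modulation applied between onset and washout.

    ``presynaptic_p_scale`` multiplies release probability,
    ``postsynaptic_q_scale`` multiplies quantal amplitude, ``leak_block``
    multiplies the postsynaptic leak conductance by ``leak_scale`` (a
    K+-leak closure), and ``mixed`` combines a presynaptic scaling with a
    leak block.  Times are in seconds of experiment time.
    """

    mechanism: str = "none"
    scale_factor: float = 1.0
    onset_time: float = 200.0  # s
    washout_time: Optional[float] = None  # s
    leak_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise InvalidParameterError(f"unknown mechanism {self.mechanism!r}")
        if self.scale_factor <= 0:
            raise InvalidParameterError("scale_factor must be > 0")
        if self.mechanism == "none" and self.scale_factor != 1.0:
            raise InvalidParameterError("mechanism 'none' requires scale_factor == 1")
        if not 0.0 < self.leak_scale <= 1.0:
            raise InvalidParameterError("leak_scale must be in (0, 1]")
        if self.washout_time is not None and not self.onset_time < self.washout_time:
            raise InvalidParameterError("onset_time must precede washout_time")

    def active(self, t_seconds: float) -> bool:
        """Whether the agent is present at experiment time ``t_seconds``."""
        if self.mechanism == "none":
            return False
        if t_seconds < self.onset_time:
            return False
        if self.washout_time is not None and t_seconds >= self.washout_time:
            return False
        return True

    @property
    def true_category(self) -> str:
        """Ground-truth synaptic modulation category implied by the scenario."""
        if self.mechanism in ("presynaptic_p_scale", "postsynaptic_q_scale", "mixed"):
            if self.scale_factor > 1.0:
                return "increase"
            if self.scale_factor < 1.0:
                return "decrease"
        return "no_change"


@dataclass(frozen=True)
class StepProtocol:
    """Current-step protocol: 800 ms steps from -100 pA in +20 pA increments."""

    step_duration: float = 800.0  # ms
    start_current: float = -100.0  # pA
    increment: float = 20.0  # pA
    n_steps: int = 31
    sampling_rate: float = 50.0  # kHz
    pre_duration: float = 100.0  # ms before step onset
    post_duration: float = 100.0  # ms after step offset

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if self.step_duration <= 0 or self.n_steps < 1:
            raise InvalidParameterError("invalid step protocol geometry")

    @property
    def currents(self) -> np.ndarray:
        return self.start_current + self.increment * np.arange(self.n_steps)

    @property
    def sweep_duration(self) -> float:
        return self.pre_duration + self.step_duration + self.post_duration


@dataclass(frozen=True)
class PairProtocol:
    """Paired-pulse protocol: two stimuli 60 ms apart, one sweep every 10 s.

    Each recorded sweep also carries a -5 mV, 100 ms voltage-clamp test pulse
    for input-resistance monitoring, preceded by a holding-current segment.
    """

    interpulse_interval: float = 60.0  # ms
    sweep_period: float = 10.0  # s
    n_sweeps_baseline: int = 20
    n_sweeps_agonist: int = 26
    n_sweeps_washout: int = 0
    holding_potential: float = -70.0  # mV
    sampling_rate: float = 50.0  # kHz
    sweep_duration: float = 320.0  # ms
    stim1_time: float = 180.0  # ms within sweep; presynaptic AP peak
    test_pulse_amp: float = -5.0  # mV
    test_pulse_start: float = 20.0  # ms
    test_pulse_duration: float = 100.0  # ms

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if self.stim1_time + self.interpulse_interval + 15.0 > self.sweep_duration:
            raise InvalidParameterError("second stimulus window exceeds sweep duration")

    @property
    def n_sweeps(self) -> int:
        return self.n_sweeps_baseline + self.n_sweeps_agonist + self.n_sweeps_washout

    @property
    def stim_times(self) -> tuple[float, float]:
        return (self.stim1_time, self.stim1_time + self.interpulse_interval)


# --------------------------------------------------------------------------
# Default parameter sets
# --------------------------------------------------------------------------

#: Calibrated FS interneuron defaults (current-clamp phenotype).
FS_NEURON = NeuronParams()

#: Calibrated non-FS interneuron defaults.
NONFS_NEURON = NeuronParams(
    cell_class=NONFS,
    membrane_capacitance=91.36,
    leak_conductance=3.066,
    leak_reversal=-59.64,
    spike_threshold=-30.5,
    spike_threshold_slope_factor=2.0,
    adaptation_increment=45.0,
    adaptation_time_constant=250.0,
    spike_upstroke_gain=413.8,
    spike_repolarization_gain=216.3,
    spike_amplitude=79.25,
    amp_adaptation_per_spike=0.012,
    reset_potential=-52.0,
    refractory_period=3.0,
    sag_conductance=5.894,
    sag_time_constant=40.0,
)

#: FS-targeting pyramidal->interneuron synapse defaults (baseline PPR ~ 1.03).
FS_SYNAPSE = SynapseParams()

#: non-FS-targeting synapse defaults: facilitating, slower, less reliable.
NONFS_SYNAPSE = SynapseParams(
    n_sites=8,
    release_prob_baseline=0.28,
    quantal_amp=28.0,
    facilitation_increment=0.10,
    recovery_time_constant=150.0,
    depression_fraction=0.20,
    latency_mean=1.23,
    latency_sd=0.55,
    rise_tau=0.2,
    decay_tau=4.0,
)

#: Voltage-clamped cell used for holding-current / Rin simulations.  The leak
#: here is the K+-dominated component targeted by the modulation, so its
#: reversal sits near E_K; the absolute holding level is set by
#: ``holding_bias`` (the analysis baseline-subtracts it anyway).
CLAMPED_RAT_CELL = NeuronParams(
    cell_class=FS,
    membrane_capacitance=60.0,
    leak_conductance=13.8,
    leak_reversal=-90.0,
    sag_conductance=0.0,
    noise_sd=0.0,
    holding_bias=-275.4,  # cancels g*(V_hold - E_leak) at V_hold = -70
)

#: Default leak-block scenario reproducing the rodent Rin ratio (~1.16).
LEAK_BLOCK_SCENARIO = ModulationScenario(mechanism="leak_block", leak_scale=0.865)

_DEFAULT_NEURONS = {FS: FS_NEURON, NONFS: NONFS_NEURON}
_DEFAULT_SYNAPSES = {FS: FS_SYNAPSE, NONFS: NONFS_SYNAPSE}

#: Between-cell coefficient of variation of the jittered parameters when
#: sampling cohorts.  FS cells are stereotyped; the non-FS group is broad.
#: Passive/excitability parameters take the full class CV; spike-shape
#: parameters use a narrower spread (their published within-class scatter is
#: dominated by measurement variance, which the extraction already adds).
_CLASS_CV = {FS: 0.10, NONFS: 0.22}
_SHAPE_CV = {FS: 0.08, NONFS: 0.12}
#: biophysical ceiling on sampled spike thresholds (mV); interneuron spike
#: initiation does not occur at depolarized plateau potentials
_MAX_SPIKE_THRESHOLD = -25.0


def default_neuron_params(cell_class: str) -> NeuronParams:
    try:
        return _DEFAULT_NEURONS[cell_class]
    except KeyError:
        raise InvalidParameterError(f"unknown cell class {cell_class!r}") from None


def default_synapse_params(cell_class: str) -> SynapseParams:
    try:
        return _DEFAULT_SYNAPSES[cell_class]
    except KeyError:
        raise InvalidParameterError(f"unknown cell class {cell_class!r}") from None


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative jitter with coefficient of variation ~cv."""
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def sample_neuron_params(
    cell_class: str, rng: np.random.Generator, cv: Optional[float] = None
) -> NeuronParams:
    """Draw one cell's parameters around the class defaults.

    Multiplicative lognormal jitter is applied to the passive and spike-shape
    parameters; the resting potential and the rest-to-threshold gap get
    matched treatment so rheobase co-varies with input resistance, as in real
    cohorts.
    """
    base = default_neuron_params(cell_class)
    if cv is None:
        cv = _CLASS_CV[cell_class]
    shape_cv = _SHAPE_CV.get(cell_class, cv / 2.0)
    f = lambda: _lognormal_factor(rng, cv)
    gap = base.spike_threshold - base.leak_reversal
    e_leak = base.leak_reversal + rng.normal(0.0, 2.5)
    # one width factor scales both spike flanks so the cohort-mean half-width
    # is preserved (the gains divide by it; E[width * factor] = width)
    width_factor = _lognormal_factor(rng, shape_cv)
    return replace(
        base,
        membrane_capacitance=base.membrane_capacitance * f(),
        leak_conductance=base.leak_conductance * f(),
        leak_reversal=e_leak,
        spike_threshold=min(
            e_leak + gap * _lognormal_factor(rng, cv), _MAX_SPIKE_THRESHOLD
        ),
        adaptation_increment=base.adaptation_increment * f(),
        spike_upstroke_gain=base.spike_upstroke_gain / width_factor,
        spike_repolarization_gain=base.spike_repolarization_gain / width_factor,
        spike_amplitude=base.spike_amplitude * _lognormal_factor(rng, shape_cv / 2.0),
        reset_potential=e_leak + (base.reset_potential - base.leak_reversal),
        sag_conductance=base.sag_conductance * f(),
    )


def sample_synapse_params(
    cell_class: str, rng: np.random.Generator, cv: float = 0.15
) -> SynapseParams:
    """Draw one connection's parameters around the class defaults."""
    base = default_synapse_params(cell_class)
    p = base.release_prob_baseline * _lognormal_factor(rng, cv)
    return replace(
        base,
        release_prob_baseline=min(0.95, p),
        quantal_amp=base.quantal_amp * _lognormal_factor(rng, cv),
        facilitation_increment=base.facilitation_increment * _lognormal_factor(rng, cv),
        depression_fraction=min(1.0, base.depression_fraction * _lognormal_factor(rng, cv)),
    )


# --------------------------------------------------------------------------
# Modulation of intrinsic parameters
# --------------------------------------------------------------------------


def apply_modulation_effect(params: NeuronParams, mod: ModulationScenario) -> NeuronParams:
    """Return the neuron parameters while the agent is active.

    Only leak-affecting mechanisms change the cell: the leak conductance is
    multiplied by ``leak_scale``, so the input resistance scales by
    ``1/leak_scale`` and the holding current at a fixed clamp potential
    shifts by ``(V_hold - E_leak) * delta_g``.
    """
    if mod.mechanism not in ("leak_block", "mixed"):
        raise InvalidParameterError(
            f"apply_modulation_effect requires a leak mechanism, got {mod.mechanism!r}"
        )
    # leak_scale domain is enforced by ModulationScenario validation.
    return replace(params, leak_conductance=params.leak_conductance * mod.leak_scale)


def holding_current_shift(
    params: NeuronParams, mod: ModulationScenario, v_hold: float
) -> float:
    """Predicted holding-current change (pA) under a leak block at ``v_hold``."""
    modded = apply_modulation_effect(params, mod)
    dg = modded.leak_conductance - params.leak_conductance  # negative for a block
    return (v_hold - params.leak_reversal) * dg
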