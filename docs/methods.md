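# Methods

## Scope and design

`pairclamp` implements the analysis chain of a paired-recording
neuromodulation study — interneuron phenotyping, FS/non-FS classification,
per-connection EPSC/PPR/failure quantification with modulation
categorization, and holding-current / input-resistance analysis — together
with a synthetic generator that produces both protocols with full ground
truth. The generator exists so that every analysis stage has an oracle: its
parameters are chosen to make each extracted quantity either analytically
predictable or recoverable from the stored truth.

## Neuron model (current clamp)

Subthreshold dynamics are an exponential integrate-and-fire membrane with
two slow currents:

    C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) + w_sag − w_adapt + I(t)
    τ_sag  dw_sag/dt  = g_sag (E_L − V) − w_sag
    τ_w    dw_adapt/dt = −w_adapt ;  w_adapt ← w_adapt + b at each spike

`w_sag` is a linear slow conductance current: on hyperpolarizing steps it
produces the classical sag and rebound (hyperpolarizing input resistance
1/(g_L + g_sag), sag ratio ≈ g_sag/(g_L + g_sag) attenuated by the finite
τ_sag/τ_m ratio), and on depolarization it opposes the drive so that the
rheobase corresponds to the steady-state I–V with the full conductance. An
earlier variant rectified the sag current to hyperpolarization only; that
made the depolarizing input resistance 1/g_L and forced biologically absurd
spike thresholds (≈ −26 mV) to reach realistic non-FS rheobase currents with
the published R_in. The linear form keeps both R_in and rheobase in range
with thresholds near −30 to −56 mV, which is why it was adopted.

When V crosses V_T + 5Δ_T a stylized spike is rendered into the trace: a
pseudo-Gaussian rise to amplitude A with peak slope `spike_upstroke_gain`
and a pseudo-Gaussian decay running from the apex down to the reset
potential with peak slope `spike_repolarization_gain` (the decay shape ends
at the reset value, so integration resumes without a sampling
discontinuity). Successive spike amplitudes shrink by
`amp_adaptation_per_spike`. Spikes are followed by a hard reset and an
absolute refractory period (1.5 ms FS, 3 ms non-FS). Spike waveforms are
deliberately phenomenological — the features under test are waveform
measurements, not channel biophysics, so the waveform parameters are the
most direct calibration handles.

Integration is forward Euler at the protocol sampling rate (default 50 kHz,
dt = 0.02 ms, vectorized across the sweeps of a step family; τ_m ≥ 2 ms so
the scheme is comfortably stable). Measurement noise is additive Gaussian,
low-pass filtered at 5 kHz to mimic recording bandwidth (σ = 0.25 mV); it is
added after integration and never feeds back into the dynamics, so spike
times and rheobase are deterministic in the parameters.

### Default phenotypes and calibration

The defaults encode two interneuron classes: FS (narrow spikes ~0.18 ms,
τ ~4 ms, R_in ~77 MΩ, small sag, low rheobase, fast up/downstrokes) and
non-FS (broad spikes ~0.43 ms, slower membrane, higher R_in, larger sag,
higher rheobase, stronger spike-frequency adaptation via a larger
adaptation increment b). Because the extraction itself biases some
measurements (the single-exponential τ fit compromises with the sag
rebound; the measured threshold sits below the render base; between-cell
jitter couples nonlinearly into measured width), the defaults are
*calibrated against the extraction code*: `scripts/calibrate_defaults.py`
iteratively adjusts C (for fitted τ), the g_L/g_sag split at fixed total
conductance (for the sag ratio at the published R_in), the spike-slope
gains (for the cohort-mean half-width under the default between-cell
jitter), and the facilitation increment of the synapse (for the sweep-mean
PPR). Calibration targets are the published FS/non-FS group means; the
committed defaults are the converged values.

Cohort sampling applies mean-one lognormal jitter: CV 0.10 (FS) / 0.22
(non-FS) on passive and excitability parameters, and a narrower width
factor (CV 0.08 / 0.12) applied *jointly* to both spike flanks in a
width-preserving direction, since the published within-class scatter of
shape features is dominated by measurement variance that the extraction
already adds. Sampled spike thresholds are capped at −25 mV so the
pre-spike trajectory always stays far below the −10 mV peak criterion of
the detector.

## Synapse model (voltage clamp)

Release follows a binomial quantal model: n sites release independently
with probability p₁ on the first pulse (quantal count k₁ ~ Binomial(n, p₁)).
For the second pulse, Δt = 60 ms later, release probability is p₂ =
min(1, p₁ + f) (additive facilitation) and sites that released are only
partially recovered: availability 1 − d·exp(−Δt/τ_rec). The evoked EPSC is
a difference-of-exponentials (rise 0.1 ms, decay 3 ms) scaled by k·q, with
per-event latency drawn from N(0.98, 0.21²) ms (floored at 0.3 ms) relative
to the presynaptic AP peak. Sweeps carry a holding segment, a −5 mV / 100 ms
test pulse with capacitive edge transients, band-limited current noise
(σ = 1.5 pA), and a slow random-walk access-resistance series (optional step
increase to exercise the QC rule).

Default connection: n = 30, p = 0.55, q = 3.8 pA (mean n·p·q ≈ 63 pA,
matching the published FS-input mean), d = 0.35, τ_rec = 200 ms,
f = 0.089 calibrated so the *sweep-averaged* PPR is 1.03 — the mean of
ratios sits a few percent above E[A₂]/E[A₁] because k₁ appears in the
denominator (Jensen term ≈ 1 + Var(k₁)/E[k₁]²). The site count was chosen
jointly with three constraints: the published mean amplitude, a sweep-wise
PPR dispersion low enough that a ×1.3 presynaptic scaling is statistically
resolvable from 300 sweeps per epoch, and a realistic quantal size. This
places the default failure probability (1−p)ⁿ near zero; failure-rate
behaviour (estimator unbiasedness against (1−p)ⁿ) is exercised by dedicated
low-p parameter sets in the tests, and the non-FS-targeting defaults
(n = 8, p = 0.28) represent the less reliable inputs onto that class.

Modulation mechanisms multiply p (presynaptic), q (postsynaptic) or g_L
(leak block, scale in (0, 1]) between onset and washout. Since q scales both
pulses identically, the expected PPR is exactly invariant under
postsynaptic scaling, while presynaptic scaling lowers it (higher p₁ both
saturates facilitation and deepens depression) — the dissociation the ΔPPR
analysis detects.

### Clamped-cell leak reversal

For voltage-clamp (intrinsic) simulations, the cell's single leak
conductance represents the K⁺-dominated component targeted by the
modulation, so its reversal is set near E_K (−90 mV) and a bias term fixes
the absolute holding level (the analysis baseline-subtracts it). This keeps
the two Ohmic identities exact and in the physiological direction: blocking
leak at V_hold = −70 mV shifts the holding current *inward* by
(V_hold − E_leak)·Δg and raises R_in by 1/leak_scale. Current-clamp
parameter sets instead use leak_reversal = resting potential, which is what
the step protocol measures.

## Extraction conventions

- **Detection**: upward crossing of dV/dt ≥ 20 mV/ms (np.gradient), peak =
  maximum between consecutive crossings, required to exceed −10 mV; events
  with peaks within 1 ms merge. Traces below 10 kHz raise a resolution
  error. Threshold time/voltage are linearly interpolated at the criterion
  crossing.
- **Shape**: amplitude = peak − threshold; half-width between interpolated
  crossings of threshold + amplitude/2 on both flanks (flagged missing if
  the decay never recrosses before the next event); up/downstroke extrema
  from the discrete derivative inside the spike window.
- **Passive**: RMP = mean pre-stimulus voltage; τ from a single-exponential
  fit over 2–100 ms after onset of each hyperpolarizing step, averaged;
  R_in = steady-state deflection (last 100 ms of the step) over injected
  current, averaged; sag ratio (V_min − V_ss)/(V_min − V_baseline) on the
  −100 pA sweep, measured on a 5 ms boxcar-smoothed trace so the trace
  minimum is not a noise extreme.
- **Firing**: rheobase = current of the first (ascending) sweep with ≥ 1 AP;
  normalized ISI accommodation = per-sweep mean ISI divided by the AP count
  (sweeps with ≥ 3 APs), averaged; amplitude adaptation = mean
  later-minus-earlier consecutive amplitude difference (negative means
  shrinking spikes).
- **Registry**: 11 mandatory features plus derived entries (per-step spike
  counts relative to rheobase, f–I slope, ISI statistics, first/last-spike
  shape values, latencies, AHP depth, …) totalling exactly 55 columns.
  Range scaling maps each column to [0, 1]; constant columns become 0.5 and
  are flagged; missing values are median-imputed and flagged; an all-missing
  column is an error naming the feature.
- **EPSC measurement**: baseline = mean over 5 ms pre-stimulus; amplitude =
  |extremum − baseline| in a 0.5–10 ms post-stimulus window on a 0.2 ms
  smoothed trace; failure below max(5 pA, 3σ_noise); onset = first crossing
  of 20% of peak amplitude (interpolated); latency from the presynaptic AP
  peak. PPR is computed per sweep and averaged per window (sweeps with a
  failed pulse excluded, exclusion counts reported) rather than as a ratio
  of window means — the sweep-ratio convention matches how the generator's
  baseline PPR was calibrated.
- **Statistics**: Mann–Whitney is exact for group sizes ≤ 8 without ties,
  tie-corrected normal approximation otherwise; per-connection and per-cell
  categories use two-sided α = 0.05 with no multiple-testing correction
  (each connection is its own experiment); cohort paired tests gate on
  Shapiro–Wilk normality of the differences (paired t vs Wilcoxon), with
  all-zero differences reported as p = 1 and flagged; category percentages
  report the exact fraction plus the nearest-integer percent.

## Analysis windows and defaults

Baseline −200…0 s and agonist +60…+260 s relative to wash-in onset (the one
minute gap lets the agonist equilibrate), configurable per run; the
interpulse interval defaults to 60 ms and is exposed in `PairProtocol` for
protocols that used 50 ms. Holding current is sampled per sweep (one sweep
per 10 s, so 10 s bins hold one sweep each), baseline-subtracted per cell;
Rin comes from the test-pulse steady state (last half of the pulse).

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: two
separable intrinsic phenotypes with overlapping between-cell scatter,
stochastic quantal EPSCs with failures, latency jitter and paired-pulse
dynamics, three modulation mechanisms with onset/washout timing, access
resistance drift, and band-limited noise. It does not emulate conductance-
based spike generation, dendritic filtering, temperature or liquid-junction
effects, series-resistance voltage errors, spontaneous synaptic activity,
or slow rundown. Passing tests therefore certify the *analysis* — that each
stage recovers what the generative model put in — not that the model is a
complete account of real recordings; on real data the same code would face
artifacts this generator does not produce.

## Problem sizes and runtimes

Test and acceptance runs use 20 cells per class for cohort statistics
(the published cohort scale), 300 sweeps per epoch for connection-level
statistics, 50 seeded runs for the mechanism-dissociation power check, and
10 embedding seeds for classification stability — sizes at which the
Monte-Carlo error of each estimate is small against its acceptance band.
The full suite runs in about five minutes on one CPU; the acceptance
script in about one minute.

## Known limitations

- The τ fit deliberately follows the stated 2–100 ms window; with a strong
  sag the single-exponential compromise under-reads the true C/g_L, which
  the calibration absorbs into C. Comparing raw C across cells with very
  different sag would be misleading.
- Extracted rheobase can sit one 20 pA grid step below the steady-state
  prediction because onset transients can fire a spike before the sag
  current equilibrates; the 1 pA-scan oracle shows the grid measurement is
  internally consistent.
- The stylized spike repolarization runs to the reset potential, so the
  measured downstroke magnitude tracks (amplitude + reset depth), not the
  repolarization gain alone; downstroke calibration is therefore joint with
  the width calibration.
- UMAP determinism holds for a fixed seed and library version; across
  versions coordinates (but not, in practice, the cluster structure) may
  change.
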