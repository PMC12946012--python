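"""Intrinsic electrophysiological feature extraction from current steps.

The extraction mirrors standard intracellular analysis practice: action
potentials are detected from a dV/dt criterion (20 mV/ms) with a subsequent
peak requirement, spike shape is measured with sub-sample interpolation,
passive properties come from the hyperpolarizing step family, and firing
properties from the ascending suprathreshold sweeps.  A 55-entry feature
registry assembles the per-cell feature vector, and the cohort matrix is
range-scaled to [0, 1] per feature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import InvalidParameterError, LowResolutionError, MissingFeatureError
from .recordings import CurrentStepRecording

#: dV/dt detection criterion, mV/ms
DVDT_THRESHOLD = 20.0
#: a detected upstroke must be followed by a peak above this voltage, mV
PEAK_CRITERION = -10.0
#: detections whose peaks fall within this window are merged, ms
MERGE_WINDOW = 1.0
#: minimum sampling rate able to resolve the dV/dt criterion, kHz
MIN_SAMPLING_RATE = 10.0

#: the eleven features every analysis reports
MANDATORY_FEATURES = (
    "rmp",
    "tau",
    "rin",
    "sag_ratio",
    "rheobase",
    "ap_halfwidth",
    "ap_amplitude",
    "max_upstroke",
    "min_downstroke",
    "isi_accommodation_norm",
    "ap_amp_adaptation",
)


@dataclass
class APEvent:
    """One detected action potential and its shape measurements."""

    sweep_index: int
    threshold_time: float  # ms
    threshold_voltage: float  # mV
    peak_time: float  # ms
    peak_voltage: float  # mV
    amplitude: float = np.nan  # mV, peak - threshold
    half_width: float = np.nan  # ms
    max_upstroke: float = np.nan  # mV/ms
    min_downstroke: float = np.nan  # mV/ms
    ahp_depth: float = np.nan  # mV below threshold after the spike

    def __post_init__(self) -> None:
        if not self.threshold_time < self.peak_time:
            raise InvalidParameterError("threshold must precede the peak")


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    """Linear interpolation of the time where y crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def detect_aps(
    trace: np.ndarray,
    sampling_rate: float,
    sweep_index: int = 0,
    dvdt_threshold: float = DVDT_THRESHOLD,
    peak_criterion: float = PEAK_CRITERION,
) -> list[APEvent]:
    """Detect action potentials on a single voltage sweep.

    An event begins where dV/dt crosses ``dvdt_threshold`` upward and the
    voltage subsequently exceeds ``peak_criterion``; the threshold point is
    the (interpolated) dV/dt-criterion crossing and the peak the local
    voltage maximum.  Double detections resolving to the same peak, or peaks
    within 1 ms, are merged.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise InvalidParameterError("voltage trace contains non-finite samples")
    if sampling_rate < MIN_SAMPLING_RATE:
        raise LowResolutionError(
            f"sampling rate {sampling_rate} kHz cannot resolve the "
            f"{dvdt_threshold} mV/ms criterion; need >= {MIN_SAMPLING_RATE} kHz"
        )
    dt = 1.0 / sampling_rate
    n = len(trace)
    dvdt = np.gradient(trace, dt)
    above = dvdt >= dvdt_threshold
    starts = np.nonzero(above[1:] & ~above[:-1])[0] + 1

    events: list[APEvent] = []
    last_peak_idx = -np.inf
    for k, i0 in enumerate(starts):
        # voltage peak: maximum between this crossing and the next one
        # (bounds the search so burst spikes stay separate)
        i1 = starts[k + 1] if k + 1 < len(starts) else n
        seg = trace[i0:i1]
        j = i0 + int(np.argmax(seg))
        if trace[j] < peak_criterion:
            continue
        if j - last_peak_idx < MERGE_WINDOW * sampling_rate:
            continue
        last_peak_idx = j
        thr_t = _interp_crossing(
            (i0 - 1) * dt, i0 * dt, dvdt[i0 - 1], dvdt[i0], dvdt_threshold
        )
        thr_v = float(np.interp(thr_t, np.arange(n) * dt, trace))
        events.append(
            APEvent(
                sweep_index=sweep_index,
                threshold_time=thr_t,
                threshold_voltage=thr_v,
                peak_time=j * dt,
                peak_voltage=float(trace[j]),
            )
        )
    return events


def ap_shape_features(
    trace: np.ndarray, event: APEvent, sampling_rate: float, next_event_time: Optional[float] = None
) -> APEvent:
    """Complete an event with amplitude, half-width, up/downstroke and AHP.

    Half-width is measured between linearly interpolated crossings of
    ``threshold + amplitude/2`` on the rising and decaying flanks; the
    up/downstroke extrema come from the discrete derivative inside the spike
    window (threshold until the voltage recrosses the threshold level).
    """
    trace = np.asarray(trace, dtype=float)
    dt = 1.0 / sampling_rate
    n = len(trace)
    i_thr = int(np.floor(event.threshold_time / dt))
    i_pk = int(round(event.peak_time / dt))
    event.amplitude = event.peak_voltage - event.threshold_voltage
    half = event.threshold_voltage + event.amplitude / 2.0

    # end of spike window: recross of threshold voltage (or the next event)
    i_max = n - 1
    if next_event_time is not None:
        i_max = min(i_max, int(next_event_time / dt))
    i_end = i_pk
    while i_end < i_max and trace[i_end] > event.threshold_voltage:
        i_end += 1

    # rising half crossing
    i = i_pk
    while i > i_thr and trace[i - 1] >= half:
        i -= 1
    t_rise = _interp_crossing((i - 1) * dt, i * dt, trace[i - 1], trace[i], half)
    # decaying half crossing
    j = i_pk
    while j < i_max and trace[j] >= half:
        j += 1
    if j >= i_max and (j >= n - 1 or trace[j] >= half):
        event.half_width = np.nan  # decay never recrossed the half level
    else:
        t_decay = _interp_crossing((j - 1) * dt, j * dt, trace[j - 1], trace[j], half)
        event.half_width = t_decay - t_rise

    window = slice(max(i_thr - 1, 0), min(i_end + 2, n))
    dvdt = np.gradient(trace[window], dt)
    event.max_upstroke = float(dvdt.max())
    event.min_downstroke = float(dvdt.min())

    # afterhyperpolarization: minimum within 20 ms after the spike window
    ahp_end = min(n, i_end + int(20.0 * sampling_rate))
    if next_event_time is not None:
        ahp_end = min(ahp_end, int(next_event_time / dt))
    if ahp_end > i_end:
        event.ahp_depth = event.threshold_voltage - float(trace[i_end:ahp_end].min())
    return event


def detect_and_measure(rec: CurrentStepRecording) -> list[list[APEvent]]:
    """Run detection + shape measurement on every sweep of a recording."""
    out: list[list[APEvent]] = []
    for s in range(rec.n_sweeps):
        events = detect_aps(rec.voltage[s], rec.sampling_rate, sweep_index=s)
        for k, ev in enumerate(events):
            nxt = events[k + 1].threshold_time if k + 1 < len(events) else None
            ap_shape_features(rec.voltage[s], ev, rec.sampling_rate, next_event_time=nxt)
        out.append(events)
    return out


# --------------------------------------------------------------------------
# Passive features
# --------------------------------------------------------------------------


def _smooth(x: np.ndarray, sampling_rate: float, width_ms: float = 5.0) -> np.ndarray:
    w = max(1, int(round(width_ms * sampling_rate)))
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _fit_tau(t: np.ndarray, v: np.ndarray) -> float:
    """Single-exponential fit V(t) = V_ss - dV exp(-t/tau); returns tau (ms)."""
    v0, vss = v[0], v[-20:].mean()
    if abs(vss - v0) < 1e-9:
        return np.nan

    def model(tt, tau, a, b):
        return b - a * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model,
            t - t[0],
            v,
            p0=[5.0, vss - v0, vss],
            bounds=([0.05, -np.inf, -np.inf], [500.0, np.inf, np.inf]),
            maxfev=2000,
        )
    except RuntimeError:
        return np.nan
    return float(popt[0])


def passive_features(rec: CurrentStepRecording) -> dict[str, float]:
    """RMP, membrane time constant, input resistance and sag ratio.

    RMP is the mean pre-stimulus voltage across sweeps.  tau comes from a
    single-exponential fit to the first 100 ms of each hyperpolarizing step
    (first 2 ms excluded), averaged across steps; Rin from the steady-state
    deflection (mean of the last 100 ms of the step) divided by the injected
    current, averaged; the sag ratio ``(V_min - V_ss)/(V_min - V_baseline)``
    is measured on the -100 pA sweep from a lightly smoothed trace.
    """
    fs = rec.sampling_rate
    onset, offset = rec.step_onset, rec.step_offset
    i_on, i_off = int(onset * fs), int(offset * fs)
    hyper = np.nonzero(rec.injected_current < 0)[0]
    out: dict[str, float] = {}
    baseline = rec.voltage[:, : i_on - int(2 * fs)] if i_on > int(2 * fs) else rec.voltage[:, :i_on]
    out["rmp"] = float(baseline.mean()) if baseline.size else np.nan
    out["rmp_sd"] = float(baseline.std()) if baseline.size else np.nan
    if len(hyper) == 0:
        out.update(tau=np.nan, rin=np.nan, sag_ratio=np.nan)
        return out

    taus, rins = [], []
    t = rec.time
    for s in hyper:
        v = rec.voltage[s]
        fit_slice = (t >= onset + 2.0) & (t <= onset + 100.0)
        taus.append(_fit_tau(t[fit_slice], v[fit_slice]))
        v_base = v[:i_on].mean()
        v_ss = v[i_off - int(100.0 * fs) : i_off].mean()
        rins.append((v_ss - v_base) / rec.injected_current[s] * 1000.0)  # MOhm
    out["tau"] = float(np.nanmean(taus))
    out["rin"] = float(np.nanmean(rins))
    out["tau_minus100"] = float(taus[0]) if len(taus) else np.nan
    out["rin_minus100"] = float(rins[0]) if len(rins) else np.nan

    # sag at the -100 pA sweep (the most negative step)
    s0 = int(np.argmin(rec.injected_current))
    v = _smooth(rec.voltage[s0], fs)
    v_base = v[int(5 * fs) : i_on - int(2 * fs)].mean()
    seg = v[i_on + int(2 * fs) : i_off]
    v_min = seg.min()
    v_ss = v[i_off - int(100.0 * fs) : i_off].mean()
    denom = v_min - v_base
    out["sag_vmin"] = float(v_min - v_base)
    out["sag_vss"] = float(v_ss - v_base)
    out["sag_ratio"] = float((v_min - v_ss) / denom) if abs(denom) > 1e-9 else np.nan
    post = v[i_off + int(2 * fs) : i_off + int(200.0 * fs)]
    out["rebound_peak"] = float(post.max() - v_base) if post.size else np.nan
    return out


# --------------------------------------------------------------------------
# Firing features
# --------------------------------------------------------------------------


def firing_features(
    rec: CurrentStepRecording, aps: Sequence[Sequence[APEvent]]
) -> dict[str, float]:
    """Rheobase, accommodation, adaptation and the derived firing statistics.

    ``isi_accommodation_norm`` follows the convention: for every sweep with
    at least three APs, the mean interspike interval divided by the number of
    APs (ms/spike), averaged over qualifying sweeps.  ``ap_amp_adaptation``
    is the mean later-minus-earlier difference of consecutive AP amplitudes.
    """
    counts = np.array([len(ev) for ev in aps])
    currents = rec.injected_current
    out: dict[str, float] = {}

    spiking = np.nonzero(counts > 0)[0]
    if len(spiking) == 0:
        out["rheobase"] = np.nan
        rheo_idx = None
    else:
        rheo_idx = int(spiking[0])
        out["rheobase"] = float(currents[rheo_idx])

    accom, amp_adapt = [], []
    for ev in aps:
        if len(ev) >= 3:
            isis = np.diff([e.peak_time for e in ev])
            accom.append(isis.mean() / len(ev))
        if len(ev) >= 2:
            amps = np.array([e.amplitude for e in ev])
            amp_adapt.append(np.diff(amps).mean())
    out["isi_accommodation_norm"] = float(np.mean(accom)) if accom else np.nan
    out["ap_amp_adaptation"] = float(np.mean(amp_adapt)) if amp_adapt else np.nan

    # registry extras -------------------------------------------------------
    out["ap_count_total"] = float(counts.sum())
    out["max_firing_rate"] = (
        float(counts.max() / (rec.step_offset - rec.step_onset) * 1000.0) if counts.max() else np.nan
    )
    supra = counts > 0
    if supra.sum() >= 2:
        slope = np.polyfit(currents[supra], counts[supra], 1)[0]
        out["fi_slope"] = float(slope * 100.0)  # spikes per 100 pA
    else:
        out["fi_slope"] = np.nan

    if rheo_idx is not None:
        first = aps[rheo_idx][0]
        out["first_spike_latency"] = float(first.threshold_time - rec.step_onset)
        out["rheobase_spike_count"] = float(counts[rheo_idx])
        idx5 = rheo_idx + 5
        if idx5 < rec.n_sweeps and counts[idx5] > 0:
            out["latency_5_steps_above"] = float(
                aps[idx5][0].threshold_time - rec.step_onset
            )
        else:
            out["latency_5_steps_above"] = np.nan
        for k in range(10):
            idx = rheo_idx + k
            out[f"spike_count_rel_step_{k}"] = (
                float(counts[idx]) if idx < rec.n_sweeps else np.nan
            )
    else:
        out["first_spike_latency"] = np.nan
        out["rheobase_spike_count"] = np.nan
        out["latency_5_steps_above"] = np.nan
        for k in range(10):
            out[f"spike_count_rel_step_{k}"] = np.nan

    # ISI statistics from the sweep with the most spikes
    best = int(np.argmax(counts))
    if counts[best] >= 3:
        isis = np.diff([e.peak_time for e in aps[best]])
        out["isi_mean"] = float(isis.mean())
        out["isi_min"] = float(isis.min())
        out["isi_max"] = float(isis.max())
        out["isi_cv"] = float(isis.std() / isis.mean())
        out["isi_first"] = float(isis[0])
        out["isi_last"] = float(isis[-1])
        out["isi_adaptation_index"] = float(isis[-1] / isis[0])
    else:
        for key in ("isi_mean", "isi_min", "isi_max", "isi_cv", "isi_first", "isi_last", "isi_adaptation_index"):
            out[key] = np.nan
    return out


def _pooled_shape_stats(aps: Sequence[Sequence[APEvent]]) -> dict[str, float]:
    """Spike-shape statistics pooled over all APs, plus first/last-spike values."""
    all_events = [e for ev in aps for e in ev]
    out: dict[str, float] = {}
    fields = {
        "ap_halfwidth": "half_width",
        "ap_amplitude": "amplitude",
        "max_upstroke": "max_upstroke",
        "min_downstroke": "min_downstroke",
        "threshold_voltage": "threshold_voltage",
        "peak_voltage": "peak_voltage",
        "ahp_depth": "ahp_depth",
    }
    for name, attr in fields.items():
        vals = np.array([getattr(e, attr) for e in all_events], dtype=float)
        out[name] = float(np.nanmean(vals)) if vals.size else np.nan

    # first/last within the sweep carrying the most spikes
    counts = [len(ev) for ev in aps]
    if counts and max(counts) >= 2:
        best = aps[int(np.argmax(counts))]
        for name, attr in fields.items():
            if name == "ahp_depth":
                continue
            out[f"{name}_first"] = float(getattr(best[0], attr))
            out[f"{name}_last"] = float(getattr(best[-1], attr))
    else:
        for name in fields:
            if name == "ahp_depth":
                continue
            out[f"{name}_first"] = np.nan
            out[f"{name}_last"] = np.nan
    return out


# --------------------------------------------------------------------------
# Feature vector and matrix
# --------------------------------------------------------------------------

#: the full 55-feature registry, in matrix column order
FEATURE_REGISTRY: tuple[str, ...] = tuple(
    list(MANDATORY_FEATURES)
    + [
        "threshold_voltage",
        "peak_voltage",
        "ahp_depth",
        "first_spike_latency",
        "fi_slope",
        "max_firing_rate",
        "isi_cv",
        "isi_mean",
        "isi_min",
        "isi_max",
        "isi_first",
        "isi_last",
        "isi_adaptation_index",
    ]
    + [f"spike_count_rel_step_{k}" for k in range(10)]
    + [
        "ap_halfwidth_first",
        "ap_halfwidth_last",
        "ap_amplitude_first",
        "ap_amplitude_last",
        "max_upstroke_first",
        "max_upstroke_last",
        "min_downstroke_first",
        "min_downstroke_last",
        "threshold_voltage_first",
        "threshold_voltage_last",
        "peak_voltage_first",
        "peak_voltage_last",
        "sag_vmin",
        "sag_vss",
        "rebound_peak",
        "tau_minus100",
        "rin_minus100",
        "rmp_sd",
        "rheobase_spike_count",
        "latency_5_steps_above",
        "ap_count_total",
    ]
)
assert len(FEATURE_REGISTRY) == 55


def extract_features(rec: CurrentStepRecording) -> dict[str, float]:
    """Full per-cell feature vector (registry keys; NaN marks missing)."""
    aps = detect_and_measure(rec)
    vec: dict[str, float] = {}
    vec.update(passive_features(rec))
    vec.update(firing_features(rec, aps))
    vec.update(_pooled_shape_stats(aps))
    return {name: vec.get(name, np.nan) for name in FEATURE_REGISTRY}


@dataclass
class FeatureMatrix:
    """Cohort feature matrix with raw values, [0, 1]-scaled values and flags."""

    raw: pd.DataFrame  # cells x features
    scaled: pd.DataFrame
    bounds: pd.DataFrame  # per-feature min/max used for scaling
    flags: dict[str, list[str]]  # feature -> list of flags

    @property
    def cell_ids(self) -> list[str]:
        return list(self.raw.index)

    def to_csv(self, raw_path, scaled_path=None) -> None:
        self.raw.to_csv(raw_path)
        if scaled_path is not None:
            self.scaled.to_csv(scaled_path)


def build_feature_matrix(
    cells: dict[str, dict[str, float]] | pd.DataFrame,
    registry: Iterable[str] = FEATURE_REGISTRY,
) -> FeatureMatrix:
    """Assemble and range-scale the cohort matrix.

    Missing values are imputed with the column median (flagged); constant
    columns scale to 0.5 everywhere (flagged); a column with no finite value
    at all raises, naming the feature.
    """
    registry = list(registry)
    if isinstance(cells, pd.DataFrame):
        raw = cells.reindex(columns=registry).astype(float)
    else:
        raw = pd.DataFrame.from_dict(cells, orient="index").reindex(columns=registry).astype(float)
    if len(raw) < 2:
        raise InvalidParameterError("need at least two cells to build a matrix")

    flags: dict[str, list[str]] = {}
    filled = raw.copy()
    for col in registry:
        vals = raw[col]
        if vals.isna().all():
            raise MissingFeatureError(f"feature {col!r} is missing for every cell")
        if vals.isna().any():
            filled[col] = vals.fillna(vals.median())
            flags.setdefault(col, []).append("imputed_median")

    lo, hi = filled.min(), filled.max()
    scaled = pd.DataFrame(index=filled.index, columns=registry, dtype=float)
    for col in registry:
        span = hi[col] - lo[col]
        if span == 0:
            scaled[col] = 0.5
            flags.setdefault(col, []).append("constant")
        else:
            scaled[col] = (filled[col] - lo[col]) / span
    bounds = pd.DataFrame({"min": lo, "max": hi})
    return FeatureMatrix(raw=raw, scaled=scaled, bounds=bounds, flags=flags)
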