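"""Evoked-EPSC quantification and per-connection modulation analysis.

Per sweep, the two evoked EPSCs are measured as the difference between the
pre-stimulus holding current and the peak of the evoked response; events
below a noise-scaled threshold count as synaptic failures.  Per connection,
amplitudes from a baseline window and an agonist window are compared with a
two-sided Mann-Whitney test to categorize the modulation as increase /
decrease / no_change, the change is normalized to the baseline mean, and the
paired-pulse ratio shift (delta PPR) separates pre- from postsynaptic
mechanisms.  Cohort-level summaries and Pearson predictor correlations
follow the same conventions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import mann_whitney, paired_location_test, percent
from .exceptions import InvalidParameterError, UndefinedCorrelationError
from .recordings import PairedRecording

#: absolute floor of the failure threshold, pA
FAILURE_FLOOR_PA = 5.0
#: failure threshold in units of the noise standard deviation
FAILURE_K_SIGMA = 3.0
#: measurement window after the stimulus, ms
MEASURE_WINDOW = (0.5, 10.0)
#: pre-stimulus baseline duration, ms
BASELINE_WINDOW = 5.0
#: default analysis windows relative to agonist onset, s
DEFAULT_WINDOWS = {"baseline": (-200.0, 0.0), "agonist": (60.0, 260.0)}
#: light smoothing applied before peak/onset measurement, ms
SMOOTH_MS = 0.2


@dataclass
class EPSCEvent:
    """One measured evoked response (or failure) for one pulse of one sweep."""

    sweep_index: int
    pulse_index: int  # 1 or 2
    amplitude: float  # pA, positive magnitude
    latency: float  # ms from presynaptic AP peak to EPSC onset; NaN on failure
    is_failure: bool
    epoch: Optional[str]
    time_in_experiment: float  # s
    valid: bool = True
    reason: str = ""


@dataclass
class QCDecision:
    include: bool
    access_increase: float  # fractional increase over the series start
    reason: str = ""


@dataclass
class ConnectionSummary:
    """Per-connection statistics across epochs and the modulation verdict."""

    pair_id: str
    epoch_stats: dict[str, dict[str, float]]  # window label -> statistics
    modulation_category: str  # increase | decrease | no_change | indeterminate
    p_value: float
    normalized_change: float
    delta_ppr: float
    delta_ppr_p: float
    qc_excluded: bool = False
    qc_reason: str = ""
    group: Optional[str] = None  # e.g. FS / nonFS cohort label
    indeterminate_reason: str = ""

    @property
    def baseline_ppr(self) -> float:
        return self.epoch_stats.get("baseline", {}).get("ppr_mean", np.nan)

    @property
    def baseline_amplitude(self) -> float:
        return self.epoch_stats.get("baseline", {}).get("amp_mean", np.nan)


def _smooth(x: np.ndarray, sampling_rate: float, width_ms: float = SMOOTH_MS) -> np.ndarray:
    w = max(1, int(round(width_ms * sampling_rate)))
    if w <= 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="same")


def measure_epsc(
    sweep: np.ndarray,
    stim_time: float,
    sampling_rate: float,
    presyn_peak_time: Optional[float] = None,
    noise_sd_estimate: Optional[float] = None,
    polarity: int = -1,
    sweep_index: int = 0,
    pulse_index: int = 1,
    epoch: Optional[str] = None,
    time_in_experiment: float = 0.0,
) -> EPSCEvent:
    """Measure one evoked EPSC on a voltage-clamp current sweep.

    Baseline is the mean over the 5 ms preceding the stimulus; the amplitude
    is the magnitude of the extremum (in the EPSC polarity) within
    stimulus + 0.5 ... + 10 ms relative to that baseline.  Events smaller than
    ``max(5 pA, 3 * noise_sd)`` are failures.  Latency runs from the
    presynaptic AP peak to the onset, defined as the first crossing of 20% of
    the peak amplitude (linearly interpolated).
    """
    sweep = np.asarray(sweep, dtype=float)
    n = len(sweep)
    dt = 1.0 / sampling_rate
    i_lo = int(round((stim_time + MEASURE_WINDOW[0]) * sampling_rate))
    i_hi = int(round((stim_time + MEASURE_WINDOW[1]) * sampling_rate))
    i_b0 = int(round((stim_time - BASELINE_WINDOW) * sampling_rate))
    i_stim = int(round(stim_time * sampling_rate))
    if i_b0 < 0 or i_hi > n:
        return EPSCEvent(
            sweep_index, pulse_index, np.nan, np.nan, False, epoch,
            time_in_experiment, valid=False, reason="window_truncated",
        )
    if presyn_peak_time is None:
        presyn_peak_time = stim_time

    smoothed = _smooth(sweep[max(i_b0 - 50, 0) : i_hi], sampling_rate)
    off = max(i_b0 - 50, 0)
    baseline = smoothed[i_b0 - off : i_stim - off].mean()
    if noise_sd_estimate is None:
        noise_sd_estimate = float(sweep[i_b0:i_stim].std())
    window = smoothed[i_lo - off : i_hi - off]
    if polarity < 0:
        ext_rel = int(np.argmin(window))
        amplitude = baseline - window[ext_rel]
    else:
        ext_rel = int(np.argmax(window))
        amplitude = window[ext_rel] - baseline
    amplitude = max(amplitude, 0.0)
    threshold = max(FAILURE_FLOOR_PA, FAILURE_K_SIGMA * float(noise_sd_estimate))
    if amplitude < threshold:
        return EPSCEvent(
            sweep_index, pulse_index, amplitude, np.nan, True, epoch, time_in_experiment
        )

    # onset: first crossing of 20% of the peak amplitude before the extremum
    level = baseline + polarity * 0.2 * amplitude
    seg = window[: ext_rel + 1]
    if polarity < 0:
        below = np.nonzero(seg <= level)[0]
    else:
        below = np.nonzero(seg >= level)[0]
    if len(below) == 0:
        onset_t = (i_lo + ext_rel) * dt
    else:
        k = below[0]
        t0 = (i_lo + k - 1) * dt
        t1 = (i_lo + k) * dt
        if k == 0:
            onset_t = t1
        else:
            y0, y1 = seg[k - 1], seg[k]
            onset_t = t0 + (level - y0) * dt / (y1 - y0) if y1 != y0 else t1
    latency = onset_t - presyn_peak_time
    return EPSCEvent(
        sweep_index, pulse_index, amplitude, latency, False, epoch, time_in_experiment
    )


def ppr(first: EPSCEvent, second: EPSCEvent) -> float:
    """Paired-pulse ratio: second over first EPSC amplitude.

    Undefined (raises) when either event is a failure; callers exclude those
    sweeps and report the exclusion count.
    """
    if first.is_failure or second.is_failure:
        raise InvalidParameterError("PPR undefined when either pulse is a failure")
    return second.amplitude / first.amplitude


def measure_connection(
    rec: PairedRecording, polarity: int = -1
) -> list[tuple[EPSCEvent, EPSCEvent]]:
    """Measure both pulses on every sweep of a paired recording."""
    out = []
    for i in range(rec.n_sweeps):
        t_exp = float(rec.sweep_start_times[i])
        epoch = rec.epoch_of(t_exp)
        events = []
        for pulse in (0, 1):
            events.append(
                measure_epsc(
                    rec.current[i],
                    float(rec.stim_times[i, pulse]),
                    rec.sampling_rate,
                    presyn_peak_time=float(rec.presyn_peak_times[i, pulse]),
                    polarity=polarity,
                    sweep_index=i,
                    pulse_index=pulse + 1,
                    epoch=epoch,
                    time_in_experiment=t_exp,
                )
            )
        out.append((events[0], events[1]))
    return out


def qc_access(rec: PairedRecording, threshold: float = 0.25) -> QCDecision:
    """Exclude recordings whose access resistance rose by more than 25%.

    The reference is the value at the start of the series; exactly 25% is
    still included.  An empty series counts as unmonitored (included, with a
    warning reason).
    """
    series = np.asarray(rec.access_resistance, dtype=float)
    if series.size == 0:
        return QCDecision(include=True, access_increase=np.nan, reason="unmonitored")
    increase = float(series.max() / series[0] - 1.0)
    return QCDecision(include=increase <= threshold, access_increase=increase)


def _window_events(
    pairs: Sequence[tuple[EPSCEvent, EPSCEvent]],
    onset_time: float,
    window: tuple[float, float],
) -> list[tuple[EPSCEvent, EPSCEvent]]:
    lo, hi = onset_time + window[0], onset_time + window[1]
    return [pq for pq in pairs if lo <= pq[0].time_in_experiment < hi]


def _epoch_stats(pairs: Sequence[tuple[EPSCEvent, EPSCEvent]]) -> dict[str, float]:
    """Summary statistics for one analysis window.

    Failure rate counts all first pulses; amplitude and latency statistics
    exclude failures; PPR averages sweep-wise ratios from sweeps where
    neither pulse failed.
    """
    firsts = [p for p, _ in pairs if p.valid]
    amps = np.array([p.amplitude for p in firsts if not p.is_failure])
    lats = np.array([p.latency for p in firsts if not p.is_failure])
    pprs = np.array(
        [
            ppr(p, q)
            for p, q in pairs
            if p.valid and q.valid and not (p.is_failure or q.is_failure)
        ]
    )
    n_fail = sum(p.is_failure for p in firsts)
    return {
        "n_sweeps": float(len(firsts)),
        "n_events": float(len(amps)),
        "amp_mean": float(amps.mean()) if amps.size else np.nan,
        "amp_sd": float(amps.std(ddof=1)) if amps.size > 1 else np.nan,
        "ppr_mean": float(pprs.mean()) if pprs.size else np.nan,
        "ppr_sd": float(pprs.std(ddof=1)) if pprs.size > 1 else np.nan,
        "n_ppr_excluded": float(len(firsts) - len(pprs)),
        "failure_rate": float(n_fail / len(firsts)) if firsts else np.nan,
        "latency_mean": float(lats.mean()) if lats.size else np.nan,
        "latency_sd": float(lats.std(ddof=1)) if lats.size > 1 else np.nan,
    }


def categorize_connection(
    pairs: Sequence[tuple[EPSCEvent, EPSCEvent]],
    onset_time: float,
    windows: dict[str, tuple[float, float]] = DEFAULT_WINDOWS,
    alpha: float = 0.05,
    min_events: int = 10,
    pair_id: str = "pair",
    include_washout: Optional[tuple[float, float]] = None,
) -> ConnectionSummary:
    """Compare baseline and agonist windows and categorize the modulation.

    Sweep-wise first-pulse amplitudes (failures excluded) enter a two-sided
    Mann-Whitney test; 'increase'/'decrease' require p < alpha and a matching
    sign of the mean change.  The normalized change is
    (mean_agonist - mean_baseline)/mean_baseline and delta PPR is the
    difference of the window mean PPRs (with its own Mann-Whitney p-value on
    sweep-wise ratios).
    """
    stats_by_window: dict[str, dict[str, float]] = {}
    window_pairs: dict[str, list] = {}
    for label, win in windows.items():
        sel = _window_events(pairs, onset_time, win)
        window_pairs[label] = sel
        stats_by_window[label] = _epoch_stats(sel)
    if include_washout is not None:
        sel = _window_events(pairs, onset_time, include_washout)
        window_pairs["washout"] = sel
        stats_by_window["washout"] = _epoch_stats(sel)

    base = window_pairs.get("baseline", [])
    agon = window_pairs.get("agonist", [])
    base_amps = [p.amplitude for p, _ in base if p.valid and not p.is_failure]
    agon_amps = [p.amplitude for p, _ in agon if p.valid and not p.is_failure]

    if len(base_amps) < min_events or len(agon_amps) < min_events:
        return ConnectionSummary(
            pair_id=pair_id,
            epoch_stats=stats_by_window,
            modulation_category="indeterminate",
            p_value=np.nan,
            normalized_change=np.nan,
            delta_ppr=np.nan,
            delta_ppr_p=np.nan,
            indeterminate_reason=(
                f"insufficient non-failure events ({len(base_amps)} baseline, "
                f"{len(agon_amps)} agonist; need {min_events})"
            ),
        )

    _, p_amp = mann_whitney(base_amps, agon_amps)
    mean_b, mean_a = float(np.mean(base_amps)), float(np.mean(agon_amps))
    normalized_change = (mean_a - mean_b) / mean_b
    if p_amp < alpha:
        category = "increase" if mean_a > mean_b else "decrease"
    else:
        category = "no_change"

    def _pprs(sel):
        return [
            ppr(p, q)
            for p, q in sel
            if p.valid and q.valid and not (p.is_failure or q.is_failure)
        ]

    base_ppr, agon_ppr = _pprs(base), _pprs(agon)
    if len(base_ppr) >= 2 and len(agon_ppr) >= 2:
        delta_ppr = float(np.mean(agon_ppr) - np.mean(base_ppr))
        _, delta_ppr_p = mann_whitney(base_ppr, agon_ppr)
    else:
        delta_ppr, delta_ppr_p = np.nan, np.nan

    return ConnectionSummary(
        pair_id=pair_id,
        epoch_stats=stats_by_window,
        modulation_category=category,
        p_value=float(p_amp),
        normalized_change=float(normalized_change),
        delta_ppr=delta_ppr,
        delta_ppr_p=delta_ppr_p,
    )


def analyze_connection(
    rec: PairedRecording,
    onset_time: Optional[float] = None,
    windows: dict[str, tuple[float, float]] = DEFAULT_WINDOWS,
    alpha: float = 0.05,
    polarity: int = -1,
    group: Optional[str] = None,
) -> ConnectionSummary:
    """QC + measurement + categorization for one paired recording."""
    qc = qc_access(rec)
    if onset_time is None:
        agonist = [e for e in rec.epochs if e.label == "agonist"]
        onset_time = agonist[0].start if agonist else float(rec.sweep_start_times[-1])
    pairs = measure_connection(rec, polarity=polarity)
    summary = categorize_connection(
        pairs, onset_time, windows=windows, alpha=alpha, pair_id=rec.pair_id
    )
    summary.qc_excluded = not qc.include
    summary.qc_reason = qc.reason or (
        f"access resistance increased {qc.access_increase:.0%}" if not qc.include else ""
    )
    summary.group = group
    return summary


# --------------------------------------------------------------------------
# Cohort level
# --------------------------------------------------------------------------


def cohort_statistics(
    summaries: Sequence[ConnectionSummary], group: Optional[str] = None
) -> dict:
    """Category counts/percentages and the population-level paired test.

    The paired test compares per-connection baseline vs agonist mean
    amplitudes: Shapiro-Wilk on the paired differences selects paired t-test
    (normal) or Wilcoxon signed-rank.  Groups with fewer than three
    connections get descriptive output only.
    """
    if group is not None:
        summaries = [s for s in summaries if s.group == group]
    summaries = [s for s in summaries if not s.qc_excluded]
    cats = [s.modulation_category for s in summaries]
    n = len([c for c in cats if c != "indeterminate"])
    out: dict = {"n": n, "group": group, "categories": {}}
    for cat in ("increase", "decrease", "no_change"):
        count = cats.count(cat)
        pct, pct_int = percent(count, n)
        out["categories"][cat] = {"count": count, "percent": pct, "percent_int": pct_int}

    base = np.array([s.baseline_amplitude for s in summaries], dtype=float)
    agon = np.array(
        [s.epoch_stats.get("agonist", {}).get("amp_mean", np.nan) for s in summaries]
    )
    ok = np.isfinite(base) & np.isfinite(agon)
    out["baseline_mean"] = float(base[ok].mean()) if ok.any() else np.nan
    out["baseline_sd"] = float(base[ok].std(ddof=1)) if ok.sum() > 1 else np.nan
    out["agonist_mean"] = float(agon[ok].mean()) if ok.any() else np.nan
    out["agonist_sd"] = float(agon[ok].std(ddof=1)) if ok.sum() > 1 else np.nan
    if ok.sum() >= 3:
        test, p, zero_flag = paired_location_test(base[ok], agon[ok])
        out["population_test"] = test
        out["population_p"] = p
        out["zero_difference_flag"] = zero_flag
    else:
        out["population_test"] = "descriptive_only"
        out["population_p"] = np.nan
    return out


def category_percentages(categories: Iterable[str]) -> dict[str, dict[str, float]]:
    """Percentage table straight from a list of per-connection categories."""
    cats = [c for c in categories if c != "indeterminate"]
    out = {}
    for cat in ("increase", "decrease", "no_change"):
        pct, pct_int = percent(cats.count(cat), len(cats))
        out[cat] = {"count": cats.count(cat), "percent": pct, "percent_int": pct_int}
    return out


PREDICTORS = ("baseline_ppr", "delta_ppr", "baseline_amplitude")


def correlate_predictors(
    summaries: Sequence[ConnectionSummary],
) -> dict[str, dict[str, float]]:
    """Pearson correlations of baseline predictors with the normalized change.

    Predictors: baseline PPR, delta PPR, baseline amplitude.  Raises on a
    zero-variance predictor (the correlation is undefined).
    """
    y = np.array([s.normalized_change for s in summaries], dtype=float)
    out = {}
    for name in PREDICTORS:
        x = np.array([getattr(s, name, np.nan) if name != "delta_ppr" else s.delta_ppr for s in summaries], dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            out[name] = {"r": np.nan, "p": np.nan, "slope": np.nan, "intercept": np.nan, "n": int(ok.sum())}
            continue
        if np.isclose(x[ok].std(), 0.0) or np.isclose(y[ok].std(), 0.0):
            raise UndefinedCorrelationError(f"zero-variance data for predictor {name!r}")
        r, p = stats.pearsonr(x[ok], y[ok])
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        out[name] = {
            "r": float(r), "p": float(p),
            "slope": float(slope), "intercept": float(intercept), "n": int(ok.sum()),
        }
    return out


def summaries_to_frame(summaries: Sequence[ConnectionSummary]) -> pd.DataFrame:
    """Flatten connection summaries into a tidy table (one row per pair)."""
    rows = []
    for s in summaries:
        row = {
            "pair_id": s.pair_id,
            "group": s.group,
            "category": s.modulation_category,
            "p_value": s.p_value,
            "normalized_change": s.normalized_change,
            "delta_ppr": s.delta_ppr,
            "delta_ppr_p": s.delta_ppr_p,
            "qc_excluded": s.qc_excluded,
        }
        for label, st in s.epoch_stats.items():
            for k, v in st.items():
                row[f"{label}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
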