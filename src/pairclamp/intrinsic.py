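"""Holding-current and input-resistance effects of the modulation.

Holding current is sampled from the pre-test-pulse segment of every sweep,
baseline-subtracted per cell and averaged in 10 s bins; input resistance is
monitored from the per-sweep -5 mV test-pulse response.  A per-cell
two-sided Mann-Whitney test on pre- vs post-onset estimates assigns each
cell a decrease / increase / no_change category (the population pie-chart
convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import mann_whitney
from .exceptions import InvalidParameterError
from .recordings import PairedRecording


@dataclass
class IntrinsicSummary:
    """Per-cell intrinsic-modulation summary."""

    cell_id: str
    holding_baseline_mean: float  # pA
    holding_baseline_sd: float
    holding_agonist_mean: float
    holding_agonist_sd: float
    binned_times: np.ndarray  # s, bin centers relative to onset
    binned_holding: np.ndarray  # pA, baseline-subtracted
    holding_category: str
    holding_p: float
    rin_baseline: float  # MOhm
    rin_agonist: float
    rin_ratio: float
    rin_category: str
    rin_p: float
    cell_class: Optional[str] = None


def holding_series(rec: PairedRecording) -> tuple[np.ndarray, np.ndarray]:
    """Per-sweep holding-current samples (times in s, currents in pA)."""
    if rec.holding_window is None:
        lo, hi = 0.0, min(20.0, rec.current.shape[1] / rec.sampling_rate)
    else:
        lo, hi = rec.holding_window
    i_lo = int(lo * rec.sampling_rate)
    i_hi = int(hi * rec.sampling_rate)
    vals = rec.current[:, i_lo:i_hi].mean(axis=1)
    return np.asarray(rec.sweep_start_times, dtype=float), vals


def holding_course(
    rec: PairedRecording,
    onset: Optional[float] = None,
    bin_width: float = 10.0,
    alpha: float = 0.05,
    settle: float = 60.0,
) -> dict:
    """Baseline-subtracted, 10-s-binned holding current and its category.

    The per-cell baseline mean (pre-onset) is subtracted, bin means are
    computed on the absolute time grid, and pre-onset bins are compared with
    post-settle bins (default: one minute after wash-in, matching the
    amplitude analysis) by a two-sided Mann-Whitney test.
    """
    if onset is None:
        agonist = [e for e in rec.epochs if e.label == "agonist"]
        if not agonist:
            raise InvalidParameterError("no agonist epoch and no onset provided")
        onset = agonist[0].start
    times, vals = holding_series(rec)
    pre = vals[times < onset]
    if pre.size == 0:
        raise InvalidParameterError("no pre-onset holding samples")
    centered = vals - pre.mean()

    edges = np.arange(times.min(), times.max() + bin_width, bin_width)
    idx = np.digitize(times, edges) - 1
    bin_means = np.array([centered[idx == k].mean() for k in range(len(edges) - 1) if (idx == k).any()])
    bin_centers = np.array(
        [(edges[k] + edges[k + 1]) / 2.0 for k in range(len(edges) - 1) if (idx == k).any()]
    )

    pre_bins = bin_means[bin_centers < onset]
    post_bins = bin_means[bin_centers >= onset + settle]
    if len(pre_bins) < 3 or len(post_bins) < 3:
        category, p = "indeterminate", np.nan
    else:
        _, p = mann_whitney(pre_bins, post_bins)
        if p < alpha:
            category = "decrease" if post_bins.mean() < pre_bins.mean() else "increase"
        else:
            category = "no_change"
    return {
        "bin_centers": bin_centers - onset,
        "bin_means": bin_means,
        "category": category,
        "p": p,
        "baseline_mean": float(pre.mean()),
        "baseline_sd": float(pre.std(ddof=1)) if pre.size > 1 else np.nan,
        "agonist_mean": float(vals[times >= onset + settle].mean())
        if (times >= onset + settle).any()
        else np.nan,
        "agonist_sd": float(vals[times >= onset + settle].std(ddof=1))
        if (times >= onset + settle).sum() > 1
        else np.nan,
    }


def rin_series(rec: PairedRecording) -> tuple[np.ndarray, np.ndarray]:
    """Per-sweep input resistance (MOhm) from the test-pulse response."""
    if rec.test_pulse_window is None or rec.test_pulse_amp == 0.0:
        raise InvalidParameterError("no test pulses present; Rin unavailable")
    lo, hi = rec.test_pulse_window
    fs = rec.sampling_rate
    # steady state: last half of the pulse (capacitive edges decayed)
    i_ss0 = int((lo + (hi - lo) / 2.0) * fs)
    i_ss1 = int(hi * fs) - int(0.5 * fs)
    if rec.holding_window is not None:
        b0, b1 = rec.holding_window
        i_b0, i_b1 = int(b0 * fs), int(b1 * fs)
    else:
        i_b0, i_b1 = 0, int(lo * fs)
    delta_i = rec.current[:, i_ss0:i_ss1].mean(axis=1) - rec.current[:, i_b0:i_b1].mean(axis=1)
    with np.errstate(divide="ignore"):
        rin = rec.test_pulse_amp / delta_i * 1000.0  # mV/pA -> GOhm -> MOhm
    return np.asarray(rec.sweep_start_times, dtype=float), rin


def rin_change(
    rec: PairedRecording,
    onset: Optional[float] = None,
    alpha: float = 0.05,
    settle: float = 60.0,
) -> dict:
    """Baseline vs agonist input resistance with a per-cell category."""
    if onset is None:
        agonist = [e for e in rec.epochs if e.label == "agonist"]
        if not agonist:
            raise InvalidParameterError("no agonist epoch and no onset provided")
        onset = agonist[0].start
    times, rin = rin_series(rec)
    pre = rin[times < onset]
    post = rin[times >= onset + settle]
    if len(pre) < 3 or len(post) < 3:
        return {
            "rin_baseline": float(pre.mean()) if pre.size else np.nan,
            "rin_agonist": float(post.mean()) if post.size else np.nan,
            "ratio": np.nan,
            "category": "indeterminate",
            "p": np.nan,
        }
    _, p = mann_whitney(pre, post)
    if p < alpha:
        category = "increase" if post.mean() > pre.mean() else "decrease"
    else:
        category = "no_change"
    return {
        "rin_baseline": float(pre.mean()),
        "rin_agonist": float(post.mean()),
        "ratio": float(post.mean() / pre.mean()),
        "category": category,
        "p": float(p),
    }


def analyze_intrinsic(
    rec: PairedRecording,
    onset: Optional[float] = None,
    alpha: float = 0.05,
    cell_class: Optional[str] = None,
) -> IntrinsicSummary:
    """Holding-current and Rin analysis for one voltage-clamped cell."""
    hc = holding_course(rec, onset=onset, alpha=alpha)
    rc = rin_change(rec, onset=onset, alpha=alpha)
    return IntrinsicSummary(
        cell_id=rec.pair_id,
        holding_baseline_mean=hc["baseline_mean"],
        holding_baseline_sd=hc["baseline_sd"],
        holding_agonist_mean=hc["agonist_mean"],
        holding_agonist_sd=hc["agonist_sd"],
        binned_times=hc["bin_centers"],
        binned_holding=hc["bin_means"],
        holding_category=hc["category"],
        holding_p=hc["p"],
        rin_baseline=rc["rin_baseline"],
        rin_agonist=rc["rin_agonist"],
        rin_ratio=rc["ratio"],
        rin_category=rc["category"],
        rin_p=rc["p"],
        cell_class=cell_class,
    )


def normalized_time_course(
    summaries: Sequence[IntrinsicSummary], cell_class: Optional[str] = None
) -> pd.DataFrame:
    """Mean +/- SEM of the baseline-subtracted binned holding per time bin."""
    if cell_class is not None:
        summaries = [s for s in summaries if s.cell_class == cell_class]
    frames = [
        pd.Series(s.binned_holding, index=np.round(s.binned_times, 3)) for s in summaries
    ]
    if not frames:
        return pd.DataFrame(columns=["mean", "sem", "n"])
    df = pd.concat(frames, axis=1)
    return pd.DataFrame(
        {"mean": df.mean(axis=1), "sem": df.sem(axis=1), "n": df.notna().sum(axis=1)}
    )


def category_counts(
    summaries: Sequence[IntrinsicSummary], which: str = "holding"
) -> dict[str, int]:
    """Pie-chart counts for holding or Rin categories."""
    attr = "holding_category" if which == "holding" else "rin_category"
    out: dict[str, int] = {}
    for s in summaries:
        out[getattr(s, attr)] = out.get(getattr(s, attr), 0) + 1
    return out
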