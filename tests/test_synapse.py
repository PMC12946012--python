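"""EPSC measurement, QC, categorization, cohort statistics, correlations."""

import dataclasses

import numpy as np
import pytest

from pairclamp import (
    ConnectionSummary,
    EPSCEvent,
    InvalidParameterError,
    UndefinedCorrelationError,
    categorize_connection,
    category_percentages,
    cohort_statistics,
    correlate_predictors,
    measure_epsc,
    ppr,
    qc_access,
)
from pairclamp.recordings import Epoch, PairedRecording
from pairclamp._stats import paired_location_test
from pairclamp.simulate import _epsc_template

FS_KHZ = 50.0


def _sweep_with_epsc(peak_pa=60.0, stim=100.0, latency=2.0, noise=0.0, seed=0, dur=200.0):
    t = np.arange(0, dur, 1.0 / FS_KHZ)
    trace = np.zeros_like(t)
    trace -= peak_pa * _epsc_template(t - (stim + latency), 0.3, 3.0)
    if noise:
        trace += np.random.default_rng(seed).normal(0, noise, len(t))
    return trace


def test_constructed_template_measured_at_its_peak():
    trace = _sweep_with_epsc(peak_pa=60.0)
    ev = measure_epsc(trace, stim_time=100.0, sampling_rate=FS_KHZ)
    assert not ev.is_failure
    assert ev.amplitude == pytest.approx(60.0, rel=0.02)


def test_flat_noisy_sweep_is_a_failure():
    rng = np.random.default_rng(0)
    trace = rng.normal(0.0, 2.0, 10000)
    ev = measure_epsc(trace, stim_time=100.0, sampling_rate=FS_KHZ, noise_sd_estimate=2.0)
    assert ev.is_failure
    assert np.isnan(ev.latency)


def test_latency_measured_from_presyn_peak_to_onset():
    trace = _sweep_with_epsc(peak_pa=80.0, stim=100.0, latency=1.5)
    ev = measure_epsc(trace, stim_time=100.0, sampling_rate=FS_KHZ, presyn_peak_time=100.0)
    # onset = 20%-of-peak crossing, slightly after the true start of the rise
    assert ev.latency == pytest.approx(1.5, abs=0.1)


def test_truncated_window_flags_event_invalid():
    trace = _sweep_with_epsc(dur=105.0)
    ev = measure_epsc(trace, stim_time=100.0, sampling_rate=FS_KHZ)
    assert not ev.valid and ev.reason == "window_truncated"


def test_ppr_values_and_failure_exclusion():
    def ev(amp, fail=False):
        return EPSCEvent(0, 1, amp, 1.0, fail, "baseline", 0.0)

    assert ppr(ev(50.0), ev(50.0)) == pytest.approx(1.0)
    assert ppr(ev(50.0), ev(75.0)) == pytest.approx(1.5)
    with pytest.raises(InvalidParameterError):
        ppr(ev(50.0, fail=True), ev(75.0))


def _recording_with_access(series):
    n = max(len(series), 2)
    return PairedRecording(
        pair_id="p",
        sampling_rate=FS_KHZ,
        holding_potential=-70.0,
        current=np.zeros((n, 100)),
        stim_times=np.tile([10.0, 70.0], (n, 1)),
        presyn_peak_times=np.tile([10.0, 70.0], (n, 1)),
        sweep_start_times=np.arange(n) * 10.0,
        access_resistance=np.asarray(series, dtype=float),
        epochs=[Epoch("baseline", 0.0, n * 10.0)],
    )


@pytest.mark.parametrize(
    "series,expected",
    [
        (np.linspace(20.0, 24.0, 10), True),   # 20% rise: keep
        (np.linspace(20.0, 26.0, 10), False),  # 30% rise: exclude
        (np.linspace(20.0, 25.0, 10), True),   # exactly 25%: boundary kept
    ],
)
def test_access_resistance_qc_rule(series, expected):
    assert qc_access(_recording_with_access(series)).include is expected


def test_empty_access_series_is_included_with_warning():
    decision = qc_access(_recording_with_access(np.array([])))
    assert decision.include and decision.reason == "unmonitored"


# --------------------------------------------------------------------------
# Categorization
# --------------------------------------------------------------------------


def _event_pairs(base_amps, agon_amps, onset=200.0, ppr_pair=1.0):
    """Construct sweep event pairs: baseline before onset, agonist at +60 s."""
    pairs = []
    for i, a in enumerate(base_amps):
        t = onset - 200.0 + i * 10.0
        first = EPSCEvent(i, 1, a, 1.0, False, "baseline", t)
        second = EPSCEvent(i, 2, a * ppr_pair, 1.0, False, "baseline", t)
        pairs.append((first, second))
    for j, a in enumerate(agon_amps):
        t = onset + 60.0 + j * 10.0
        k = len(base_amps) + j
        first = EPSCEvent(k, 1, a, 1.0, False, "agonist", t)
        second = EPSCEvent(k, 2, a * ppr_pair, 1.0, False, "agonist", t)
        pairs.append((first, second))
    return pairs


def test_identical_epochs_are_no_change_with_zero_normalized_change():
    rng = np.random.default_rng(0)
    amps = rng.normal(100.0, 5.0, 20)
    summary = categorize_connection(_event_pairs(amps, amps), onset_time=200.0)
    assert summary.modulation_category == "no_change"
    assert summary.normalized_change == pytest.approx(0.0, abs=1e-12)
    assert summary.delta_ppr == pytest.approx(0.0, abs=1e-12)


def test_disjoint_increase_yields_thirty_percent_change():
    rng = np.random.default_rng(1)
    base = rng.normal(100.0, 1.0, 20)
    base = base - base.mean() + 100.0  # exact mean 100
    agon = rng.normal(130.0, 1.0, 20)
    agon = agon - agon.mean() + 130.0
    summary = categorize_connection(_event_pairs(base, agon), onset_time=200.0)
    assert summary.modulation_category == "increase"
    assert summary.normalized_change == pytest.approx(0.30, abs=1e-9)
    assert summary.p_value < 0.05


def test_insufficient_events_are_indeterminate():
    summary = categorize_connection(
        _event_pairs([100.0] * 5, [100.0] * 5), onset_time=200.0
    )
    assert summary.modulation_category == "indeterminate"
    assert "insufficient" in summary.indeterminate_reason


# --------------------------------------------------------------------------
# Cohort statistics and correlations
# --------------------------------------------------------------------------


def test_category_percentage_table():
    cats = ["increase"] * 6 + ["decrease"] * 2 + ["no_change"] * 3
    table = category_percentages(cats)
    assert table["increase"]["count"] == 6
    assert table["increase"]["percent"] == pytest.approx(100 * 6 / 11)
    assert table["decrease"]["percent_int"] == 18


def test_all_identical_paired_values_degenerate_to_p_one():
    name, p, zero_flag = paired_location_test([5.0, 5.0, 5.0, 5.0], [5.0, 5.0, 5.0, 5.0])
    assert zero_flag and p == 1.0


def _summary(pair_id, base_amp, agon_amp, base_ppr=1.0, delta_ppr=0.0, category=None):
    nc = (agon_amp - base_amp) / base_amp
    return ConnectionSummary(
        pair_id=pair_id,
        epoch_stats={
            "baseline": {"amp_mean": base_amp, "ppr_mean": base_ppr},
            "agonist": {"amp_mean": agon_amp, "ppr_mean": base_ppr + delta_ppr},
        },
        modulation_category=category or ("increase" if nc > 0 else "no_change"),
        p_value=0.01,
        normalized_change=nc,
        delta_ppr=delta_ppr,
        delta_ppr_p=0.5,
    )


def test_cohort_statistics_counts_and_paired_test():
    rng = np.random.default_rng(2)
    summaries = [
        _summary(f"p{i}", 100.0 + rng.normal(0, 3), 120.0 + rng.normal(0, 3))
        for i in range(8)
    ]
    out = cohort_statistics(summaries)
    assert out["n"] == 8
    assert out["categories"]["increase"]["count"] == 8
    assert out["population_test"] in ("paired_t", "wilcoxon")
    assert out["population_p"] < 0.05


def test_exact_linear_relation_recovers_r_and_slope():
    summaries = [
        _summary(f"p{i}", 100.0 + i, (100.0 + i) * (1 + 2 * x), base_ppr=x, delta_ppr=0.1 * i)
        for i, x in enumerate([0.1, 0.2, 0.3, 0.4, 0.5])
    ]
    out = correlate_predictors(summaries)
    assert out["baseline_ppr"]["r"] == pytest.approx(1.0, abs=1e-9)
    assert out["baseline_ppr"]["slope"] == pytest.approx(2.0, abs=1e-9)


def test_zero_variance_predictor_raises():
    summaries = [_summary(f"p{i}", 100.0, 120.0, base_ppr=1.0) for i in range(5)]
    with pytest.raises(UndefinedCorrelationError):
        correlate_predictors(summaries)


def test_latency_estimate_recovers_generator_mean(baseline_events):
    """300 simulated sweeps: measured latency within 2 SEM of 0.98 ms."""
    lats = np.array([a.latency for a, _ in baseline_events if not a.is_failure])
    sem = lats.std(ddof=1) / np.sqrt(len(lats))
    assert abs(lats.mean() - 0.98) < 2.0 * sem


def test_baseline_ppr_recovers_default_calibration(baseline_events):
    """300 simulated sweeps: epoch mean PPR within 2 SEM of 1.03."""
    ratios = np.array(
        [ppr(a, b) for a, b in baseline_events if not (a.is_failure or b.is_failure)]
    )
    sem = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 1.03) < 2.0 * sem
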