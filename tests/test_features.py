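"""Feature extraction against analytic traces and closed-form geometry."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pairclamp import (
    APEvent,
    CurrentStepRecording,
    FEATURE_REGISTRY,
    FS_NEURON,
    LowResolutionError,
    MissingFeatureError,
    StepProtocol,
    ap_shape_features,
    build_feature_matrix,
    detect_aps,
    firing_features,
    passive_features,
    simulate_current_steps,
)

FS_KHZ = 50.0


def _trace_with_gaussian_spike(sigma_ms: float, apex_ms: float = 100.0, amp: float = 100.0):
    t = np.arange(0, 200.0, 1.0 / FS_KHZ)
    return -65.0 + amp * np.exp(-0.5 * ((t - apex_ms) / sigma_ms) ** 2), t


def test_flat_trace_has_no_events():
    trace = np.full(5000, -65.0)
    assert detect_aps(trace, FS_KHZ) == []


def test_low_sampling_rate_raises():
    with pytest.raises(LowResolutionError):
        detect_aps(np.zeros(100), sampling_rate=2.0)


def test_single_constructed_spike_detected_at_apex():
    # piecewise-linear rise whose slope ramps 10 -> 110 mV/ms, apex at 100 ms
    dt = 1.0 / FS_KHZ
    t = np.arange(0, 200.0, dt)
    slope = np.where((t >= 99.0) & (t < 100.0), 10.0 + 100.0 * (t - 99.0), 0.0)
    slope = np.where((t >= 100.0) & (t < 100.5), -120.0, slope)
    trace = -65.0 + np.cumsum(slope) * dt
    events = detect_aps(trace, FS_KHZ)
    assert len(events) == 1
    assert events[0].peak_time == pytest.approx(100.0, abs=2.0 * dt)


def test_triangular_spike_halfwidth_equals_geometry():
    # symmetric triangle: 0.2 ms rise, 0.2 ms decay -> half-width 0.2 ms
    dt = 1.0 / FS_KHZ
    t = np.arange(0, 200.0, dt)
    apex, rise = 100.0, 0.2
    tri = np.maximum(0.0, 1.0 - np.abs(t - apex) / rise)
    trace = -65.0 + 100.0 * tri
    events = detect_aps(trace, FS_KHZ)
    assert len(events) == 1
    ev = ap_shape_features(trace, events[0], FS_KHZ)
    # half level sits at threshold + amplitude/2; the dV/dt threshold point is
    # at the triangle base, so the half-width equals the rise time
    assert ev.half_width == pytest.approx(0.2, abs=2 * dt)


def test_gaussian_spike_halfwidth_equals_fwhm_identity():
    sigma = 0.1
    trace, _ = _trace_with_gaussian_spike(sigma)
    events = detect_aps(trace, FS_KHZ)
    assert len(events) == 1
    ev = ap_shape_features(trace, events[0], FS_KHZ)
    assert ev.half_width == pytest.approx(2.3548 * sigma, abs=1.5 / FS_KHZ)


def test_halfwidth_flagged_when_decay_never_recrosses():
    dt = 1.0 / FS_KHZ
    t = np.arange(0, 20.0, dt)
    trace = -65.0 + 100.0 / (1.0 + np.exp(-(t - 10.0) / 0.05))  # rises and stays up
    events = detect_aps(trace, FS_KHZ)
    assert len(events) == 1
    ev = ap_shape_features(trace, events[0], FS_KHZ)
    assert np.isnan(ev.half_width)


def test_detection_equals_local_maximum_oracle_on_simulated_sweeps(fs_cohort):
    """Spike counts match a brute-force count of local maxima above 0 mV."""
    recs, _ = fs_cohort
    rec = recs[0]
    for s in range(rec.n_sweeps):
        trace = rec.voltage[s]
        events = detect_aps(trace, rec.sampling_rate)
        interior = trace[1:-1]
        oracle = int(
            np.sum((interior > trace[:-2]) & (interior >= trace[2:]) & (interior > 0.0))
        )
        assert len(events) == oracle


# --------------------------------------------------------------------------
# Passive features
# --------------------------------------------------------------------------


def _rc_cell(noise=0.0):
    return dataclasses.replace(
        FS_NEURON,
        leak_conductance=10.0,
        sag_conductance=0.0,
        membrane_capacitance=100.0,
        noise_sd=noise,
    )


def test_rc_cell_recovers_tau_and_rin():
    rec = simulate_current_steps(_rc_cell(), StepProtocol(n_steps=5), seed=0)
    feats = passive_features(rec)
    assert feats["rin"] == pytest.approx(100.0, rel=0.01)
    assert feats["tau"] == pytest.approx(10.0, rel=0.05)
    assert feats["rmp"] == pytest.approx(FS_NEURON.leak_reversal, abs=0.05)


def test_monotonic_rc_response_has_zero_sag():
    rec = simulate_current_steps(_rc_cell(noise=0.1), StepProtocol(n_steps=5), seed=0)
    assert passive_features(rec)["sag_ratio"] == pytest.approx(0.0, abs=0.02)


def test_sag_ratio_matches_trace_extrema_directly():
    """Extraction agrees with the ratio computed from the noiseless trace."""
    cell = dataclasses.replace(FS_NEURON, noise_sd=0.0)
    proto = StepProtocol(n_steps=1)  # -100 pA only
    rec = simulate_current_steps(cell, proto, seed=0)
    feats = passive_features(rec)
    fs = rec.sampling_rate
    v = rec.voltage[0]
    i_on, i_off = int(proto.pre_duration * fs), int((proto.pre_duration + 800) * fs)
    v_base = v[: i_on - int(2 * fs)].mean()
    v_min = v[i_on:i_off].min()
    v_ss = v[i_off - int(100 * fs) : i_off].mean()
    oracle = (v_min - v_ss) / (v_min - v_base)
    assert feats["sag_ratio"] == pytest.approx(oracle, abs=0.01)
    assert feats["sag_ratio"] > 0.05  # the sag conductance is visible


# --------------------------------------------------------------------------
# Firing features
# --------------------------------------------------------------------------


def _fake_recording(n_sweeps=1):
    volts = np.full((n_sweeps, 100), -65.0)
    return CurrentStepRecording(
        cell_id="fake",
        sampling_rate=10.0,
        step_onset=0.0,
        step_offset=800.0,
        injected_current=np.arange(n_sweeps) * 20.0 + 100.0,
        voltage=volts,
    )


def _event(sweep, peak_ms, amplitude=90.0):
    return APEvent(
        sweep_index=sweep,
        threshold_time=peak_ms - 0.2,
        threshold_voltage=-40.0,
        peak_time=peak_ms,
        peak_voltage=-40.0 + amplitude,
        amplitude=amplitude,
    )


def test_isi_accommodation_formula():
    # APs at 100, 200, 300 ms: mean ISI 100 ms over 3 APs -> 33.33 ms/spike
    rec = _fake_recording()
    aps = [[_event(0, 100.0), _event(0, 200.0), _event(0, 300.0)]]
    out = firing_features(rec, aps)
    assert out["isi_accommodation_norm"] == pytest.approx(100.0 / 3.0, rel=1e-6)
    assert out["rheobase"] == 100.0


def test_amplitude_adaptation_formula():
    # amplitudes 80, 78, 76 -> mean consecutive difference -2 mV/spike
    rec = _fake_recording()
    aps = [
        [
            _event(0, 100.0, amplitude=80.0),
            _event(0, 200.0, amplitude=78.0),
            _event(0, 300.0, amplitude=76.0),
        ]
    ]
    assert firing_features(rec, aps)["ap_amp_adaptation"] == pytest.approx(-2.0)


def test_missing_firing_features_are_nan_not_zero():
    rec = _fake_recording(n_sweeps=2)
    out = firing_features(rec, [[], []])
    assert np.isnan(out["rheobase"])
    assert np.isnan(out["isi_accommodation_norm"])


# --------------------------------------------------------------------------
# Feature matrix
# --------------------------------------------------------------------------


def test_range_scaling_on_simple_column():
    cells = {
        "a": {"x": 2.0, "y": 5.0},
        "b": {"x": 4.0, "y": 5.0},
        "c": {"x": 6.0, "y": 5.0},
    }
    fm = build_feature_matrix(cells, registry=["x", "y"])
    assert list(fm.scaled["x"]) == pytest.approx([0.0, 0.5, 1.0])
    # constant column: all 0.5 and flagged
    assert list(fm.scaled["y"]) == pytest.approx([0.5, 0.5, 0.5])
    assert "constant" in fm.flags["y"]


def test_missing_values_imputed_and_flagged():
    cells = {
        "a": {"x": 1.0},
        "b": {"x": np.nan},
        "c": {"x": 3.0},
    }
    fm = build_feature_matrix(cells, registry=["x"])
    assert "imputed_median" in fm.flags["x"]
    assert fm.scaled.loc["b", "x"] == pytest.approx(0.5)  # median of {1, 3}


def test_all_missing_column_raises_naming_the_feature():
    cells = {"a": {"x": 1.0, "bad": np.nan}, "b": {"x": 2.0, "bad": np.nan}}
    with pytest.raises(MissingFeatureError, match="bad"):
        build_feature_matrix(cells, registry=["x", "bad"])


def test_scaling_is_idempotent_and_order_invariant():
    rng = np.random.default_rng(0)
    cells = {f"c{i}": {"x": float(v), "y": float(w)} for i, (v, w) in enumerate(rng.normal(size=(6, 2)))}
    fm1 = build_feature_matrix(cells, registry=["x", "y"])
    # re-scaling the scaled matrix changes nothing
    again = build_feature_matrix(fm1.scaled, registry=["x", "y"])
    assert np.allclose(fm1.scaled.to_numpy(), again.scaled.to_numpy())
    # permuting the cells permutes rows only
    perm = dict(reversed(list(cells.items())))
    fm2 = build_feature_matrix(perm, registry=["x", "y"])
    assert np.allclose(
        fm1.scaled.loc[sorted(cells)].to_numpy(), fm2.scaled.loc[sorted(cells)].to_numpy()
    )


def test_registry_yields_55_columns_on_simulated_cohort(cohort_matrix):
    fm, _ = cohort_matrix
    assert fm.raw.shape[1] == 55
    assert list(fm.raw.columns) == list(FEATURE_REGISTRY)
    scaled = fm.scaled.to_numpy()
    assert np.nanmin(scaled) >= 0.0 and np.nanmax(scaled) <= 1.0


def test_group_differences_reproduce_in_direction(fs_features, nonfs_features):
    """FS cells: narrower spikes, faster tau, lower Rin, less sag, lower rheobase."""
    fs = pd.DataFrame.from_dict(fs_features, orient="index")
    non = pd.DataFrame.from_dict(nonfs_features, orient="index")
    for feat in ("ap_halfwidth", "tau", "rin", "sag_ratio", "rheobase", "isi_accommodation_norm"):
        assert fs[feat].mean() < non[feat].mean(), feat
    assert fs["max_upstroke"].mean() > non["max_upstroke"].mean()
    assert fs["min_downstroke"].mean() < non["min_downstroke"].mean()
    assert fs["rmp"].mean() < non["rmp"].mean()
    assert fs["ap_amplitude"].mean() > non["ap_amplitude"].mean()
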