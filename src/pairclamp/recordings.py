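"""In-memory containers for simulated/recorded sweeps plus file I/O.

The on-disk container is a single HDF5 file::

    /cells/<cell_id>/voltage            (n_sweeps, n_samples) mV
    /cells/<cell_id>/injected_current   (n_sweeps,) pA
        attrs: sampling_rate_khz, step_onset_ms, step_offset_ms, cell_class
    /pairs/<pair_id>/current            (n_sweeps, n_samples) pA
    /pairs/<pair_id>/stim_times         (n_sweeps, 2) ms within sweep
    /pairs/<pair_id>/presyn_peak_times  (n_sweeps, 2) ms within sweep
    /pairs/<pair_id>/sweep_start_times  (n_sweeps,) s of experiment time
    /pairs/<pair_id>/access_resistance  (n_sweeps,) MOhm
    /pairs/<pair_id>/epochs             table of (label, start_s, end_s)
        attrs: sampling_rate_khz, holding_potential_mv, ...

Ground truth travels in a JSON sidecar written next to the container.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import h5py
import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .params import ModulationScenario, NeuronParams, SynapseParams

EPOCH_DTYPE = np.dtype([("label", "S16"), ("start", "f8"), ("end", "f8")])


@dataclass
class CurrentStepRecording:
    """Voltage responses of one cell to an ascending family of current steps."""

    cell_id: str
    sampling_rate: float  # kHz
    step_onset: float  # ms
    step_offset: float  # ms
    injected_current: np.ndarray  # (n_sweeps,) pA, ascending
    voltage: np.ndarray  # (n_sweeps, n_samples) mV
    cell_class: Optional[str] = None  # ground-truth label if simulated

    def __post_init__(self) -> None:
        self.injected_current = np.asarray(self.injected_current, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.voltage.ndim != 2 or len(self.injected_current) != self.voltage.shape[0]:
            raise InvalidParameterError("one voltage trace per injected current required")
        if np.any(np.diff(self.injected_current) <= 0):
            raise InvalidParameterError("sweeps must be ordered by ascending current")

    @property
    def n_sweeps(self) -> int:
        return self.voltage.shape[0]

    @property
    def time(self) -> np.ndarray:
        """Shared time base in ms."""
        return np.arange(self.voltage.shape[1]) / self.sampling_rate


@dataclass
class Epoch:
    label: str  # baseline | agonist | washout
    start: float  # s
    end: float  # s


@dataclass
class PairedRecording:
    """Postsynaptic voltage-clamp sweeps evoked by paired presynaptic spikes."""

    pair_id: str
    sampling_rate: float  # kHz
    holding_potential: float  # mV
    current: np.ndarray  # (n_sweeps, n_samples) pA
    stim_times: np.ndarray  # (n_sweeps, 2) ms within sweep
    presyn_peak_times: np.ndarray  # (n_sweeps, 2) ms within sweep
    sweep_start_times: np.ndarray  # (n_sweeps,) s of experiment time
    access_resistance: np.ndarray  # (n_sweeps,) MOhm
    epochs: list[Epoch] = field(default_factory=list)
    test_pulse_window: Optional[tuple[float, float]] = None  # ms within sweep
    test_pulse_amp: float = 0.0  # mV
    holding_window: Optional[tuple[float, float]] = None  # ms within sweep

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.stim_times.ndim != 2 or self.stim_times.shape[1] != 2:
            raise InvalidParameterError("exactly two stimuli per sweep required")
        starts = [e.start for e in self.epochs]
        if any(e.end <= e.start for e in self.epochs) or sorted(starts) != starts:
            raise InvalidParameterError("epochs must be ordered and non-degenerate")

    @property
    def n_sweeps(self) -> int:
        return self.current.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.current.shape[1]) / self.sampling_rate

    def epoch_of(self, t_seconds: float) -> Optional[str]:
        for e in self.epochs:
            if e.start <= t_seconds < e.end:
                return e.label
        return None


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated connection."""

    pair_id: str
    synapse: SynapseParams
    scenario: ModulationScenario
    neuron: Optional[NeuronParams] = None  # postsynaptic clamped cell
    released_quanta: Optional[np.ndarray] = None  # (n_sweeps, 2)
    true_category: str = "no_change"

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "pair_id": self.pair_id,
            "synapse": dataclasses.asdict(self.synapse),
            "scenario": dataclasses.asdict(self.scenario),
            "true_category": self.true_category,
        }
        if self.neuron is not None:
            d["neuron"] = dataclasses.asdict(self.neuron)
        if self.released_quanta is not None:
            d["released_quanta"] = np.asarray(self.released_quanta).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GroundTruth":
        return cls(
            pair_id=d["pair_id"],
            synapse=SynapseParams(**d["synapse"]),
            scenario=ModulationScenario(**d["scenario"]),
            neuron=NeuronParams(**d["neuron"]) if "neuron" in d else None,
            released_quanta=(
                np.asarray(d["released_quanta"]) if "released_quanta" in d else None
            ),
            true_category=d.get("true_category", "no_change"),
        )


# --------------------------------------------------------------------------
# HDF5 container
# --------------------------------------------------------------------------


def write_container(
    path: str | Path,
    cells: list[CurrentStepRecording] = (),
    pairs: list[PairedRecording] = (),
    mode: str = "w",
) -> None:
    with h5py.File(path, mode) as f:
        for rec in cells:
            g = f.require_group("cells").create_group(rec.cell_id)
            g.create_dataset("voltage", data=rec.voltage, compression="gzip")
            g.create_dataset("injected_current", data=rec.injected_current)
            g.attrs["sampling_rate_khz"] = rec.sampling_rate
            g.attrs["step_onset_ms"] = rec.step_onset
            g.attrs["step_offset_ms"] = rec.step_offset
            g.attrs["units_voltage"] = "mV"
            g.attrs["units_current"] = "pA"
            if rec.cell_class is not None:
                g.attrs["cell_class"] = rec.cell_class
        for pr in pairs:
            g = f.require_group("pairs").create_group(pr.pair_id)
            g.create_dataset("current", data=pr.current, compression="gzip")
            g.create_dataset("stim_times", data=pr.stim_times)
            g.create_dataset("presyn_peak_times", data=pr.presyn_peak_times)
            g.create_dataset("sweep_start_times", data=pr.sweep_start_times)
            g.create_dataset("access_resistance", data=pr.access_resistance)
            ep = np.array(
                [(e.label.encode(), e.start, e.end) for e in pr.epochs], dtype=EPOCH_DTYPE
            )
            g.create_dataset("epochs", data=ep)
            g.attrs["sampling_rate_khz"] = pr.sampling_rate
            g.attrs["holding_potential_mv"] = pr.holding_potential
            g.attrs["units_current"] = "pA"
            if pr.test_pulse_window is not None:
                g.attrs["test_pulse_window_ms"] = pr.test_pulse_window
                g.attrs["test_pulse_amp_mv"] = pr.test_pulse_amp
            if pr.holding_window is not None:
                g.attrs["holding_window_ms"] = pr.holding_window


def read_container(
    path: str | Path,
) -> tuple[list[CurrentStepRecording], list[PairedRecording]]:
    cells: list[CurrentStepRecording] = []
    pairs: list[PairedRecording] = []
    with h5py.File(path, "r") as f:
        for cid, g in f.get("cells", {}).items():
            cells.append(
                CurrentStepRecording(
                    cell_id=cid,
                    sampling_rate=float(g.attrs["sampling_rate_khz"]),
                    step_onset=float(g.attrs["step_onset_ms"]),
                    step_offset=float(g.attrs["step_offset_ms"]),
                    injected_current=g["injected_current"][...],
                    voltage=g["voltage"][...],
                    cell_class=g.attrs.get("cell_class"),
                )
            )
        for pid, g in f.get("pairs", {}).items():
            epochs = [
                Epoch(label=row["label"].decode(), start=float(row["start"]), end=float(row["end"]))
                for row in g["epochs"][...]
            ]
            tp = g.attrs.get("test_pulse_window_ms")
            hw = g.attrs.get("holding_window_ms")
            pairs.append(
                PairedRecording(
                    pair_id=pid,
                    sampling_rate=float(g.attrs["sampling_rate_khz"]),
                    holding_potential=float(g.attrs["holding_potential_mv"]),
                    current=g["current"][...],
                    stim_times=g["stim_times"][...],
                    presyn_peak_times=g["presyn_peak_times"][...],
                    sweep_start_times=g["sweep_start_times"][...],
                    access_resistance=g["access_resistance"][...],
                    epochs=epochs,
                    test_pulse_window=tuple(tp) if tp is not None else None,
                    test_pulse_amp=float(g.attrs.get("test_pulse_amp_mv", 0.0)),
                    holding_window=tuple(hw) if hw is not None else None,
                )
            )
    cells.sort(key=lambda r: r.cell_id)
    pairs.sort(key=lambda r: r.pair_id)
    return cells, pairs


def write_ground_truth(path: str | Path, truths: list[GroundTruth]) -> None:
    payload = {gt.pair_id: gt.to_dict() for gt in truths}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict[str, GroundTruth]:
    payload = json.loads(Path(path).read_text())
    return {pid: GroundTruth.from_dict(d) for pid, d in payload.items()}


def sweep_to_csv(path: str | Path, time_ms: np.ndarray, values: np.ndarray, value_name: str) -> None:
    """Plain-text export of a single sweep as (time, value) columns."""
    pd.DataFrame({"time_ms": time_ms, value_name: values}).to_csv(path, index=False)


def read_sweep_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time, value) sweep CSV back; returns (time_ms, values)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidParameterError("sweep CSV needs a time column and a value column")
    return df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)


def steps_from_sweep_csvs(
    cell_id: str,
    paths: list[str | Path],
    injected_current: np.ndarray,
    step_onset: float,
    step_offset: float,
) -> CurrentStepRecording:
    """Assemble a step recording from per-sweep CSV files (shared time base)."""
    traces, time_ms = [], None
    for p in paths:
        t, v = read_sweep_csv(p)
        if time_ms is None:
            time_ms = t
        elif not np.allclose(t, time_ms):
            raise InvalidParameterError("all sweeps must share the same time base")
        traces.append(v)
    if time_ms is None or len(time_ms) < 2:
        raise InvalidParameterError("no sweep data found")
    sampling_rate = 1.0 / float(np.median(np.diff(time_ms)))
    return CurrentStepRecording(
        cell_id=cell_id,
        sampling_rate=sampling_rate,
        step_onset=step_onset,
        step_offset=step_offset,
        injected_current=np.asarray(injected_current, dtype=float),
        voltage=np.vstack(traces),
    )
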