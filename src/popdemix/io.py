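"""On-disk formats: long CSV (canonical), HDF5 tensor container, design JSON.

The canonical CSV is one row per (neuron, trial, bin) with header
``neuron_id,trial_id,parameter_level,visual_level,bin_index,rate_hz``;
trial ids run 0..r-1 within each (neuron, condition) cell.  The HDF5
container stores ``/rates`` of shape (N, S, V, T, maxTrials) with a boolean
``/mask`` for valid trial slots, neuron ids, and the design as a JSON
attribute.  Rates are written to CSV with 17 significant digits so the two
formats round-trip bit-exactly.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .designs import TaskDesign
from .recording import NeuronRecord, PopulationRecording, Trial

__all__ = [
    "write_csv",
    "read_csv",
    "write_hdf5",
    "read_hdf5",
    "recording_to_frame",
    "frame_to_recording",
]

CSV_COLUMNS = [
    "neuron_id",
    "trial_id",
    "parameter_level",
    "visual_level",
    "bin_index",
    "rate_hz",
]


def recording_to_frame(recording: PopulationRecording) -> pd.DataFrame:
    d = recording.design
    T = d.n_bins
    rows_id, rows_trial, rows_p, rows_v = [], [], [], []
    rates = []
    for neuron in recording.neurons:
        seen: dict[tuple[str, str], int] = {}
        # Stable order: condition cells in design order, trials in recorded order.
        by_cell: dict[tuple[str, str], list[np.ndarray]] = {}
        for trial in neuron.trials:
            by_cell.setdefault((trial.parameter_level, trial.visual_level), []).append(
                np.asarray(trial.rates, float)
            )
        for p_level in d.parameter_levels:
            for v_level in d.visual_levels:
                for tid, r in enumerate(by_cell.get((p_level, v_level), [])):
                    rows_id.append(neuron.neuron_id)
                    rows_trial.append(tid)
                    rows_p.append(p_level)
                    rows_v.append(v_level)
                    rates.append(r)
    n_rows = len(rates)
    frame = pd.DataFrame(
        {
            "neuron_id": np.repeat(rows_id, T),
            "trial_id": np.repeat(rows_trial, T),
            "parameter_level": np.repeat(rows_p, T),
            "visual_level": np.repeat(rows_v, T),
            "bin_index": np.tile(np.arange(T), n_rows),
            "rate_hz": np.concatenate(rates) if rates else np.array([]),
        }
    )
    return frame


def frame_to_recording(frame: pd.DataFrame, design: TaskDesign) -> PopulationRecording:
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"CSV missing columns {sorted(missing)}")
    T = design.n_bins
    neurons: list[NeuronRecord] = []
    counts = []
    for neuron_id, nf in frame.groupby("neuron_id", sort=False):
        trials: list[Trial] = []
        for (p_level, v_level, _tid), tf in nf.groupby(
            ["parameter_level", "visual_level", "trial_id"], sort=True
        ):
            tf = tf.sort_values("bin_index")
            rates = tf["rate_hz"].to_numpy(float)
            if rates.shape != (T,):
                raise ValueError(
                    f"neuron {neuron_id}: trial has {rates.shape[0]} bins, expected {T}"
                )
            trials.append(Trial(str(p_level), str(v_level), rates))
            counts.append(1)
        # Re-order trials into design cell order for determinism.
        order = {
            (p, v): i
            for i, (p, v) in enumerate(
                (p, v) for p in design.parameter_levels for v in design.visual_levels
            )
        }
        trials.sort(key=lambda t: order[(t.parameter_level, t.visual_level)])
        neurons.append(NeuronRecord(neuron_id=str(neuron_id), trials=trials))
    rec = PopulationRecording(design=design, neurons=neurons)
    cell_counts = rec.trial_counts()
    rec.min_trials = int(cell_counts.min())
    rec.max_trials = int(cell_counts.max())
    return rec


def write_csv(recording: PopulationRecording, path) -> None:
    recording_to_frame(recording).to_csv(path, index=False, float_format="%.17g")


def read_csv(path, design: TaskDesign) -> PopulationRecording:
    # round_trip parsing: the default fast float parser loses the last ulp,
    # breaking bit-exact CSV <-> HDF5 conversion.
    return frame_to_recording(
        pd.read_csv(path, float_precision="round_trip"), design
    )


def write_hdf5(recording: PopulationRecording, path) -> None:
    d = recording.design
    N = recording.n_neurons
    S, V, T = d.n_parameter_levels, d.n_visual_levels, d.n_bins
    counts = recording.trial_counts()
    R = int(counts.max())
    rates = np.zeros((N, S, V, T, R))
    mask = np.zeros((N, S, V, R), bool)
    for i, neuron in enumerate(recording.neurons):
        slot = np.zeros((S, V), int)
        for trial in neuron.trials:
            s = d.parameter_index(trial.parameter_level)
            v = d.visual_index(trial.visual_level)
            r = slot[s, v]
            rates[i, s, v, :, r] = trial.rates
            mask[i, s, v, r] = True
            slot[s, v] += 1
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rates", data=rates)
        fh.create_dataset("mask", data=mask)
        fh.create_dataset(
            "neuron_ids",
            data=np.array([n.neuron_id for n in recording.neurons], dtype="S"),
        )
        fh.attrs["design"] = json.dumps(d.to_dict(), sort_keys=True)
        fh.attrs["min_trials"] = recording.min_trials
        fh.attrs["max_trials"] = recording.max_trials


def read_hdf5(path) -> PopulationRecording:
    with h5py.File(path, "r") as fh:
        rates = fh["rates"][...]
        mask = fh["mask"][...]
        neuron_ids = [s.decode() for s in fh["neuron_ids"][...]]
        design = TaskDesign.from_dict(json.loads(fh.attrs["design"]))
        min_trials = int(fh.attrs["min_trials"])
        max_trials = int(fh.attrs["max_trials"])
    N, S, V, T, R = rates.shape
    neurons = []
    for i in range(N):
        trials: list[Trial] = []
        for s in range(S):
            for v in range(V):
                for r in range(R):
                    if mask[i, s, v, r]:
                        trials.append(
                            Trial(
                                design.parameter_levels[s],
                                design.visual_levels[v],
                                rates[i, s, v, :, r].copy(),
                            )
                        )
        neurons.append(NeuronRecord(neuron_id=neuron_ids[i], trials=trials))
    return PopulationRecording(
        design=design, neurons=neurons, min_trials=min_trials, max_trials=max_trials
    )
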