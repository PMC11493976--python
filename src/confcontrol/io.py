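"""File formats: evidence traces and trial tables as CSV, epochs as HDF5."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .encoding import SensorEpochs
from .evidence import EvidenceTrace


def save_traces_csv(traces: dict, path):
    """Write a stimulus bank to one long CSV (one row per stimulus frame)."""
    rows = []
    for sid, tr in traces.items():
        n = tr.n_frames
        rows.append(pd.DataFrame({
            "stimulus_id": sid, "condition_id": tr.condition_id,
            "side": tr.side, "frame": np.arange(n),
            "time_s": (np.arange(n) + 1) * tr.dt,
            "nu_left": tr.nu_left, "nu_right": tr.nu_right,
            "circ_var": tr.circ_var,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def load_traces_csv(path) -> dict:
    df = pd.read_csv(path)
    traces = {}
    for sid, grp in df.groupby("stimulus_id", sort=False):
        grp = grp.sort_values("frame")
        traces[sid] = EvidenceTrace(
            nu_left=grp["nu_left"].to_numpy(),
            nu_right=grp["nu_right"].to_numpy(),
            circ_var=grp["circ_var"].to_numpy(),
            stimulus_id=sid, condition_id=grp["condition_id"].iloc[0],
            side=grp["side"].iloc[0],
        )
    return traces


def save_epochs_h5(epochs: SensorEpochs, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = epochs.sfreq
        f.create_dataset("labels", data=np.array(epochs.labels, dtype="S"))


def load_epochs_h5(path) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        return SensorEpochs(
            data=f["data"][()], times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            labels=[s.decode() for s in f["labels"][()]],
        )


def save_fit_json(fit_result, path):
    Path(path).write_text(json.dumps(fit_result.to_dict(), indent=2))


def load_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())
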