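"""File formats: response tables (TSV), recordings/evoked (HDF5), reports (JSON).

Recordings use a simple hierarchical layout::

    /subjects/<id>/data      (channels x samples, float64)
    /subjects/<id>/events    (structured: sample, stimulus_id, category, task)
    attrs: sample_rate, modality, ch_names (on the data group)

Evoked sets store per-subject condition averages with their cell labels and
counts; everything round-trips losslessly through :func:`save_recordings`
/ :func:`load_recordings` and the evoked equivalents.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocessing import EvokedSet, Recording

RESPONSE_COLUMNS = [
    "subject_id", "group", "task", "trial_index",
    "stimulus_id", "bmi", "category", "response",
]


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses[RESPONSE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response table misses columns: {sorted(missing)}")
    return df


def write_bpi_table(bpi: pd.DataFrame, path: str | Path) -> None:
    bpi.to_csv(path, sep="\t", index=False)


def _events_to_struct(events: pd.DataFrame) -> np.ndarray:
    return np.array(
        list(
            zip(
                events["sample"].astype(np.int64),
                events["stimulus_id"].astype(np.int64),
                events["category"].astype(str),
                events["task"].astype(str),
            )
        ),
        dtype=[("sample", "i8"), ("stimulus_id", "i8"),
               ("category", "S8"), ("task", "S16")],
    )


def _events_from_struct(arr: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": arr["sample"].astype(int),
            "stimulus_id": arr["stimulus_id"].astype(int),
            "category": [c.decode() for c in arr["category"]],
            "task": [t.decode() for t in arr["task"]],
        }
    )


def save_recordings(recordings: Mapping[str, Recording], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for sid, rec in recordings.items():
            g = root.create_group(str(sid))
            g.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
            g.create_dataset("events", data=_events_to_struct(rec.events))
            g.attrs["sample_rate"] = rec.sample_rate
            g.attrs["modality"] = rec.modality
            g.attrs["ch_names"] = [n.encode() for n in rec.ch_names]


def load_recordings(path: str | Path) -> dict[str, Recording]:
    out: dict[str, Recording] = {}
    with h5py.File(path, "r") as f:
        for sid, g in f["subjects"].items():
            out[sid] = Recording(
                data=g["data"][()],
                sample_rate=float(g.attrs["sample_rate"]),
                events=_events_from_struct(g["events"][()]),
                ch_names=[n.decode() if isinstance(n, bytes) else str(n)
                          for n in g.attrs.get("ch_names", [])],
                modality=str(g.attrs.get("modality", "meg")),
            )
    return out


def save_evoked(evoked: Mapping[str, EvokedSet], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for sid, ev in evoked.items():
            g = root.create_group(str(sid))
            g.create_dataset("data", data=ev.data, compression="gzip", compression_opts=1)
            g.create_dataset("times", data=ev.times)
            g.create_dataset("counts", data=ev.counts)
            g.attrs["sample_rate"] = ev.sample_rate
            g.attrs["cell_columns"] = list(ev.cells.columns)
            for col in ev.cells.columns:
                g.create_dataset(f"cells_{col}",
                                 data=[str(v).encode() for v in ev.cells[col]])


def load_evoked(path: str | Path) -> dict[str, EvokedSet]:
    out: dict[str, EvokedSet] = {}
    with h5py.File(path, "r") as f:
        for sid, g in f["subjects"].items():
            cols = list(g.attrs["cell_columns"])
            cells = pd.DataFrame(
                {c: [v.decode() for v in g[f"cells_{c}"][()]] for c in cols}
            )
            out[sid] = EvokedSet(
                data=g["data"][()],
                times=g["times"][()],
                sample_rate=float(g.attrs["sample_rate"]),
                cells=cells,
                counts=g["counts"][()],
            )
    return out


def load_config_file(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_config_file(config: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True, cls=_NumpyEncoder)
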