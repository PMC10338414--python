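"""Readers and writers for the pipeline's external formats.

EEG comes in as EDF (via mne, when installed) or CSV (first column time in
seconds, one further column per channel, header row of channel names).  RR
intervals are single-column text (ms) or two-column CSV (t, rr_ms).  Spike
trains serialize to columnar (channel, t_index, polarity) triples; trained
cubes to a single HDF5 container with a content hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import SpikeTrains
from .hrv import RRSeries
from .reservoir import LIFConfig, ReservoirCube, SWCConfig
from .synth import Recording
from .template import BrainTemplate

__all__ = [
    "read_eeg_csv",
    "write_eeg_csv",
    "read_eeg_edf",
    "read_rr",
    "write_rr",
    "save_spiketrains",
    "load_spiketrains",
    "save_cube",
    "load_cube",
]


def write_eeg_csv(rec: Recording, path: str | Path) -> None:
    """CSV with time first; markers go to a JSON sidecar (<path>.markers.json)."""
    t = np.arange(rec.data.shape[1]) / rec.rate
    df = pd.DataFrame({"time": t} | {c: rec.data[i] for i, c in enumerate(rec.channels)})
    df.to_csv(path, index=False, float_format="%.6g")
    side = Path(str(path) + ".markers.json")
    side.write_text(json.dumps({"label": rec.label, "markers": rec.markers}))


def read_eeg_csv(path: str | Path) -> Recording:
    df = pd.read_csv(path)
    if df.columns[0].lower() not in ("time", "t"):
        raise ValueError("first CSV column must be time in seconds")
    t = df.iloc[:, 0].to_numpy(dtype=np.float64)
    if len(t) < 2:
        raise ValueError("recording too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    channels = list(df.columns[1:])
    data = df.iloc[:, 1:].to_numpy(dtype=np.float64).T
    side = Path(str(path) + ".markers.json")
    markers, label = {}, -1
    if side.exists():
        meta = json.loads(side.read_text())
        markers, label = meta.get("markers", {}), meta.get("label", -1)
    return Recording(Path(path).stem, data, channels, rate, markers, label)


def read_eeg_edf(path: str | Path) -> Recording:
    """EDF via mne (optional dependency)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF support requires mne (pip install spikecube[edf])") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        Path(path).stem, raw.get_data(), list(raw.ch_names),
        float(raw.info["sfreq"]), {}, -1,
    )


def write_rr(rr: RRSeries, path: str | Path) -> None:
    np.savetxt(path, rr.intervals, fmt="%.6g")


def read_rr(path: str | Path, t0: float = 0.0) -> RRSeries:
    arr = np.loadtxt(path, delimiter=None, ndmin=2)
    intervals = arr[:, -1]  # single column, or (t, rr_ms)
    return RRSeries(intervals, t0=t0, subject=Path(path).stem)


def save_spiketrains(trains: SpikeTrains, path: str | Path) -> None:
    ch, ti = np.nonzero(trains.events)
    df = pd.DataFrame(
        {
            "channel": [trains.channels[c] for c in ch],
            "t_index": ti,
            "polarity": trains.events[ch, ti],
        }
    )
    with open(path, "w") as f:
        f.write(f"# rate={trains.rate} length={trains.length} "
                f"channels={','.join(trains.channels)}\n")
        df.to_csv(f, index=False)


def load_spiketrains(path: str | Path) -> SpikeTrains:
    with open(path) as f:
        header = f.readline().strip().lstrip("# ")
        meta = dict(kv.split("=", 1) for kv in header.split(" "))
        df = pd.read_csv(f)
    channels = meta["channels"].split(",")
    events = np.zeros((len(channels), int(meta["length"])), dtype=np.int8)
    pos = {c: i for i, c in enumerate(channels)}
    for _, row in df.iterrows():
        events[pos[row["channel"]], int(row["t_index"])] = int(row["polarity"])
    return SpikeTrains(channels, events, float(meta["rate"]))


def save_cube(cube: ReservoirCube, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("indptr", data=cube.indptr)
        f.create_dataset("indices", data=cube.indices)
        f.create_dataset("w", data=cube.w)
        f.create_dataset("d", data=cube.d)
        f.create_dataset("coords", data=cube.template.coords)
        f.create_dataset("input_indices", data=cube.template.input_indices)
        f.attrs["channels"] = json.dumps(cube.template.channels)
        f.attrs["swc"] = json.dumps(vars(cube.swc))
        f.attrs["lif"] = json.dumps(vars(cube.lif))
        f.attrs["init_id"] = cube.init_id
        f.attrs["trained_on"] = cube.trained_on or ""
        f.attrs["sha256"] = hashlib.sha256(cube.w.tobytes()).hexdigest()


def load_cube(path: str | Path) -> ReservoirCube:
    import h5py

    with h5py.File(path, "r") as f:
        w = f["w"][...]
        if hashlib.sha256(w.tobytes()).hexdigest() != f.attrs["sha256"]:
            raise ValueError("cube file corrupt: content hash mismatch")
        tpl = BrainTemplate(
            f["coords"][...],
            json.loads(f.attrs["channels"]),
            f["input_indices"][...],
        )
        return ReservoirCube(
            tpl, f["indptr"][...], f["indices"][...], w, f["d"][...],
            SWCConfig(**json.loads(f.attrs["swc"])),
            LIFConfig(**json.loads(f.attrs["lif"])),
            str(f.attrs["init_id"]),
            str(f.attrs["trained_on"]) or None,
        )
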