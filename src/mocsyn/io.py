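"""File I/O for the package's exchange formats.

Sweep sets travel as HDF5 (traces dataset + scalar attrs) or CSV for small
fixtures; event/cluster tables as TSV; generator and channel configurations
as YAML; calcium movies as HDF5 with ROI polygons in JSON.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .events import SweepSet
from .model import ChannelSet
from .synth import CalciumGenSpec, ClusterGenSpec, SweepGenSpec

__all__ = [
    "save_sweep_set",
    "load_sweep_set",
    "sweep_set_to_csv",
    "sweep_set_from_csv",
    "save_table",
    "load_table",
    "save_sweep_spec",
    "load_sweep_spec",
    "save_calcium_spec",
    "load_calcium_spec",
    "save_channels",
    "load_channels",
    "save_movie",
    "load_movie",
    "save_rois",
    "load_rois",
]


def save_sweep_set(path, sweep_set: SweepSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=sweep_set.traces)
        f.attrs["dt_ms"] = sweep_set.dt
        f.attrs["holding_mV"] = sweep_set.holding_potential
        f.attrs["stim_times_ms"] = np.asarray(sweep_set.stim_times, dtype=float)
        f.attrs["metadata"] = json.dumps(sweep_set.metadata, default=str)


def load_sweep_set(path) -> SweepSet:
    with h5py.File(path, "r") as f:
        return SweepSet(
            traces=f["traces"][...],
            dt=float(f.attrs["dt_ms"]),
            holding_potential=float(f.attrs["holding_mV"]),
            stim_times=np.asarray(f.attrs["stim_times_ms"], dtype=float),
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )


def sweep_set_to_csv(path, sweep_set: SweepSet) -> None:
    """Small-fixture CSV: one column per sweep, header carries the attrs."""
    df = pd.DataFrame(sweep_set.traces.T,
                      columns=[f"sweep{i}" for i in range(sweep_set.n_sweeps)])
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={sweep_set.dt} holding_mV={sweep_set.holding_potential} "
                 f"stim_times_ms={','.join(map(str, sweep_set.stim_times))}\n")
        df.to_csv(fh, index=False)


def sweep_set_from_csv(path) -> SweepSet:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        df = pd.read_csv(fh)
    return SweepSet(
        traces=df.to_numpy(dtype=float).T,
        dt=float(meta["dt_ms"]),
        holding_potential=float(meta["holding_mV"]),
        stim_times=np.array([float(x) for x in meta["stim_times_ms"].split(",")]),
    )


def save_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_sweep_spec(path, spec: SweepGenSpec) -> None:
    d = dataclasses.asdict(spec)
    d["clusters"] = [dataclasses.asdict(c) for c in spec.clusters]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_sweep_spec(path) -> SweepGenSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["clusters"] = tuple(ClusterGenSpec(**c) for c in d.get("clusters", []))
    for key in ("stim_times",):
        if key in d:
            d[key] = tuple(d[key])
    return SweepGenSpec(**d)


def save_calcium_spec(path, spec: CalciumGenSpec) -> None:
    d = dataclasses.asdict(spec)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_calcium_spec(path) -> CalciumGenSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("stim_bout_frames", "frame_shape"):
        if key in d:
            d[key] = tuple(d[key])
    return CalciumGenSpec(**d)


def save_channels(path, channels: ChannelSet, extra: dict | None = None) -> None:
    doc = {"channels": dataclasses.asdict(channels)}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_channels(path) -> ChannelSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ChannelSet(**doc["channels"])


def save_movie(path, movie: np.ndarray, frame_rate: float) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=movie)
        f.attrs["frame_rate_hz"] = frame_rate


def load_movie(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        return f["frames"][...], float(f.attrs["frame_rate_hz"])


def save_rois(path, polygons) -> None:
    with open(path, "w") as fh:
        json.dump([np.asarray(p).tolist() for p in polygons], fh)


def load_rois(path) -> list[np.ndarray]:
    with open(path) as fh:
        return [np.asarray(p, dtype=float) for p in json.load(fh)]
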