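"""Plain-text and HDF5 serialization for pipeline inputs and outputs.

Event schedules travel as a TSV trial table plus a JSON sidecar (rest
windows and task constants); arrays (simulated sensor recordings, envelope
datasets) go into HDF5 with sampling-rate/seed attributes; network maps and
sensor geometry are TSV tables; binned beta series and Weibull
decompositions export as tidy CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .beamformer import NetworkMap
from .task import EnvelopeDataset, EventSchedule, GroundTruthParams, Trial
from .weibull import BetaDecomposition, component_auc

__all__ = [
    "save_schedule", "load_schedule",
    "save_envelope_dataset", "load_envelope_dataset",
    "save_sensor_data", "load_sensor_data",
    "save_network_map", "load_network_map",
    "save_sensor_geometry", "load_sensor_geometry",
    "decompositions_to_frame",
]


def save_schedule(schedule: EventSchedule, tsv_path) -> None:
    tsv_path = Path(tsv_path)
    rows = [
        dict(onset_ms=t.onset_ms, block=t.block_index, block_type=t.block_type,
             stimulus_type=t.stimulus_type, relevant=int(t.is_relevant),
             target=int(t.is_target))
        for t in schedule.trials
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False,
                              float_format="%.17g")
    sidecar = dict(
        rest_windows=[[float(a), float(b)] for a, b in schedule.rest_windows],
        stimulus_duration_ms=schedule.stimulus_duration_ms,
        seed=schedule.seed,
    )
    tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_schedule(tsv_path) -> EventSchedule:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    meta = json.loads(tsv_path.with_suffix(".json").read_text())
    trials = tuple(
        Trial(float(r.onset_ms), int(r.block), str(r.block_type),
              str(r.stimulus_type), bool(r.relevant), bool(r.target))
        for r in df.itertuples()
    )
    return EventSchedule(
        trials,
        tuple(tuple(w) for w in meta["rest_windows"]),
        stimulus_duration_ms=meta["stimulus_duration_ms"],
        seed=meta["seed"],
    )


def save_envelope_dataset(ds: EnvelopeDataset, h5_path) -> None:
    with h5py.File(h5_path, "w") as f:
        f.attrs["seed"] = ds.seed
        for (group, subject, network, condition), series in ds.data.items():
            g = f.create_group(f"envelope/{group}/{subject}/{network}/{condition}")
            d = g.create_dataset("series", data=series)
            truth = ds.truth[(group, subject, network, condition)]
            for k, v in dataclasses.asdict(truth).items():
                d.attrs[k] = v


def load_envelope_dataset(h5_path) -> EnvelopeDataset:
    data, truth, subjects = {}, {}, {}
    with h5py.File(h5_path, "r") as f:
        seed = int(f.attrs["seed"])
        env = f["envelope"]
        for group in env:
            subjects[group] = tuple(sorted(env[group]))
            for subject in env[group]:
                for network in env[group][subject]:
                    for condition in env[group][subject][network]:
                        d = env[group][subject][network][condition]["series"]
                        key = (group, subject, network, condition)
                        data[key] = d[()]
                        truth[key] = GroundTruthParams(**dict(d.attrs))
    return EnvelopeDataset(data, truth, subjects, seed)


def save_sensor_data(data: np.ndarray, h5_path, fs: float,
                     positions: np.ndarray | None = None,
                     orientations: np.ndarray | None = None,
                     seed: int | None = None) -> None:
    with h5py.File(h5_path, "w") as f:
        d = f.create_dataset("sensor/data", data=np.asarray(data))
        d.attrs["sampling_rate_hz"] = fs
        if seed is not None:
            d.attrs["seed"] = seed
        if positions is not None:
            f.create_dataset("sensor/positions", data=np.asarray(positions))
        if orientations is not None:
            f.create_dataset("sensor/orientations", data=np.asarray(orientations))


def load_sensor_data(h5_path):
    with h5py.File(h5_path, "r") as f:
        d = f["sensor/data"]
        out = dict(data=d[()], fs=float(d.attrs["sampling_rate_hz"]))
        if "sensor/positions" in f:
            out["positions"] = f["sensor/positions"][()]
        if "sensor/orientations" in f:
            out["orientations"] = f["sensor/orientations"][()]
    return out


def save_network_map(net_map: NetworkMap, tsv_path) -> None:
    df = pd.DataFrame(
        dict(x_mm=net_map.voxels_mm[:, 0], y_mm=net_map.voxels_mm[:, 1],
             z_mm=net_map.voxels_mm[:, 2], weight=net_map.weights)
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def load_network_map(tsv_path, name: str = "") -> NetworkMap:
    df = pd.read_csv(tsv_path, sep="\t")
    return NetworkMap(
        voxels_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        weights=df["weight"].to_numpy(float),
        name=name,
    )


def save_sensor_geometry(positions: np.ndarray, orientations: np.ndarray,
                         tsv_path) -> None:
    pos = np.asarray(positions)
    ori = np.asarray(orientations)
    df = pd.DataFrame(
        dict(x=pos[:, 0], y=pos[:, 1], z=pos[:, 2],
             ox=ori[:, 0], oy=ori[:, 1], oz=ori[:, 2])
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def load_sensor_geometry(tsv_path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(tsv_path, sep="\t")
    return (df[["x", "y", "z"]].to_numpy(float),
            df[["ox", "oy", "oz"]].to_numpy(float))


def decompositions_to_frame(decomps: dict[tuple, BetaDecomposition]
                            ) -> pd.DataFrame:
    """Tidy table of fitted components, one row per (series, component).

    Keys are (subject, group, network, condition) tuples.
    """
    rows = []
    for (subject, group, network, condition), dec in decomps.items():
        for comp_name in ("local", "integrative"):
            comp = getattr(dec, comp_name)
            rows.append(dict(
                subject=subject, group=group, network=network,
                condition=condition, component=comp_name, a_ms=comp.a,
                b=comp.b, coefficient=comp.coefficient,
                auc=component_auc(dec, comp_name),
                peak_latency_ms=comp.peak_latency_ms, ssr=dec.ssr,
                flags=";".join(dec.flags),
            ))
    return pd.DataFrame(rows)
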