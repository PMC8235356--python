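"""Waveform file I/O, image containers and experiment configuration.

Waveform records are stored as a CSV of samples (columns ``time_s``,
``pressure_cmH2O``, ``flow_Lps``, ``volume_L``, ``cycle_id``) plus a JSON
sidecar carrying per-cycle labels, DT-event pairs, the generator seed and
the ventilator settings.  Fused images go into an HDF5 container with
datasets ``images``, ``labels`` and ``cycle_ids``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import (DT_STEP, BreathCycle, VentilatorSettings, WaveformRecord)

CSV_COLUMNS = ("time_s", "pressure_cmH2O", "flow_Lps", "volume_L", "cycle_id")

_MECHANICS_FIELDS = ("resistance", "compliance")


def write_waveform_csv(record: WaveformRecord, path) -> None:
    """Write a record as CSV + JSON sidecar; byte-deterministic."""
    path = Path(path)
    frames = []
    for cyc in record.cycles:
        frames.append(pd.DataFrame({
            "time_s": cyc.t, "pressure_cmH2O": cyc.pressure,
            "flow_Lps": cyc.flow, "volume_L": cyc.volume,
            "cycle_id": cyc.cycle_id}))
    df = pd.concat(frames, ignore_index=True)
    # %.17g keeps full float64 precision so read-back is bit-exact
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")
    sidecar = {
        "labels": {str(c.cycle_id): c.label for c in record.cycles},
        "dt_events": [list(pair) for pair in record.dt_events],
        "seed": record.seed,
        "settings": dataclasses.asdict(record.settings),
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1,
                                             sort_keys=True) + "\n")


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def read_waveform_csv(path) -> WaveformRecord:
    """Read a CSV + sidecar pair back into a record.

    Validates column presence and the 50 Hz sample spacing (to 1e-6 s).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    side = json.loads(sidecar_path(path).read_text())
    labels = {int(k): v for k, v in side["labels"].items()}
    settings = VentilatorSettings(**side["settings"])
    cycles = []
    for cid, sub in df.groupby("cycle_id", sort=True):
        t = sub["time_s"].to_numpy()
        steps = np.diff(t)
        if np.any(np.abs(steps - DT_STEP) > 1e-6):
            raise ValueError(f"cycle {cid}: timestamps are not uniform "
                             "50 Hz samples")
        cycles.append(BreathCycle(
            t=t, pressure=sub["pressure_cmH2O"].to_numpy(),
            flow=sub["flow_Lps"].to_numpy(),
            volume=sub["volume_L"].to_numpy(),
            label=labels[int(cid)], cycle_id=int(cid)))
    return WaveformRecord(
        cycles=cycles,
        dt_events=[tuple(p) for p in side["dt_events"]],
        seed=int(side["seed"]), settings=settings)


def write_images_h5(images, path) -> None:
    """Store fused images in HDF5 (datasets: images, labels, cycle_ids)."""
    x = np.stack([im.pixels for im in images]).astype(np.float32)
    labels = np.array([im.label for im in images], dtype="S8")
    ids = np.array([im.cycle_id for im in images])
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=x, compression="gzip")
        fh.create_dataset("labels", data=labels)
        fh.create_dataset("cycle_ids", data=ids)


def read_images_h5(path) -> tuple:
    with h5py.File(path, "r") as fh:
        x = fh["images"][:]
        labels = [s.decode() for s in fh["labels"][:]]
        ids = fh["cycle_ids"][:]
    return x, labels, ids


def export_png(image_pixels: np.ndarray, path) -> None:
    """8-bit PNG export of a channel or fused image (values x 255)."""
    from PIL import Image
    arr = np.clip(np.asarray(image_pixels) * 255, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path, format="PNG")


@dataclass
class ExperimentConfig:
    """Every knob of the pipeline, with serializable defaults."""

    out_dir: str = "results"
    # generator
    n_dt_events: int = 50
    n_iee: int = 100
    n_other: int = 200
    noise_sd: float = 0.02
    artifact_fraction: float = 0.0
    # task / evaluation
    pos_label: str = "DT"
    model_names: tuple = ("Pr_Tiny_DC", "Rd_Tiny_DC")
    prrs: tuple = (1.0, 0.1, 0.01)
    k: int = 5
    seeds: tuple = (0,)
    int_mode: str = "floor"
    stratify_m1: bool = True
    norm_scope: str = "breath"
    # training
    freeze_extractor: bool = True
    head_epochs: int = 60
    pretrain_epochs: int = 10
    pretrain_n_per_class: int = 40
    lstm_units: int = 16

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: list(v) if isinstance(v, tuple) else v
                for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        clean = {}
        for key, value in data.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            clean[key] = value
        return cls(**clean)
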