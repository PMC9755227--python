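"""Persistence and configuration glue: HDF5 datasets, CSV/JSON artifacts.

A dataset is one HDF5 file with groups ``/trial_<k>/{taxels, piezo,
proprio}`` (float32) and the trial metadata stored as group attributes;
``schema_version`` is a file attribute checked on load.  Spike trains,
feature matrices and innervation maps round-trip through plain CSV so
every artifact stays inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import yaml

from .features_classify import FeatureMatrix
from .encoding import SpikeTrain
from .synth_rig import SensorRecording

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "save_dataset",
    "load_dataset",
    "spike_trains_to_csv",
    "spike_trains_from_csv",
    "feature_matrix_to_csv",
]

SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    """Validated end-to-end run configuration (YAML-loadable).

    Defaults follow the reference acquisition protocol: ten textures, six
    speeds 40-90 mm/s, ten repetitions, 1 kHz sampling, 12:24 SA-I:RA-I
    afferents and 1000-tree Random Forest / k=1 KNN classifiers.
    """

    textures: int = 10
    speeds: list[float] = field(
        default_factory=lambda: [40.0, 50.0, 60.0, 70.0, 80.0, 90.0])
    repetitions: int = 10
    displacement_mm: float = 40.0
    sample_rate: float = 1000.0
    indentation: float = 0.4
    n_sa1: int = 12
    n_ra1: int = 24
    target_mean_innervation: float = 7.2
    classifier: str = "rf"
    n_estimators: int = 1000
    knn_k: int = 1
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.textures < 1 or self.repetitions < 1:
            raise ValueError("textures and repetitions must be >= 1")
        if not self.speeds:
            raise ValueError("speeds must be non-empty")
        if self.classifier not in ("rf", "knn"):
            raise ValueError("classifier must be 'rf' or 'knn'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw)}")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def save_dataset(recordings: list[SensorRecording], path: str | Path) -> None:
    """Write recordings to one HDF5 file (float32, lossless round-trip)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["n_trials"] = len(recordings)
        for k, rec in enumerate(recordings):
            grp = fh.create_group(f"trial_{k:04d}")
            grp.create_dataset("taxels", data=rec.taxels.astype(np.float32))
            grp.create_dataset("piezo", data=rec.piezo.astype(np.float32))
            grp.create_dataset("proprio", data=rec.proprio.astype(np.float32))
            grp.attrs["sample_rate"] = rec.sample_rate
            grp.attrs["meta"] = json.dumps(rec.meta)


def load_dataset(path: str | Path) -> list[SensorRecording]:
    """Read a dataset written by :func:`save_dataset`; validates the schema."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"dataset schema version {version!r} unsupported "
                f"(reader supports {SCHEMA_VERSION!r})")
        n = int(fh.attrs["n_trials"])
        names = sorted(k for k in fh.keys() if k.startswith("trial_"))
        if len(names) != n:
            raise ValueError(
                f"truncated dataset: header says {n} trials, found "
                f"{len(names)}")
        out = []
        for name in names:
            grp = fh[name]
            rec = SensorRecording(
                taxels=np.array(grp["taxels"], dtype=np.float32),
                piezo=np.array(grp["piezo"], dtype=np.float32),
                proprio=np.array(grp["proprio"], dtype=np.float32),
                sample_rate=float(grp.attrs["sample_rate"]),
                meta=json.loads(grp.attrs["meta"]),
            )
            out.append(rec)
    return out


def spike_trains_to_csv(trains: list[SpikeTrain], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("afferent_id,afferent_type,spike_time_s\n")
        for tr in trains:
            for t in tr.spike_times:
                fh.write(f"{tr.afferent_id},{tr.afferent_type},{t:.6f}\n")


def spike_trains_from_csv(path: str | Path, duration: float
                          ) -> list[SpikeTrain]:
    order: list[str] = []
    times: dict[str, list[float]] = {}
    types: dict[str, str] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            aid, atype, t = line.strip().split(",")
            if aid not in times:
                order.append(aid)
                times[aid] = []
                types[aid] = atype
            times[aid].append(float(t))
    return [SpikeTrain(np.array(times[a]), duration, a, types[a])
            for a in order]


def feature_matrix_to_csv(fm: FeatureMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("texture,speed_class," + ",".join(fm.feature_names) + "\n")
        for i in range(fm.n_trials):
            row = ",".join(f"{v:.6f}" for v in fm.X[i])
            fh.write(f"{fm.y_texture[i]},{fm.y_speed_class[i]},{row}\n")
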