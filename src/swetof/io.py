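"""HDF5 container for A-line ensembles / velocity fields, and CSV results.

Container layout (format version 1.0): one group per object type
(``velocity_field``, ``rf_ensemble`` or ``iq_ensemble``) holding a
``values`` dataset plus axis datasets, with every geometry and acquisition
field stored as a group attribute.  Reading back yields an object equal to
the one written.  Results serialize to one CSV row per acquisition with a
fixed, documented column schema.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import ContainerFormatError
from .fields import IQEnsemble, RFEnsemble, ScattererRecord, VelocityField
from .geometry import AcquisitionConfig, FixtureGeometry, SWSEstimate

__all__ = [
    "FORMAT_VERSION",
    "write_container",
    "read_container",
    "ResultRecord",
    "RESULT_COLUMNS",
    "write_records",
    "read_records",
    "config_hash",
]

FORMAT_VERSION = "1.0"

_GEOM_FIELDS = (
    "one_way_distances",
    "focal_length",
    "face_to_container_bottom",
    "sample_width",
    "sample_length",
    "f_number",
)
_ACQ_FIELDS = (
    "center_frequency",
    "prf",
    "n_frames",
    "rf_sampling_rate",
    "push_cycles",
    "push_duration",
    "compressional_sound_speed",
)


def _write_metadata(group: h5py.Group, obj) -> None:
    group.attrs["format_version"] = FORMAT_VERSION
    for name in _GEOM_FIELDS:
        group.attrs[f"geometry.{name}"] = getattr(obj.geometry, name)
    for name in _ACQ_FIELDS:
        group.attrs[f"acquisition.{name}"] = getattr(obj.acquisition, name)


def _read_metadata(group: h5py.Group) -> tuple[FixtureGeometry, AcquisitionConfig]:
    gkw = {}
    for name in _GEOM_FIELDS:
        val = group.attrs[f"geometry.{name}"]
        gkw[name] = tuple(float(x) for x in val) if name == "one_way_distances" else float(val)
    akw = {}
    for name in _ACQ_FIELDS:
        val = group.attrs[f"acquisition.{name}"]
        akw[name] = int(val) if name in ("n_frames", "push_cycles") else float(val)
    return FixtureGeometry(**gkw), AcquisitionConfig(**akw)


def write_container(path: str | Path, obj: VelocityField | RFEnsemble | IQEnsemble) -> None:
    """Write one acquisition object to an HDF5 container at ``path``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        if isinstance(obj, VelocityField):
            g = f.create_group("velocity_field")
            g.create_dataset("values", data=obj.values)
            g.create_dataset("depth_axis_mm", data=obj.depth_axis_mm)
            g.create_dataset("time_axis_ms", data=obj.time_axis_ms)
            g.attrs["flags"] = json.dumps(list(obj.flags))
        elif isinstance(obj, RFEnsemble):
            g = f.create_group("rf_ensemble")
            g.create_dataset("values", data=obj.values)
            g.attrs["rf_sampling_rate"] = obj.rf_sampling_rate
            g.attrs["fast_time_offset_s"] = obj.fast_time_offset_s
            if obj.scatterers is not None:
                s = g.create_group("scatterers")
                s.create_dataset("positions_mm", data=obj.scatterers.positions_mm)
                s.create_dataset("amplitudes", data=obj.scatterers.amplitudes)
                s.attrs["seed"] = obj.scatterers.seed
        elif isinstance(obj, IQEnsemble):
            g = f.create_group("iq_ensemble")
            g.create_dataset("values", data=obj.values)
            g.attrs["demodulation_frequency"] = obj.demodulation_frequency
            g.attrs["sampling_rate"] = obj.sampling_rate
            g.attrs["fast_time_offset_s"] = obj.fast_time_offset_s
        else:
            raise ContainerFormatError(f"unsupported object type {type(obj).__name__}")
        _write_metadata(g, obj)


def _check_version(group: h5py.Group) -> None:
    version = str(group.attrs.get("format_version", ""))
    if not version:
        raise ContainerFormatError("container has no format_version attribute")
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise ContainerFormatError(
            f"container version {version} incompatible with reader {FORMAT_VERSION}"
        )


def read_container(path: str | Path) -> VelocityField | RFEnsemble | IQEnsemble:
    """Read back whatever object type the container holds."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        known = [k for k in ("velocity_field", "rf_ensemble", "iq_ensemble") if k in f]
        if not known:
            raise ContainerFormatError(
                f"no recognized object group in {path.name}; groups: {list(f)}"
            )
        kind = known[0]
        g = f[kind]
        _check_version(g)
        if "values" not in g:
            raise ContainerFormatError(f"group '{kind}' is missing dataset 'values'")
        geometry, acquisition = _read_metadata(g)
        if kind == "velocity_field":
            for ds in ("depth_axis_mm", "time_axis_ms"):
                if ds not in g:
                    raise ContainerFormatError(f"group '{kind}' is missing dataset '{ds}'")
            return VelocityField(
                values=g["values"][()],
                depth_axis_mm=g["depth_axis_mm"][()],
                time_axis_ms=g["time_axis_ms"][()],
                geometry=geometry,
                acquisition=acquisition,
                flags=tuple(json.loads(g.attrs.get("flags", "[]"))),
            )
        if kind == "rf_ensemble":
            scatterers = None
            if "scatterers" in g:
                s = g["scatterers"]
                scatterers = ScattererRecord(
                    positions_mm=s["positions_mm"][()],
                    amplitudes=s["amplitudes"][()],
                    seed=int(s.attrs["seed"]),
                )
            return RFEnsemble(
                values=g["values"][()],
                rf_sampling_rate=float(g.attrs["rf_sampling_rate"]),
                fast_time_offset_s=float(g.attrs["fast_time_offset_s"]),
                geometry=geometry,
                acquisition=acquisition,
                scatterers=scatterers,
            )
        return IQEnsemble(
            values=g["values"][()],
            demodulation_frequency=float(g.attrs["demodulation_frequency"]),
            sampling_rate=float(g.attrs["sampling_rate"]),
            fast_time_offset_s=float(g.attrs["fast_time_offset_s"]),
            geometry=geometry,
            acquisition=acquisition,
        )


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "sample_id",
    "timestamp_label",
    "mean_sws",
    "s_1",
    "s_2",
    "s_3",
    "s_4",
    "t_1",
    "t_2",
    "t_3",
    "t_4",
    "variance",
    "initial_estimate",
    "flags",
    "config_hash",
    "seed",
)


def config_hash(payload: dict) -> str:
    """Short deterministic hash of a configuration mapping."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ResultRecord:
    """One SWS measurement, serializable to a single CSV row."""

    sample_id: str
    mean_sws: float
    per_path_speeds: tuple[float, float, float, float]
    arrival_times: tuple[float, float, float, float]
    variance: float
    initial_estimate: float | None = None
    timestamp_label: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)
    config_hash: str = ""
    seed: int = 0

    @classmethod
    def from_estimate(
        cls,
        sample_id: str,
        estimate: SWSEstimate,
        timestamp_label: str = "",
        config_hash: str = "",
        seed: int = 0,
    ) -> "ResultRecord":
        return cls(
            sample_id=sample_id,
            mean_sws=estimate.mean_sws,
            per_path_speeds=estimate.per_path_speeds,
            arrival_times=estimate.arrival_times,
            variance=estimate.speed_variance,
            initial_estimate=estimate.initial_estimate,
            timestamp_label=timestamp_label,
            flags=estimate.flags,
            config_hash=config_hash,
            seed=seed,
        )

    def to_row(self) -> dict[str, str]:
        row = {
            "sample_id": self.sample_id,
            "timestamp_label": self.timestamp_label,
            "mean_sws": repr(float(self.mean_sws)),
            "variance": repr(float(self.variance)),
            "initial_estimate": "" if self.initial_estimate is None else repr(float(self.initial_estimate)),
            "flags": ";".join(self.flags),
            "config_hash": self.config_hash,
            "seed": str(self.seed),
        }
        for i in range(4):
            row[f"s_{i+1}"] = repr(float(self.per_path_speeds[i]))
            row[f"t_{i+1}"] = repr(float(self.arrival_times[i]))
        return row

    @classmethod
    def from_row(cls, row: dict[str, str]) -> "ResultRecord":
        return cls(
            sample_id=row["sample_id"],
            timestamp_label=row["timestamp_label"],
            mean_sws=float(row["mean_sws"]),
            per_path_speeds=tuple(float(row[f"s_{i+1}"]) for i in range(4)),
            arrival_times=tuple(float(row[f"t_{i+1}"]) for i in range(4)),
            variance=float(row["variance"]),
            initial_estimate=float(row["initial_estimate"]) if row["initial_estimate"] else None,
            flags=tuple(f for f in row["flags"].split(";") if f),
            config_hash=row["config_hash"],
            seed=int(row["seed"]),
        )


def write_records(path: str | Path, records: list[ResultRecord]) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=RESULT_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(rec.to_row())


def read_records(path: str | Path) -> list[ResultRecord]:
    with open(path, newline="") as f:
        return [ResultRecord.from_row(row) for row in csv.DictReader(f)]
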