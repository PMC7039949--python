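"""Trace-container persistence.

Sweep sets travel in a single HDF5 file with a JSON manifest stored as a
root attribute.  The manifest is schema-versioned and round-trips
unknown fields untouched; sweep matrices round-trip bit-identically.
Cleaned evoked traces use the same container with a different group
layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .preprocess import EvokedTrace
from .synthdata import Condition, GroundTruth, SweepSet

__all__ = [
    "SchemaError",
    "TraceContainer",
    "write_container",
    "read_container",
    "write_evoked",
    "read_evoked",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1
UNITS = {"voltage": "uV", "current": "uA", "charge": "nC", "time": "us"}


class SchemaError(ValueError):
    """Container violates the manifest schema; message names the field."""


@dataclass
class TraceContainer:
    sweepsets: list[SweepSet]
    manifest: dict = field(default_factory=dict)
    ground_truth: GroundTruth | None = None


def _base_manifest(sampling_rate_hz: float, n_sweepsets: int,
                   extra: dict | None) -> dict:
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "units": dict(UNITS),
        "sampling_rate_hz": sampling_rate_hz,
        "n_sweepsets": n_sweepsets,
        "provenance": [],
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_container(
    path,
    sweepsets: list[SweepSet],
    ground_truth: GroundTruth | None = None,
    extra_manifest: dict | None = None,
) -> str:
    if not sweepsets:
        raise ValueError("no sweep sets to write")
    manifest = _base_manifest(
        sweepsets[0].sampling_rate_hz, len(sweepsets), extra_manifest
    )
    if ground_truth is not None:
        manifest["ground_truth"] = ground_truth.to_dict()
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest)
        for i, ss in enumerate(sweepsets):
            g = f.create_group(f"sweepsets/{i:04d}")
            g.create_dataset("sweeps_uv", data=ss.sweeps_uv)
            g.attrs["condition"] = json.dumps(ss.condition.to_dict())
            g.attrs["delay_tag_us"] = ss.delay_tag_us
            g.attrs["t0_index"] = ss.t0_index
            g.attrs["sampling_rate_hz"] = ss.sampling_rate_hz
            g.attrs["above_facial_nerve"] = ss.above_facial_nerve
    return str(path)


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required field: {where}.{key}")
    return mapping[key]


def read_container(path) -> TraceContainer:
    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs:
            raise SchemaError("missing required field: manifest")
        manifest = json.loads(f.attrs["manifest"])
        _require(manifest, "schema_version", "manifest")
        _require(manifest, "sampling_rate_hz", "manifest")
        _require(manifest, "units", "manifest")
        sweepsets = []
        if "sweepsets" in f:
            for name in sorted(f["sweepsets"]):
                g = f[f"sweepsets/{name}"]
                for key in ("condition", "delay_tag_us", "t0_index",
                            "sampling_rate_hz"):
                    if key not in g.attrs:
                        raise SchemaError(
                            f"missing required field: sweepsets/{name}.{key}"
                        )
                sweepsets.append(
                    SweepSet(
                        sweeps_uv=g["sweeps_uv"][()],
                        sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                        delay_tag_us=float(g.attrs["delay_tag_us"]),
                        condition=Condition.from_dict(
                            json.loads(g.attrs["condition"])
                        ),
                        t0_index=int(g.attrs["t0_index"]),
                        above_facial_nerve=bool(
                            g.attrs.get("above_facial_nerve", False)
                        ),
                    )
                )
    gt = None
    if manifest.get("ground_truth") is not None:
        gt = GroundTruth.from_dict(manifest["ground_truth"])
    return TraceContainer(sweepsets=sweepsets, manifest=manifest, ground_truth=gt)


def write_evoked(path, traces: list[EvokedTrace],
                 extra_manifest: dict | None = None) -> str:
    """Persist cleaned evoked traces (one group per trace)."""
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "units": dict(UNITS),
        "kind": "evoked",
        "n_traces": len(traces),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest)
        for i, tr in enumerate(traces):
            g = f.create_group(f"evoked/{i:04d}")
            g.create_dataset("samples_uv", data=tr.samples_uv)
            g.attrs["sample_interval_us"] = tr.sample_interval_us
            g.attrs["t0_us"] = tr.t0_us
            if tr.condition is not None:
                g.attrs["condition"] = json.dumps(tr.condition.to_dict())
            g.attrs["provenance"] = json.dumps(tr.provenance)
    return str(path)


def read_evoked(path) -> list[EvokedTrace]:
    traces = []
    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs:
            raise SchemaError("missing required field: manifest")
        for name in sorted(f.get("evoked", [])):
            g = f[f"evoked/{name}"]
            cond = (
                Condition.from_dict(json.loads(g.attrs["condition"]))
                if "condition" in g.attrs
                else None
            )
            traces.append(
                EvokedTrace(
                    samples_uv=g["samples_uv"][()],
                    sample_interval_us=float(g.attrs["sample_interval_us"]),
                    t0_us=float(g.attrs["t0_us"]),
                    condition=cond,
                    provenance=json.loads(g.attrs.get("provenance", "[]")),
                )
            )
    return traces
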