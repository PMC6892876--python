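"""Readers and writers for the package's on-disk formats.

Stacks travel as OME-TIFF (axes CZYX, physical voxel sizes in the OME
metadata) with a JSON sidecar that carries geometry, channel roles and any
generator ground truth; traces as two-column time(s),current(pA) CSV plus a
JSON metadata sidecar.  All result tables keep explicit units in their
column names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidSpecError
from .geometry import ImageStack, VoxelGeometry
from .nanopore import NanoporeTrace, TranslocationEvent

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_trace_csv",
    "read_trace_csv",
    "events_to_frame",
    "write_events_csv",
    "profile_to_frame",
    "write_json",
    "read_json",
]


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyJSONEncoder, indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image_stack(path, stack: ImageStack, truth: dict | None = None) -> Path:
    """Write an OME-TIFF plus a JSON sidecar; returns the sidecar path."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.geom.dx / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.geom.dy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.geom.dz / 1000.0,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channels)},
        },
        ome=True,
    )
    sidecar = {
        "voxel_nm": {"dx": stack.geom.dx, "dy": stack.geom.dy, "dz": stack.geom.dz},
        "channels": list(stack.channels),
        "metadata": stack.metadata,
    }
    if truth is not None:
        sidecar["truth"] = truth
    sc_path = _sidecar_path(path)
    write_json(sidecar, sc_path)
    return sc_path


def read_image_stack(path, sidecar=None) -> ImageStack:
    """Read a stack written by :func:`write_image_stack` (sidecar preferred)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    sc_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sc_path.exists():
        raise InvalidSpecError(
            f"missing JSON sidecar {sc_path}; voxel geometry and channel roles required"
        )
    sc = read_json(sc_path)
    geom = VoxelGeometry(
        dx=sc["voxel_nm"]["dx"], dy=sc["voxel_nm"]["dy"], dz=sc["voxel_nm"]["dz"]
    )
    return ImageStack(data, geom, tuple(sc["channels"]), metadata=sc.get("metadata", {}))


def write_trace_csv(path, trace: NanoporeTrace, extra_metadata: dict | None = None) -> Path:
    """Two-column time_s,current_pA CSV plus a JSON sidecar; returns the sidecar."""
    path = Path(path)
    t = np.arange(len(trace)) * trace.dt
    pd.DataFrame({"time_s": t, "current_pA": trace.samples_pa}).to_csv(path, index=False)
    sidecar = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "voltage_mv": trace.voltage_mv,
        "n_samples": len(trace),
        "metadata": {**trace.metadata, **(extra_metadata or {})},
    }
    sc_path = _sidecar_path(path)
    write_json(sidecar, sc_path)
    return sc_path


def read_trace_csv(path, sidecar=None) -> NanoporeTrace:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "current_pA"} <= set(df.columns):
        raise InvalidSpecError("trace CSV needs columns time_s, current_pA")
    sc_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sc_path.exists():
        sc = read_json(sc_path)
        fs = float(sc["sampling_rate_hz"])
        voltage = float(sc.get("voltage_mv", 200.0))
        meta = sc.get("metadata", {})
    else:  # fall back to the time column
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        fs, voltage, meta = 1.0 / dt, 200.0, {}
    return NanoporeTrace(df["current_pA"].to_numpy(), fs, voltage, meta)


def events_to_frame(events: list[TranslocationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_sample": [e.start for e in events],
            "end_sample": [e.end for e in events],
            "duration_s": [e.duration_s for e in events],
            "mean_amplitude_pA": [e.mean_amplitude_pa for e in events],
            "ecd_pAs": [e.ecd_pas for e in events],
            "mw_Da": [e.mw_da for e in events],
            "flags": [";".join(e.flags) for e in events],
        }
    )


def write_events_csv(path, events: list[TranslocationEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False)


def profile_to_frame(profile) -> pd.DataFrame:
    """Export a radial/axial profile for plotting."""
    return pd.DataFrame(
        {
            "r_nm": profile.r_nm,
            "intensity": profile.intensity,
            "count": profile.counts,
        }
    )
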