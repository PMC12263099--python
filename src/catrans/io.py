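"""Readers and writers for CNMF-style outputs, session descriptors and tables.

Trace arrays live in a labeled-array container (a zarr group written through
xarray, the convention of CNMF-based extraction pipelines): one array per
variable, keyed by the upstream names ``C``, ``S``, ``YrA``, ``A``, ``dff``,
with axis identity carried by dimension *labels* (``unit_id``/``frame`` and,
for footprints, ``height``/``width``), never by axis position.

Session metadata comes in two interchangeable forms: a flat INI file per
recording session, and a hierarchical JSON file grouping many sessions by
animal → day → session stage.

CSV (comma, UTF-8, header row) is the single tabular dialect, for events,
behavior flags and export tables.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .trace_model import CalciumTraceSet, TransientEvent

__all__ = [
    "SessionDescriptor",
    "load_traceset",
    "save_traceset",
    "parse_session_ini",
    "write_session_ini",
    "build_experiment_json",
    "read_experiment_json",
    "save_events",
    "load_events",
    "load_behavior",
]

_CELL_DIMS = ("unit_id", "cell", "cells")
_FRAME_DIMS = ("frame", "frames", "time")

# Mandatory INI keys: (section, key)
_INI_REQUIRED = {
    "animal_id": ("session", "animal_id"),
    "day": ("session", "day"),
    "session_stage": ("session", "session_stage"),
    "trace_path": ("data", "trace_path"),
}
_INI_OPTIONAL = {
    "behavior_path": ("data", "behavior_path"),
    "ca_video_path": ("data", "ca_video_path"),
    "behavior_video_path": ("data", "behavior_video_path"),
}


@dataclass
class SessionDescriptor:
    """Flat description of one recording session.

    Video paths are recorded verbatim but never opened (visualization is out
    of scope for this library).  Unrecognized INI keys survive round trips
    in ``extras``.
    """

    animal_id: str
    day: str
    session_stage: str
    trace_path: str
    behavior_path: Optional[str] = None
    ca_video_path: Optional[str] = None
    behavior_video_path: Optional[str] = None
    extras: Dict[str, str] = field(default_factory=dict)


def _norm_temporal(da: xr.DataArray, name: str) -> np.ndarray:
    """Return a (cells, frames) ndarray from a labeled 2-D DataArray."""
    if da.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got {da.dims}")
    cell_dim = next((d for d in da.dims if d in _CELL_DIMS), None)
    frame_dim = next((d for d in da.dims if d in _FRAME_DIMS), None)
    if cell_dim is None or frame_dim is None:
        raise ValueError(
            f"{name} dims {da.dims} lack recognizable cell/frame axis labels "
            f"(expected one of {_CELL_DIMS} x {_FRAME_DIMS})"
        )
    return da.transpose(cell_dim, frame_dim).to_numpy()


def load_traceset(path) -> CalciumTraceSet:
    """Load a :class:`CalciumTraceSet` from a labeled-array container.

    ``C`` and ``S`` are mandatory; ``YrA``, ``A`` (footprints) and ``dff``
    are optional.  Axis order is normalized to ``(cells, frames)`` from the
    stored dimension labels.  Shape disagreement across variables is an
    error, never silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace container not found: {path}")
    ds = xr.open_zarr(path, consolidated=False)
    missing = [k for k in ("C", "S") if k not in ds]
    if missing:
        raise KeyError(
            f"trace container {path} is missing mandatory variable(s): "
            + ", ".join(missing)
        )
    C = _norm_temporal(ds["C"], "C")
    S = _norm_temporal(ds["S"], "S")
    YrA = _norm_temporal(ds["YrA"], "YrA") if "YrA" in ds else None
    dff = _norm_temporal(ds["dff"], "dff") if "dff" in ds else None
    shapes = {"C": C.shape, "S": S.shape}
    for nm, arr in (("YrA", YrA), ("dff", dff)):
        if arr is not None:
            shapes[nm] = arr.shape
    if len(set(shapes.values())) != 1:
        raise ValueError(f"temporal variables disagree in shape: {shapes}")
    footprints = None
    if "A" in ds:
        A = ds["A"]
        cell_dim = next((d for d in A.dims if d in _CELL_DIMS), None)
        if A.ndim != 3 or cell_dim is None:
            raise ValueError(f"A must be (cells, height, width), got dims {A.dims}")
        other = [d for d in A.dims if d != cell_dim]
        footprints = A.transpose(cell_dim, *other).to_numpy()
    cell_dim = next(d for d in ds["C"].dims if d in _CELL_DIMS)
    if cell_dim in ds["C"].coords:
        cell_ids = [c.item() for c in ds["C"].coords[cell_dim]]
    else:
        cell_ids = list(range(C.shape[0]))
    frame_rate = float(ds.attrs.get("frame_rate", 30.0))
    category = json.loads(ds.attrs["category"]) if "category" in ds.attrs else {}
    # JSON stringifies keys; map back onto the actual cell ids
    category = {type(cell_ids[0])(k) if cell_ids else k: v for k, v in category.items()}
    return CalciumTraceSet(
        cell_ids=cell_ids, C=C, S=S, YrA=YrA, dff=dff,
        footprints=footprints, frame_rate=frame_rate, category=category,
    )


def save_traceset(ts: CalciumTraceSet, path) -> None:
    """Write a trace set as a labeled-array (zarr) container; inverse of
    :func:`load_traceset`."""
    path = Path(path)
    coords = {"unit_id": ts.cell_ids, "frame": np.arange(ts.n_frames)}
    data = {
        "C": (("unit_id", "frame"), ts.C),
        "S": (("unit_id", "frame"), ts.S),
    }
    if ts.YrA is not None:
        data["YrA"] = (("unit_id", "frame"), ts.YrA)
    if ts.dff is not None:
        data["dff"] = (("unit_id", "frame"), ts.dff)
    if ts.footprints is not None:
        data["A"] = (("unit_id", "height", "width"), ts.footprints)
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["frame_rate"] = ts.frame_rate
    if ts.category:
        ds.attrs["category"] = json.dumps(
            {str(k): v for k, v in ts.category.items()}
        )
    ds.to_zarr(path, mode="w", consolidated=False)


def parse_session_ini(path) -> SessionDescriptor:
    """Parse a flat INI session file into a :class:`SessionDescriptor`.

    The INI schema is a reconstruction of the demo-file layout shipped with
    upstream GUI tools (the original schema is informally specified); see the
    repository docs for the compatibility note.  Unknown keys are preserved
    in ``extras`` as ``section.key`` entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"INI file not found: {path}")
    cp = configparser.ConfigParser()
    cp.read(path)
    values, known = {}, set()
    for name, (sec, key) in {**_INI_REQUIRED, **_INI_OPTIONAL}.items():
        known.add((sec, key))
        if cp.has_option(sec, key):
            values[name] = cp.get(sec, key)
    missing = [n for n in _INI_REQUIRED if n not in values]
    if missing:
        raise KeyError(
            f"INI {path} is missing mandatory key(s): " + ", ".join(missing)
        )
    extras = {
        f"{sec}.{key}": cp.get(sec, key)
        for sec in cp.sections()
        for key in cp.options(sec)
        if (sec, key) not in known
    }
    return SessionDescriptor(**values, extras=extras)


def write_session_ini(desc: SessionDescriptor, path) -> None:
    """Inverse of :func:`parse_session_ini`."""
    cp = configparser.ConfigParser()
    for name, (sec, key) in {**_INI_REQUIRED, **_INI_OPTIONAL}.items():
        val = getattr(desc, name)
        if val is None:
            continue
        if not cp.has_section(sec):
            cp.add_section(sec)
        cp.set(sec, key, str(val))
    for flat, val in desc.extras.items():
        sec, key = flat.split(".", 1)
        if not cp.has_section(sec):
            cp.add_section(sec)
        cp.set(sec, key, val)
    with open(path, "w") as fh:
        cp.write(fh)


def _desc_to_dict(d: SessionDescriptor) -> dict:
    out = {
        "trace_path": d.trace_path,
        "behavior_path": d.behavior_path,
        "ca_video_path": d.ca_video_path,
        "behavior_video_path": d.behavior_video_path,
    }
    if d.extras:
        out["extras"] = dict(d.extras)
    return {k: v for k, v in out.items() if v is not None}


def build_experiment_json(
    descriptors: Sequence[SessionDescriptor], path=None
) -> dict:
    """Group session descriptors hierarchically: animal → day → stage.

    Duplicate (animal, day, stage) triples are an error.  When ``path`` is
    given the record is also written as sorted-key JSON, which makes the
    write → read → write cycle byte-identical.
    """
    if not descriptors:
        raise ValueError("need at least one descriptor")
    tree: dict = {}
    for d in descriptors:
        stage_map = tree.setdefault(str(d.animal_id), {}).setdefault(str(d.day), {})
        if str(d.session_stage) in stage_map:
            raise ValueError(
                f"duplicate session ({d.animal_id}, {d.day}, {d.session_stage})"
            )
        stage_map[str(d.session_stage)] = _desc_to_dict(d)
    if path is not None:
        Path(path).write_text(json.dumps(tree, indent=2, sort_keys=True) + "\n")
    return tree


def read_experiment_json(path) -> List[SessionDescriptor]:
    """Inverse of :func:`build_experiment_json`: back to a flat list."""
    tree = json.loads(Path(path).read_text())
    out = []
    for animal, days in tree.items():
        for day, stages in days.items():
            for stage, leaf in stages.items():
                leaf = dict(leaf)
                extras = leaf.pop("extras", {})
                out.append(
                    SessionDescriptor(
                        animal_id=animal, day=day, session_stage=stage,
                        extras=extras, **leaf,
                    )
                )
    return out


_EVENT_COLUMNS = [
    "cell_id", "rise_start", "rise_stop",
    "peak_amplitude", "total_amplitude", "interval_prev",
]


def save_events(events: Sequence[TransientEvent], path) -> None:
    """Persist events as CSV, one row per event (header-only when empty)."""
    rows = [
        {
            "cell_id": e.cell_id,
            "rise_start": e.rise_start,
            "rise_stop": e.rise_stop,
            "peak_amplitude": e.peak_amplitude,
            "total_amplitude": e.total_amplitude,
            "interval_prev": e.interval_prev,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def load_events(path) -> List[TransientEvent]:
    """Inverse of :func:`save_events`; malformed rows are reported with their
    line number."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events CSV {path} lacks columns: {sorted(missing)}")
    out = []
    # note: iterate records, not iterrows -- the latter upcasts whole rows
    for i, row in enumerate(df.to_dict("records")):
        try:
            cid = row["cell_id"]
            if isinstance(cid, float) and cid.is_integer():
                cid = int(cid)
            out.append(
                TransientEvent(
                    cell_id=cid,
                    rise_start=int(row["rise_start"]),
                    rise_stop=int(row["rise_stop"]),
                    peak_amplitude=float(row["peak_amplitude"]),
                    total_amplitude=float(row["total_amplitude"]),
                    interval_prev=None
                    if pd.isna(row["interval_prev"])
                    else int(row["interval_prev"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed event at line {i + 2}: {exc}")
    return out


def load_behavior(path, n_frames: Optional[int] = None) -> pd.DataFrame:
    """Read a per-frame behavioral flag table (channels such as ALP, ILP, RNF).

    Flags must be binary; the frame count must not exceed the recording's.
    """
    df = pd.read_csv(path)
    if not df.isin([0, 1]).all().all():
        raise ValueError(f"behavior table {path} has non-binary flags")
    if n_frames is not None and len(df) > n_frames:
        raise ValueError(
            f"behavior table has {len(df)} frames, more than the {n_frames} "
            "trace frames"
        )
    return df.astype(int)
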