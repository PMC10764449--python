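"""Reading and writing the pipeline's on-disk formats.

Traces travel as CSV (``cage_id, timestamp_iso8601, activity_index``) with a
JSON sidecar holding the schedule and surgery anchor; fields as single-channel
16-bit TIFF with a JSON sidecar (pixel size, area/field indices, preset id,
seed); ground truth as JSON; presets and configs as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import date, datetime, time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .activity import ActivityTrace
from .histomorph import FieldImage

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_field_tiff",
    "read_field_tiff",
    "write_preset_yaml",
    "read_preset_yaml",
]


def write_trace_csv(trace: ActivityTrace, csv_path: str | Path) -> Path:
    """Write one trace plus a ``<name>.meta.json`` sidecar next to it."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "cage_id": trace.cage_id,
            "timestamp_iso8601": trace.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
            "activity_index": trace.values,
        }
    ).to_csv(csv_path, index=False)
    meta = {
        "cage_id": trace.cage_id,
        "period": trace.period,
        "lights_on": trace.lights_on.isoformat(),
        "lights_off": trace.lights_off.isoformat(),
        "surgery_day": trace.surgery_day.isoformat(),
        "group": trace.group,
    }
    with open(csv_path.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return csv_path


def read_trace_csv(csv_path: str | Path) -> ActivityTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    with open(csv_path.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    ts = pd.to_datetime(df["timestamp_iso8601"])
    return ActivityTrace(
        cage_id=meta["cage_id"],
        start=ts.iloc[0].to_pydatetime(),
        values=df["activity_index"].to_numpy(dtype=float),
        period=int(meta["period"]),
        lights_on=time.fromisoformat(meta["lights_on"]),
        lights_off=time.fromisoformat(meta["lights_off"]),
        surgery_day=date.fromisoformat(meta["surgery_day"]),
        group=meta.get("group", ""),
    )


def write_field_tiff(image: FieldImage, tiff_path: str | Path,
                     preset_id: str = "", seed: int | None = None) -> Path:
    """Write a field as 16-bit TIFF plus a JSON sidecar with its metadata."""
    tiff_path = Path(tiff_path)
    px = np.asarray(image.pixels, dtype=float)
    tifffile.imwrite(tiff_path, np.clip(px, 0, 65535).astype(np.uint16))
    meta = {
        "pixel_size_um": image.pixel_size,
        "area_index": image.area_index,
        "field_index": image.field_index,
        "tendon_id": image.tendon_id,
        "preset_id": preset_id,
        "seed": seed,
    }
    with open(tiff_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return tiff_path


def read_field_tiff(tiff_path: str | Path) -> FieldImage:
    tiff_path = Path(tiff_path)
    px = tifffile.imread(tiff_path).astype(float)
    with open(tiff_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return FieldImage(
        pixels=px,
        pixel_size=float(meta["pixel_size_um"]),
        area_index=int(meta["area_index"]),
        field_index=int(meta["field_index"]),
        tendon_id=meta.get("tendon_id", ""),
    )


def write_preset_yaml(preset, path: str | Path) -> Path:
    path = Path(path)
    d = asdict(preset)
    d["_type"] = type(preset).__name__
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
        elif isinstance(v, np.ndarray):
            d[k] = v.tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return path


def read_preset_yaml(path: str | Path):
    from . import synthetic

    with open(path) as fh:
        d = yaml.safe_load(fh)
    cls = getattr(synthetic, d.pop("_type"))
    for f_ in cls.__dataclass_fields__.values():
        if f_.name in d and isinstance(d[f_.name], list) and "tuple" in str(f_.type):
            val = d[f_.name]
            if val and isinstance(val[0], list):
                val = [tuple(v) for v in val]
            d[f_.name] = tuple(val)
    return cls(**d)
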