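"""Event-container readers and writers.

Two on-disk layouts are supported: the community HDF5 container (an
``events`` group of equal-length named datasets plus root attributes for
acquisition metadata, the ".rtdc"-style layout) and plain CSV with metadata
embedded as ``# key: value`` comment lines before the header. Feature-name
aliases used by acquisition software ("deform", "size_x", ...) are mapped
onto the canonical column names on read. Canonical units: µm² for area,
dimensionless shape features, raw camera units for brightness.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, SchemaError
from .synthetic import SampleRecord

__all__ = ["read_events", "write_events", "ALIASES", "MANDATORY_COLUMNS",
           "SCHEMA_VERSION", "write_manifest", "read_manifest"]

SCHEMA_VERSION = "1"

#: Community / acquisition-software aliases mapped to canonical names.
ALIASES: dict[str, str] = {
    "deform": "deformation",
    "area_um": "area_um2",
    "area": "area_um2",
    "aspect": "aspect_ratio",
    "area_ratio_raw": "area_ratio",
    "bright_avg": "brightness_avg",
    "bright_sd": "brightness_sd",
    "fl1_max": "fl_ch1_max",
    "fl2_max": "fl_ch2_max",
    "fl3_max": "fl_ch3_max",
}

MANDATORY_COLUMNS = ("area_um2", "deformation", "aspect_ratio", "area_ratio")

_META_KEYS = ("sample_id", "tissue", "condition", "pairing_id", "pixel_size")


def _canonicalize(events: pd.DataFrame) -> pd.DataFrame:
    renames = {c: ALIASES[c] for c in events.columns
               if c in ALIASES and ALIASES[c] not in events.columns}
    return events.rename(columns=renames)


def _check_schema(events: pd.DataFrame, path) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("hdf5", "csv"):
            raise ParameterError(f"unknown format {fmt!r}; use 'hdf5' or 'csv'")
        return fmt
    return "hdf5" if path.suffix.lower() in (".rtdc", ".h5", ".hdf5") else "csv"


def read_events(path: str | Path, fmt: str | None = None) -> SampleRecord:
    """Read one sample from an HDF5 event container or CSV table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    if _infer_format(path, fmt) == "hdf5":
        return _read_hdf5(path)
    return _read_csv(path)


def _read_hdf5(path: Path) -> SampleRecord:
    try:
        with h5py.File(path, "r") as f:
            if "events" not in f:
                raise FormatError(f"{path}: no 'events' group")
            grp = f["events"]
            data = {}
            for name in grp:
                arr = np.asarray(grp[name])
                data[name] = arr
            lengths = {len(v) for v in data.values()}
            if len(lengths) > 1:
                raise FormatError(f"{path}: unequal event-array lengths {lengths}")
            meta = {k: (v.decode() if isinstance(v, bytes) else v)
                    for k, v in f.attrs.items()}
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 container ({exc})") from exc
    events = _canonicalize(pd.DataFrame(data))
    _check_schema(events, path)
    return _record_from_meta(events, meta, path)


def _read_csv(path: Path) -> SampleRecord:
    meta: dict = {}
    import io as _io

    lines = path.read_text(encoding="utf-8").splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        if ":" in line:
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
        body_start += 1
    try:
        events = pd.read_csv(_io.StringIO("".join(lines[body_start:])),
                             float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no tabular data") from exc
    if "pixel_size" in meta:
        meta["pixel_size"] = float(meta["pixel_size"])
    events = _canonicalize(events)
    _check_schema(events, path)
    return _record_from_meta(events, meta, path)


def _record_from_meta(events: pd.DataFrame, meta: dict, path: Path) -> SampleRecord:
    extra = {k: v for k, v in meta.items()
             if k not in _META_KEYS and k != "schema_version"}
    return SampleRecord(
        sample_id=str(meta.get("sample_id", path.stem)),
        events=events,
        tissue=str(meta.get("tissue", "unknown")),
        condition=meta.get("condition"),
        pairing_id=meta.get("pairing_id"),
        pixel_size=float(meta.get("pixel_size", 0.34)),
        metadata=extra,
    )


def write_events(record: SampleRecord, path: str | Path,
                 fmt: str | None = None, overwrite: bool = False) -> None:
    """Write a sample so that :func:`read_events` round-trips it bit-exactly."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if len(record.events.columns) == 0:
        raise ParameterError("record has no event columns")
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "sample_id": record.sample_id,
        "tissue": record.tissue,
        "pixel_size": record.pixel_size,
        "schema_version": SCHEMA_VERSION,
    }
    if record.condition is not None:
        meta["condition"] = record.condition
    if record.pairing_id is not None:
        meta["pairing_id"] = record.pairing_id
    for k, v in record.metadata.items():
        meta.setdefault(k, v)

    if _infer_format(path, fmt) == "hdf5":
        with h5py.File(path, "w") as f:
            grp = f.create_group("events")
            for col in record.events.columns:
                values = record.events[col].to_numpy()
                if values.dtype == object:
                    values = values.astype("S")
                grp.create_dataset(col, data=values)
            for k, v in meta.items():
                f.attrs[k] = v
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            # %.17g round-trips float64 bit-exactly through text
            record.events.to_csv(fh, index=False, float_format="%.17g")


def write_manifest(records: list[SampleRecord], paths: list[str | Path],
                   manifest_path: str | Path) -> None:
    """Cohort manifest CSV: sample id, label, pairing id, file path."""
    rows = [{"sample_id": r.sample_id, "label": r.condition,
             "pairing_id": r.pairing_id, "path": str(p)}
            for r, p in zip(records, paths)]
    pd.DataFrame(rows).to_csv(manifest_path, index=False)


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    missing = [c for c in ("sample_id", "label", "path") if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing columns {missing}")
    return df


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
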