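"""Reading and writing the pipeline's standard formats.

Gridded monthly fields travel as CF-style NetCDF (time/lat/lon dims,
``units`` attribute; the classic-format backend, so files stay portable
and text-tool friendly); monthly indices and annual yields as two-column
CSV; run metadata as YAML manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

__all__ = [
    "write_field",
    "read_field",
    "write_series",
    "read_series",
    "write_yields",
    "read_yields",
    "write_manifest",
    "read_manifest",
    "file_checksum",
]


def write_field(field: xr.DataArray, path: str | Path) -> Path:
    """Write a (time, lat, lon) monthly field as classic NetCDF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = field.name or "field"
    field.to_dataset(name=name).to_netcdf(path, engine="scipy")
    return path


def read_field(path: str | Path, name: str | None = None) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    if name is None:
        name = next(iter(ds.data_vars))
    return ds[name].load()


def write_series(series: pd.Series, path: str | Path) -> Path:
    """Write a monthly series as CSV with columns (date, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {"date": series.index.astype(str), "value": series.to_numpy()}
    )
    frame.to_csv(path, index=False)
    return path


def read_series(path: str | Path, name: str | None = None) -> pd.Series:
    frame = pd.read_csv(path)
    idx = pd.PeriodIndex(frame["date"], freq="M")
    out = pd.Series(frame["value"].to_numpy(dtype=float), index=idx)
    out.name = name or Path(path).stem
    return out


def write_yields(yields: pd.Series, path: str | Path, region: str = "synthetic") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"region": region, "year": yields.index.astype(int), "yield": yields.to_numpy()}
    ).to_csv(path, index=False)
    return path


def read_yields(path: str | Path, region: str | None = None) -> pd.Series:
    frame = pd.read_csv(path)
    if region is not None:
        frame = frame[frame["region"] == region]
    if frame.empty:
        raise FileNotFoundError(f"no yield rows for region {region!r} in {path}")
    out = pd.Series(
        frame["yield"].to_numpy(dtype=float),
        index=pd.Index(frame["year"].to_numpy(dtype=int), name="year"),
        name="yield",
    )
    return out


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(manifest), fh, sort_keys=True)
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
    return path
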