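"""File formats: trace/angle CSVs, volume TIFFs with TOML sidecars, JSON.

CSVs are UTF-8 with a mandatory header row and '.' decimal separator.
Volumes are multi-page TIFFs (8-bit grey or 0/255 binary) accompanied by a
TOML sidecar holding at least ``voxel_edge_um`` and, for grey volumes, the
segmentation ``polarity``.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ct import VoxelVolume

__all__ = [
    "read_traces",
    "write_traces",
    "read_angle_series",
    "write_angle_series",
    "read_volume",
    "write_volume",
    "write_json",
]

_TRACE_COLS = ["material", "f", "replicate", "depth_mm", "Fz_N"]
_ANGLE_COLS = ["time_min", "angle_deg", "replicate", "treatment"]


def read_traces(path: str | Path, meta: str | Path | None = None) -> pd.DataFrame:
    """Read force traces; merge per-replicate metadata (material, f) if given."""
    df = pd.read_csv(path)
    if meta is not None:
        meta_df = pd.read_csv(meta)
        on = [c for c in ("replicate", "trace_id") if c in df and c in meta_df]
        df = df.merge(meta_df, on=on)
    missing = [c for c in _TRACE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table is missing columns {missing}")
    return df


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_angle_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _ANGLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"angle table is missing columns {missing}")
    return df


def write_angle_series(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_volume(tiff_path: str | Path, sidecar: str | Path | None = None) -> VoxelVolume:
    """Load a multi-page TIFF volume with its TOML sidecar.

    The sidecar defaults to the TIFF path with a ``.toml`` suffix.  Values
    of a 0/255 binary stack are mapped to {0, 1}.
    """
    tiff_path = Path(tiff_path)
    sidecar = Path(sidecar) if sidecar else tiff_path.with_suffix(".toml")
    with open(sidecar, "rb") as fh:
        meta = tomllib.load(fh)
    values = tifffile.imread(tiff_path)
    uniq = np.unique(values)
    if set(uniq.tolist()) <= {0, 255}:
        values = (values > 0).astype(np.uint8)
    return VoxelVolume(values, float(meta["voxel_edge_um"]))


def write_volume(vol: VoxelVolume, tiff_path: str | Path, **meta) -> None:
    """Write a volume as multi-page TIFF plus a TOML sidecar."""
    tiff_path = Path(tiff_path)
    values = vol.values
    if values.dtype == bool:
        values = values.astype(np.uint8) * 255
    tifffile.imwrite(tiff_path, values, compression=None)
    lines = [f"voxel_edge_um = {vol.voxel_edge_um}"]
    for key, val in meta.items():
        lines.append(f'{key} = "{val}"' if isinstance(val, str) else f"{key} = {val}")
    tiff_path.with_suffix(".toml").write_text("\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
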