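"""Readers and writers for cubes, curves and result maps.

Native container: one HDF5 file with datasets ``/ch{k}/counts`` (uint32,
row-major, y x t) and attributes ``channel_width_ps``, ``rep_period_ns``,
``pixel_pitch_um`` and ``spectral_nm`` per channel group.  Also supported:
multi-page 32-bit TIFF stacks (pages = time channels) with a JSON metadata
sidecar, and per-pixel CSV for toy data.  Curves load from two-column text
(time_ps, counts).  Result maps are written as single-page 32-bit float
TIFFs plus a descriptive-statistics CSV and a JSON provenance record.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import (
    FitResultMaps,
    FormatError,
    IRFCurve,
    LensDecay,
    MetadataError,
    TCSPCCube,
    TimeAxis,
)

__all__ = ["load_cube", "save_cube", "load_curve", "save_results"]

_REQUIRED_META = ("channel_width_ps", "rep_period_ns", "pixel_pitch_um")


def _axis_from_meta(meta: dict, n_channels: int) -> TimeAxis:
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise MetadataError(f"missing metadata fields: {missing}")
    return TimeAxis(
        n_channels=n_channels,
        channel_width_ps=float(meta["channel_width_ps"]),
        rep_period_ns=float(meta["rep_period_ns"]),
    )


def _cube_from_counts(counts: np.ndarray, meta: dict) -> TCSPCCube:
    axis = _axis_from_meta(meta, counts.shape[2])
    return TCSPCCube(
        counts=counts,
        time=axis,
        spectral_range_nm=tuple(meta.get("spectral_nm", (498.0, 560.0))),
        pixel_pitch_um=float(meta["pixel_pitch_um"]),
        channel_id=int(meta.get("channel_id", 1)),
    )


def save_cube(cube: TCSPCCube, path: str | Path) -> Path:
    """Write a cube to the native HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group(f"ch{cube.channel_id}")
        g.create_dataset("counts", data=cube.counts.astype(np.uint32))
        g.attrs["channel_width_ps"] = cube.time.channel_width_ps
        g.attrs["rep_period_ns"] = cube.time.rep_period_ns
        g.attrs["pixel_pitch_um"] = cube.pixel_pitch_um
        g.attrs["spectral_nm"] = list(cube.spectral_range_nm)
    return path


def _load_cube_h5(path: Path, channel_id: int | None) -> TCSPCCube:
    with h5py.File(path, "r") as f:
        groups = [k for k in f if k.startswith("ch")]
        if not groups:
            raise FormatError("container holds no channel groups")
        name = f"ch{channel_id}" if channel_id is not None else sorted(groups)[0]
        if name not in f:
            raise MetadataError(f"channel group {name!r} not in container")
        g = f[name]
        counts = np.asarray(g["counts"])
        meta = dict(g.attrs)
        meta["channel_id"] = int(name[2:])
    return _cube_from_counts(counts, meta)


def _sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise MetadataError(f"metadata sidecar {sidecar.name} not found")
    return json.loads(sidecar.read_text())


def _load_cube_tiff(path: Path) -> TCSPCCube:
    meta = _sidecar(path)
    pages = tifffile.imread(path)  # (t, y, x)
    if pages.ndim != 3:
        raise FormatError("expected a multi-page TIFF stack")
    counts = np.moveaxis(pages, 0, 2)
    return _cube_from_counts(counts, meta)


def _load_cube_csv(path: Path) -> TCSPCCube:
    """Per-pixel CSV toy format: columns row, col, c0, c1, ... per line."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh):
            if not rec or rec[0].strip().startswith("#") or rec[0] == "row":
                continue
            rows.append([float(v) for v in rec])
    if not rows:
        raise FormatError("empty CSV cube")
    arr = np.asarray(rows)
    ny = int(arr[:, 0].max()) + 1
    nx = int(arr[:, 1].max()) + 1
    nt = arr.shape[1] - 2
    counts = np.zeros((ny, nx, nt))
    for rec in arr:
        counts[int(rec[0]), int(rec[1]), :] = rec[2:]
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:  # toy default: clinical fundus timing
        meta = {
            "channel_width_ps": 12.2,
            "rep_period_ns": 12.5,
            "pixel_pitch_um": 59.0,
        }
    return _cube_from_counts(counts, meta)


def load_cube(
    path: str | Path,
    format_hint: str | None = None,
    channel_id: int | None = None,
) -> TCSPCCube:
    """Load a TCSPC cube from HDF5, TIFF+JSON sidecar or toy CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or path.suffix.lstrip(".").lower()
    if fmt in ("h5", "hdf5"):
        return _load_cube_h5(path, channel_id)
    if fmt in ("tif", "tiff"):
        return _load_cube_tiff(path)
    if fmt == "csv":
        return _load_cube_csv(path)
    raise FormatError(f"unknown cube format {fmt!r}")


def load_curve(
    path: str | Path,
    time: TimeAxis,
    kind: str = "irf",
    normalize: bool = False,
) -> IRFCurve | LensDecay:
    """Load a 1-D curve from two-column text (time_ps, counts).

    The curve is linearly resampled onto the channel centers of `time`.
    ``kind`` selects IRFCurve or LensDecay; ``normalize`` rescales to unit
    sum.
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter=None, ndmin=2)
    if data.shape[1] == 1:
        values = data[:, 0]
        if values.size != time.n_channels:
            raise MetadataError("single-column curve must match the time axis")
    else:
        t, v = data[:, 0], data[:, 1]
        values = np.interp(time.centers_ps(), t, v, left=0.0, right=0.0)
    if normalize and values.sum() > 0:
        values = values / values.sum()
    cls = IRFCurve if kind == "irf" else LensDecay
    return cls(values=values, time=time)


def save_results(results: FitResultMaps, out_dir: str | Path) -> dict:
    """Write result maps, summary statistics and provenance.

    Each map becomes a single-page 32-bit float TIFF; ``summary.csv`` holds
    per-map descriptive statistics; ``provenance.json`` records the model
    configuration and RNG seed.  Returns a manifest of written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    rows = []
    for name, arr in results.maps.items():
        fname = out / f"{name}.tiff"
        tifffile.imwrite(fname, np.asarray(arr, dtype=np.float32))
        manifest[name] = str(fname)
        finite = np.asarray(arr, dtype=float)
        finite = finite[np.isfinite(finite)]
        rows.append(
            {
                "map": name,
                "mean": float(finite.mean()),
                "median": float(np.median(finite)),
                "std": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
                "min": float(finite.min()),
                "max": float(finite.max()),
                "count": int(finite.size),
            }
        )
    summary = out / "summary.csv"
    pd.DataFrame(rows).to_csv(summary, index=False)
    manifest["summary"] = str(summary)
    prov = out / "provenance.json"
    prov.write_text(
        json.dumps(
            {
                "provenance": results.provenance,
                "artifact_intervals": [list(iv) for iv in results.artifact_intervals],
            },
            indent=2,
        )
    )
    manifest["provenance"] = str(prov)
    return manifest
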