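"""Readers and writers for the pipeline's on-disk formats.

Traces: two-column CSV (time_s, counts) or flat binary uint32 + JSON
sidecar. Curves: CSV (lag_s, G, sd, n). Images: multi-page TIFF (one page
per z-plane) with voxel sizes both in the TIFF resolution tags and in a
JSON sidecar. Tables: plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd
import tifffile

from .types import CorrelationCurve, IntensityTrace, MorphometryRecord, NucleusImage

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_binary",
    "read_trace_binary",
    "write_curve_csv",
    "read_curve_csv",
    "write_nucleus_tiff",
    "read_nucleus_tiff",
    "write_morphometry_csv",
]

PathLike = Union[str, Path]


def write_trace_csv(trace: IntensityTrace, path: PathLike) -> None:
    df = pd.DataFrame({"time_s": trace.times, "counts": trace.counts})
    df.to_csv(path, index=False)


def read_trace_csv(path: PathLike, **meta) -> IntensityTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace file must contain >= 2 bins")
    bin_width = float(np.median(np.diff(t)))
    return IntensityTrace(counts=df["counts"].to_numpy(), bin_width=bin_width, **meta)


def write_trace_binary(trace: IntensityTrace, path: PathLike, **extra) -> None:
    """Flat uint32 counts plus a JSON sidecar with acquisition metadata."""
    path = Path(path)
    trace.counts.astype("<u4").tofile(path)
    sidecar = {
        "bin_width": trace.bin_width,
        "duration": trace.duration,
        "n_bins": int(trace.counts.size),
        "label": trace.label,
        "condition": trace.condition,
        **extra,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace_binary(path: PathLike) -> IntensityTrace:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    counts = np.fromfile(path, dtype="<u4").astype(np.int64)
    return IntensityTrace(
        counts=counts,
        bin_width=float(sidecar["bin_width"]),
        label=sidecar.get("label", ""),
        condition=sidecar.get("condition", ""),
    )


def write_curve_csv(curve: CorrelationCurve, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "lag_s": curve.lags,
            "G": curve.g,
            "sd": curve.sd if curve.sd is not None else np.full(curve.lags.size, np.nan),
            "n": curve.n_traces_averaged,
        }
    )
    df.to_csv(path, index=False)


def read_curve_csv(path: PathLike, **meta) -> CorrelationCurve:
    df = pd.read_csv(path)
    sd = df["sd"].to_numpy() if "sd" in df and not df["sd"].isna().all() else None
    n = int(df["n"].iloc[0]) if "n" in df else 1
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(), g=df["G"].to_numpy(), sd=sd, n_traces_averaged=n, **meta
    )


def write_nucleus_tiff(image: NucleusImage, path: PathLike) -> None:
    """Multi-page TIFF (z-pages) with resolution tags + JSON sidecar."""
    path = Path(path)
    dx, dy, dz = image.voxel_size
    tifffile.imwrite(
        path,
        image.data.astype(np.float32),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
        imagej=True,
    )
    sidecar = {"voxel_size_um": [dx, dy, dz], "channel": image.channel}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_nucleus_tiff(path: PathLike) -> NucleusImage:
    """Read a z-stack; voxel sizes from the sidecar, else the TIFF tags."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        voxel = tuple(sidecar["voxel_size_um"])
        channel = sidecar.get("channel", "")
    else:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            meta = tf.imagej_metadata or {}
            dx = xres.value[1] / xres.value[0] if xres else 1.0
            dy = yres.value[1] / yres.value[0] if yres else 1.0
            dz = float(meta.get("spacing", 1.0))
        voxel, channel = (dx, dy, dz), ""
    return NucleusImage(data=np.asarray(data, dtype=float), voxel_size=voxel, channel=channel)


def write_morphometry_csv(records: List[MorphometryRecord], path: PathLike) -> None:
    pd.DataFrame([r.as_row() for r in records]).to_csv(path, index=False)
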