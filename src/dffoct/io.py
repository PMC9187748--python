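"""Readers and writers: TIFF stacks, trace CSVs, configs, geometry sidecars.

Physical calibration always comes from the configuration, never from TIFF
tags: the pixel pitch and frame timing are instrument knowledge (e.g. a
320 um field on a 1440 px camera), and files routinely carry stale or absent
metadata.  Tags found in a file are reported back to the caller but do not
override the config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, InvalidInputError
from .params import PipelineConfig
from .profiler import RoiPolygon, ScratchLine, WoundTrace

TRACE_COLUMNS = [
    "time_min",
    "area_px",
    "area_um2",
    "width_min_um",
    "width_mean_um",
    "width_max_um",
    "closure_pct",
]


def read_stack(path):
    """Read a multi-page grayscale TIFF as a (T, H, W) array plus metadata.

    Single-page files yield a stack of length 1.  Mixed page shapes or RGB
    pages raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) != 1:
                raise FormatError(f"{path}: pages have mixed shapes {shapes}")
            (shape,) = shapes
            if len(shape) != 2:
                raise FormatError(f"{path}: pages are not grayscale (shape {shape})")
            arr = tif.asarray()
            meta = {
                "n_pages": len(tif.pages),
                "dtype": str(arr.dtype),
                "resolution_tag": getattr(tif.pages[0], "resolution", None),
            }
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot read as multi-page TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: unexpected array shape {arr.shape}")
    return arr, meta


def write_stack(path, stack) -> None:
    """Write a (T, H, W) array as a multi-page TIFF, preserving dtype."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidInputError("stack must be 2-D or 3-D")
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def trace_to_frame(trace: WoundTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_min": trace.times,
            "area_px": trace.area_px,
            "area_um2": trace.area_um2,
            "width_min_um": trace.width_min_um,
            "width_mean_um": trace.width_mean_um,
            "width_max_um": trace.width_max_um,
            "closure_pct": trace.closure_pct,
        }
    )


def export_trace(trace: WoundTrace, path) -> None:
    """Write a wound trace as CSV with the canonical column header."""
    df = trace_to_frame(trace)
    df.to_csv(Path(path), index=False, float_format="%.17g")


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if list(df.columns) != TRACE_COLUMNS:
        raise FormatError(
            f"{path}: unexpected trace columns {list(df.columns)}; "
            f"expected {TRACE_COLUMNS}"
        )
    return df


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of a config, for run logging."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def save_geometry(path, line: ScratchLine | None = None, roi: RoiPolygon | None = None) -> None:
    """Write a JSON geometry sidecar (0-based (row, col), origin top-left)."""
    data: dict = {"indexing": "row-col", "origin": "top-left", "base": 0}
    if line is not None:
        data["line"] = [list(map(float, line.p0)), list(map(float, line.p1))]
    if roi is not None:
        data["roi"] = {
            "vertices": [list(map(float, v)) for v in roi.vertices],
            "reference_frame": roi.reference_frame,
        }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def load_geometry(path):
    """Read a geometry sidecar; returns ``(line_or_None, roi_or_None)``."""
    with open(path) as fh:
        data = json.load(fh)
    line = None
    roi = None
    if "line" in data:
        p0, p1 = data["line"]
        line = ScratchLine(p0=tuple(p0), p1=tuple(p1))
    if "roi" in data:
        roi = RoiPolygon(
            vertices=[tuple(v) for v in data["roi"]["vertices"]],
            reference_frame=data["roi"].get("reference_frame", "first"),
        )
    return line, roi
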