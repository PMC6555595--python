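"""Table and image IO with schema validation.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header row;
units are encoded in column names (``_um``, ``_um2``, ``_deg``).  Coordinates
in files are µm (0-based pixel centers converted on ingest when they come
from images).  Images are single-plane grayscale TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

SCHEMAS: dict[str, dict] = {
    "perimeter_profile": {
        "columns": ["cell_id", "sample_index", "intensity"],
        "numeric": ["sample_index", "intensity"],
        "unique": ["cell_id", "sample_index"],
    },
    "polyline": {
        "columns": ["trace_id", "point_index", "x_um", "y_um"],
        "numeric": ["point_index", "x_um", "y_um"],
        "unique": ["trace_id", "point_index"],
    },
    "island_spans": {
        "columns": ["cell_id", "span_start_um", "span_end_um"],
        "numeric": ["span_start_um", "span_end_um"],
        "unique": [],
    },
    "segments": {
        "columns": ["segment_id", "x1_um", "y1_um", "x2_um", "y2_um"],
        "numeric": ["x1_um", "y1_um", "x2_um", "y2_um"],
        "unique": ["segment_id"],
    },
    "cross_profile": {
        "columns": ["segment_id", "position_um", "intensity"],
        "numeric": ["position_um", "intensity"],
        "unique": ["segment_id", "position_um"],
    },
    "roi": {
        "columns": ["cell_id", "roi_id", "vertex_index", "x_um", "y_um",
                    "touches_border"],
        "numeric": ["vertex_index", "x_um", "y_um", "touches_border"],
        "unique": ["cell_id", "roi_id", "vertex_index"],
    },
    "fan": {
        "columns": ["cell_id", "cx_um", "cy_um", "eax_um", "eay_um", "ebx_um",
                    "eby_um", "sx_um", "sy_um"],
        "numeric": ["cx_um", "cy_um", "eax_um", "eay_um", "ebx_um", "eby_um",
                    "sx_um", "sy_um"],
        "unique": ["cell_id"],
    },
    "lengths": {
        "columns": ["trace_id", "length_um"],
        "numeric": ["length_um"],
        "unique": ["trace_id"],
    },
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Errors name the offending column and 1-based data row so files can be
    fixed by hand.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {missing} required by schema "
            f"{schema_name!r}"
        )
    df = df[schema["columns"]].copy()
    for col in schema["numeric"]:
        probe = pd.to_numeric(df[col], errors="coerce")
        if probe.isna().any():
            row = int(probe.isna().idxmax()) + 1
            raise SchemaError(
                f"{path.name}: non-numeric value in column {col!r} at data row {row}"
            )
        # Python's float() is correctly rounded; pandas' fast parser is not
        df[col] = np.array([float(s) for s in df[col]], dtype=float)
    key = schema["unique"]
    if key and df.duplicated(subset=key).any():
        row = int(df.duplicated(subset=key).idxmax()) + 1
        raise SchemaError(
            f"{path.name}: duplicate key {tuple(key)} at data row {row}"
        )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_image(path, pixel_um: float | None = None) -> tuple[np.ndarray, float | None]:
    """Read a single-plane grayscale TIFF; returns (array, pixel size in µm).

    The pixel size from the caller's configuration wins; TIFF resolution
    metadata is consulted only when no configured value is given.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{Path(path).name}: RGB/multi-channel image; select a single "
            "grayscale channel before analysis"
        )
    if arr.ndim != 2:
        raise ValueError(f"{Path(path).name}: expected a single 2-D plane")
    if pixel_um is None:
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_um = den / num  # resolution stored as px per unit
    return np.asarray(arr, dtype=float), pixel_um


def write_image(image: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def polylines_to_frame(polylines, prefix: str = "trace") -> pd.DataFrame:
    rows = []
    for t, pts in enumerate(polylines):
        for i, (x, y) in enumerate(np.asarray(pts, dtype=float)):
            rows.append((f"{prefix}{t:04d}", i, x, y))
    return pd.DataFrame(rows, columns=SCHEMAS["polyline"]["columns"])


def frame_to_polylines(df: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("point_index")
        out[str(tid)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
    return out
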