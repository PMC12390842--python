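"""Volume and table I/O with spacing metadata.

Volumes are single-file TIFFs whose image description carries a JSON blob
with the voxel spacing (um) and frame interval; tables are CSVs with schema
headers.  Round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Malformed file or missing required metadata."""


def write_volume(path, volume: np.ndarray, spacing,
                 frame_interval: float | None = None) -> None:
    meta = {"spacing_um": [float(s) for s in spacing]}
    if frame_interval is not None:
        meta["frame_interval_h"] = float(frame_interval)
    tifffile.imwrite(Path(path), volume, description=json.dumps(meta))


def read_volume(path):
    """Returns ``(array, spacing, frame_interval_or_None)``."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:  # noqa: BLE001 - normalize to a typed error
        raise FormatError(f"cannot read TIFF volume {path}: {exc}") from exc
    try:
        meta = json.loads(desc)
        spacing = tuple(meta["spacing_um"])
    except Exception as exc:
        raise FormatError(
            f"{path} lacks spacing metadata in its description"
        ) from exc
    return arr, spacing, meta.get("frame_interval_h")


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing table {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"malformed CSV table {path}: {exc}") from exc
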