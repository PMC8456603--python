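"""Readers and writers for the tabular and image formats the pipeline uses.

Track and trace tables are plain CSV with fixed column names shared by
the generators and the analysis stages; images are 16-bit grayscale
TIFF; coordinates are PDB ATOM records; ground truth travels as sidecar
JSON next to the data file it describes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .growth_stats import GrowthCurve
from .imagequant import ImageField
from .motility import TrackSet
from .photobleach import IntensityTrace

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_tiff",
    "read_tiff",
    "write_growth_csv",
    "read_growth_csv",
    "write_groups_csv",
    "read_groups_csv",
    "write_ground_truth",
    "read_ground_truth",
]

TRACK_COLUMNS = ["track_id", "t_s", "x_nm", "intensity_au"]
TRACE_COLUMNS = ["particle_id", "t_s", "intensity_au"]


def write_tracks_csv(tracks: TrackSet, path: str | Path) -> None:
    tracks.to_dataframe().to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> TrackSet:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return TrackSet.from_dataframe(df)


def write_traces_csv(traces: list[IntensityTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for t, y in zip(tr.times, tr.intensities):
            rows.append({"particle_id": tr.particle_id, "t_s": t, "intensity_au": y})
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    out = []
    for pid, g in df.groupby("particle_id", sort=False):
        g = g.sort_values("t_s")
        out.append(
            IntensityTrace(str(pid), g["t_s"].to_numpy(), g["intensity_au"].to_numpy())
        )
    return out


def write_tiff(image: ImageField, path: str | Path) -> None:
    """Save as 16-bit grayscale; values are clipped to the uint16 range."""
    data = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_tiff(path: str | Path, pixel_size_um: float, channel: str = "") -> ImageField:
    return ImageField(
        tifffile.imread(path).astype(float), pixel_size_um, channel=channel
    )


def write_growth_csv(curve: GrowthCurve, path: str | Path) -> None:
    pd.DataFrame({"t_min": curve.times_min, "od600": curve.od}).to_csv(
        path, index=False
    )


def read_growth_csv(path: str | Path) -> GrowthCurve:
    df = pd.read_csv(path)
    return GrowthCurve(df["t_min"].to_numpy(), df["od600"].to_numpy())


def write_groups_csv(groups: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [
        {"group": name, "value": float(v)}
        for name, values in groups.items()
        for v in np.asarray(values).ravel()
    ]
    pd.DataFrame(rows, columns=["group", "value"]).to_csv(path, index=False)


def read_groups_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        str(name): g["value"].to_numpy() for name, g in df.groupby("group", sort=False)
    }


def write_ground_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_jsonify)


def read_ground_truth(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
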