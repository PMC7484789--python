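"""Readers and writers for the plain-text formats the pipeline consumes.

Tables are TSV/CSV via pandas, intervals are BED (0-based half-open,
optionally a 4th state/label column), volumes are single-channel TIFF
stacks or named arrays in an ``.npz`` archive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

FIBRE_TRACK_COLUMNS = [
    "track_id", "first_len_um", "second_len_um", "first_pulse_min", "second_pulse_min",
]
PAIR_COLUMNS = ["origin_id", "left_um", "right_um", "pulse_min"]
TRACE_COLUMNS = ["t_min", "reporter", "normalizer"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_fibre_tracks(path) -> pd.DataFrame:
    return _require_columns(pd.read_csv(path, sep="\t"), FIBRE_TRACK_COLUMNS, path)


def read_pairs(path) -> pd.DataFrame:
    return _require_columns(pd.read_csv(path, sep="\t"), PAIR_COLUMNS, path)


def read_trace(path) -> pd.DataFrame:
    return _require_columns(pd.read_csv(path, sep="\t"), TRACE_COLUMNS, path)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_bed(path, with_label: bool = False) -> pd.DataFrame:
    """Read a 3- or 4-column BED file (chrom, start, end[, label])."""
    names = ["chrom", "start", "end"] + (["state"] if with_label else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(len(names)), names=names)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end at line {bad[0] + 1}")
    return df


def write_bed(df: pd.DataFrame, path, label_column: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    columns = ["chrom", "start", "end"] + ([label_column] if label_column else [])
    df[columns].to_csv(path, sep="\t", header=False, index=False)


def read_volume(path) -> np.ndarray:
    """Read a single-channel 3D volume from TIFF or an .npy file."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    elif path.suffix == ".npy":
        arr = np.load(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {arr.shape}")
    return arr


def write_volume(arr: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    elif path.suffix == ".npy":
        np.save(path, arr)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")
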