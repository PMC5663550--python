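"""File-format helpers: TIFF stacks, label masks, CSV tables, YAML configs.

All images travel as single-channel TIFF (multipage for stacks, integer
labels for masks with 0 = background); all tables are CSV with a header
row; run configuration is YAML.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import InputError

PathLike = Union[str, Path]


def write_stack_tiff(path: PathLike, stack: np.ndarray, multipage: bool = True) -> list:
    """Write an image stack as one multipage TIFF or one file per frame.

    Returns the list of paths written.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InputError("stack must be (n_frames, height, width)")
    path = Path(path)
    if multipage:
        tifffile.imwrite(path, stack.astype(np.float32))
        return [path]
    paths = []
    for i, frame in enumerate(stack):
        p = path.with_name(f"{path.stem}_f{i:03d}{path.suffix}")
        tifffile.imwrite(p, frame.astype(np.float32))
        paths.append(p)
    return paths


def read_stack_tiff(path: PathLike) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return np.asarray(arr, dtype=float)


def write_image_tiff(path: PathLike, image: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def write_label_tiff(path: PathLike, mask: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))
    return path


def read_image_tiff(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def read_label_tiff(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int64)


def write_frame_times_csv(path: PathLike, times_min: Sequence[float]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"frame_index": np.arange(len(times_min)), "minutes": np.asarray(times_min, float)}
    ).to_csv(path, index=False)
    return path


def read_frame_times_csv(path: PathLike) -> np.ndarray:
    df = pd.read_csv(path)
    if "minutes" not in df.columns:
        raise InputError("frame-times CSV needs a 'minutes' column")
    return df.sort_values("frame_index")["minutes"].to_numpy(float) \
        if "frame_index" in df.columns else df["minutes"].to_numpy(float)


def read_trace_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"minutes", "c_pf", "c_cc"} - set(df.columns)
    if missing:
        raise InputError(f"trace CSV missing columns {sorted(missing)}")
    return df


def load_yaml_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_yaml_config(path: PathLike, config: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def config_hash(config: dict) -> str:
    """Stable content hash of a config mapping (for run logs)."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
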