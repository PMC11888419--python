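"""File I/O conventions: TIFF stacks, PNG directories, tidy CSV + YAML.

Every CSV written by the pipeline carries a commented header recording
the seed and configuration hash so any output table can be traced back
to the run that produced it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ParameterError

PathLike = Union[str, Path]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def read_frames(path: PathLike) -> np.ndarray:
    """Read a frame sequence from a TIFF stack or a directory of images.

    Directories are read in sorted filename order.  Returns an array of
    shape (n_frames, H, W); single-image files yield n_frames = 1.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ParameterError(f"no image files in {p}")
        frames = [np.asarray(iio.imread(f)) for f in files]
        return np.stack(frames)
    if not p.exists():
        raise ParameterError(f"no such frame source: {p}")
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = np.asarray(iio.imread(p))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_frames(path: PathLike, frames: np.ndarray) -> Path:
    """Write frames as a multi-page TIFF (one page per frame)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(p, np.asarray(frames))
    return p


def write_table(
    df: pd.DataFrame, path: PathLike, meta: Optional[Mapping[str, object]] = None
) -> Path:
    """Write a tidy CSV with a commented metadata header."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
    return p


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_yaml(obj: Mapping, path: PathLike) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)
    return p


def read_yaml(path: PathLike) -> Dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(obj: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(dict(obj), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
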