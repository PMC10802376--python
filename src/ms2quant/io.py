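"""Readers and writers shared by the pipeline stages.

Volumes move as (T, Z, Y, X) arrays stored either as chunked zarr (one
chunk per time point, matching the out-of-memory access pattern of large
light-sheet datasets) or multi-page TIFF. Tabular outputs are CSV with
JSON sidecars for metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import zarr


def write_movie(path, movie: np.ndarray, pixel_size=None):
    """Write a (T, Z, Y, X) movie as zarr (.zarr) or TIFF (.tif/.tiff)."""
    path = Path(path)
    movie = np.asarray(movie)
    if path.suffix == ".zarr":
        arr = zarr.open(str(path), mode="w", shape=movie.shape,
                        chunks=(1,) + movie.shape[1:], dtype=movie.dtype)
        arr[:] = movie
        if pixel_size is not None:
            arr.attrs["pixel_size"] = list(pixel_size)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie)
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")


def read_movie(path) -> np.ndarray:
    """Read a (T, Z, Y, X) movie from zarr or TIFF."""
    path = Path(path)
    if path.suffix == ".zarr":
        return np.asarray(zarr.open(str(path), mode="r"))
    if path.suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    raise ValueError(f"unsupported movie format: {path.suffix}")


def write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonify)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
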