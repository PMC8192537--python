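"""Single-band TIFF raster I/O.

Rasters are written as single-band TIFFs with the georeferencing metadata
(origin, cell size, cell area, nodata value) serialized as JSON into the
ImageDescription tag, so a write/read round trip reproduces both values and
grid registration bit-exactly.  Continuous layers are stored as float32 with
NaN nodata; binary masks as uint8 with 255 nodata.
"""

from __future__ import annotations

import json
import os

import numpy as np
import tifffile

from .grid import BinaryMask, Grid, GridMismatchError, Layer

_NODATA_U8 = 255


def _grid_meta(grid: Grid) -> str:
    return json.dumps(
        {
            "x0": grid.x0,
            "y0": grid.y0,
            "dx": grid.dx,
            "dy": grid.dy,
            "cell_area": grid.cell_area,
        }
    )


def write_raster(layer: Layer | BinaryMask, path: str) -> None:
    """Write a Layer (float64, NaN nodata) or BinaryMask (uint8, 255 nodata)."""
    grid = layer.grid
    if isinstance(layer, BinaryMask):
        data = layer.values.astype(np.uint8).copy()
        data[grid.nodata_mask] = _NODATA_U8
    else:
        data = layer.values.astype(np.float64)
    tifffile.imwrite(path, data, description=_grid_meta(grid))


def read_raster(path: str, grid: Grid | None = None) -> Layer | BinaryMask:
    """Read a single-band TIFF into a Layer or BinaryMask.

    Integer rasters whose valid values are all 0/1 load as :class:`BinaryMask`
    (255 = nodata); floating rasters load as :class:`Layer` (NaN = nodata).
    When ``grid`` is given, the file must register to it exactly, else
    :class:`GridMismatchError` is raised.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise ValueError(f"{path}: expected a single-band raster, got {len(tf.pages)} pages")
        page = tf.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D single-band raster, got shape {data.shape}")

    if np.issubdtype(data.dtype, np.integer):
        nodata = data == _NODATA_U8
        values = np.where(nodata, 0, data)
        file_grid = _make_grid(data.shape, meta, nodata)
        if grid is not None:
            file_grid = _reconcile(file_grid, grid, path)
        return BinaryMask(file_grid, values)

    data = data.astype(float)
    nodata = ~np.isfinite(data)
    values = np.where(nodata, 0.0, data)
    file_grid = _make_grid(data.shape, meta, nodata)
    if grid is not None:
        file_grid = _reconcile(file_grid, grid, path)
    out = Layer(file_grid, values)
    out.values[nodata] = np.nan
    return out


def _make_grid(shape: tuple[int, int], meta: dict, nodata: np.ndarray) -> Grid:
    return Grid(
        n_rows=shape[0],
        n_cols=shape[1],
        x0=float(meta.get("x0", 0.0)),
        y0=float(meta.get("y0", 0.0)),
        dx=float(meta.get("dx", 1.0)),
        dy=float(meta.get("dy", 1.0)),
        cell_area=float(meta.get("cell_area", 1.0)),
        nodata_mask=nodata,
    )


def _reconcile(file_grid: Grid, grid: Grid, path: str) -> Grid:
    if not file_grid.compatible(grid):
        raise GridMismatchError(
            f"{path}: raster (shape {file_grid.shape}) does not match the "
            f"registered grid (shape {grid.shape})"
        )
    return grid
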