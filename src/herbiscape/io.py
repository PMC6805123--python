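"""On-disk formats: GeoTIFF rasters via tifffile and documented CSV tables.

Rasters are written north-up, one band per layer, with minimal GeoTIFF
georeferencing (ModelPixelScale / ModelTiepoint tags, cell-centre
registration) so standard GIS tools place the grid correctly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import LandscapeGrid

__all__ = [
    "write_raster",
    "read_raster",
    "write_grid_rasters",
    "write_surface_csv",
]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_raster(
    path: str | Path,
    layers: dict[str, np.ndarray],
    shape: tuple[int, int],
    cell_size: float = 500.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> None:
    """Write flat layers as a multi-band GeoTIFF (one band per layer).

    ``shape`` is (rows, cols); ``origin`` is the map coordinate of the
    top-left raster corner.  Band names are stored in the image description.
    """
    names = list(layers)
    stack = np.stack([np.asarray(layers[n], float).reshape(shape) for n in names])
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cell_size, cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, origin[0], origin[1], 0.0)),
    ]
    tifffile.imwrite(
        str(path),
        stack.astype(np.float32),
        description=json.dumps({"bands": names, "cell_size": cell_size}),
        extratags=extratags,
    )


def read_raster(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """Read a raster written by :func:`write_raster`.

    Returns ({band name: flat array}, cell size).
    """
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    if stack.ndim == 2:
        stack = stack[None]
    layers = {
        name: stack[i].astype(float).ravel() for i, name in enumerate(meta["bands"])
    }
    return layers, float(meta["cell_size"])


def write_grid_rasters(path: str | Path, grid: LandscapeGrid) -> None:
    """All covariate layers of a grid as one multi-band GeoTIFF."""
    write_raster(path, grid.covariates, grid.shape, grid.cell_size)


def write_surface_csv(path: str | Path, surface: pd.DataFrame) -> None:
    """Cellwise posterior surface (cell, mean, CI columns) as CSV."""
    surface.to_csv(path, index=False)
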