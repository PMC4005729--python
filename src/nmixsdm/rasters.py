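"""ESRI ASCII grid (.asc) reading and writing.

A minimal, text-based raster format: a six-line header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by rows of values,
top row first. Values are written with repr-stable formatting so that a
fixed seed yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grids import GridGeometry

NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: np.ndarray, geometry: GridGeometry,
                     mask: np.ndarray | None = None) -> None:
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (geometry.n_rows, geometry.n_cols):
        raise ValueError("grid shape does not match geometry")
    out = grid.copy()
    if mask is not None:
        out[~mask] = NODATA
    out[np.isnan(out)] = NODATA
    lines = [
        f"ncols {geometry.n_cols}",
        f"nrows {geometry.n_rows}",
        f"xllcorner {geometry.x0!r}",
        f"yllcorner {geometry.y0!r}",
        f"cellsize {geometry.cell_size!r}",
        f"NODATA_value {NODATA!r}",
    ]
    for row in out:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry, np.ndarray]:
    """Returns (grid with NaN at nodata, geometry, validity mask)."""
    text = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    rows = [np.array(line.split(), dtype=float) for line in text[i:] if line.strip()]
    grid = np.vstack(rows)
    geom = GridGeometry(
        n_rows=int(header["nrows"]), n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        x0=header.get("xllcorner", 0.0), y0=header.get("yllcorner", 0.0),
    )
    if grid.shape != (geom.n_rows, geom.n_cols):
        raise ValueError(f"{path}: data shape {grid.shape} does not match header")
    nodata = header.get("nodata_value", NODATA)
    mask = grid != nodata
    grid = np.where(mask, grid, np.nan)
    return grid, geom, mask
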