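"""ESRI ASCII grid raster I/O on the analysis grid.

Layers are numpy arrays with row 0 at the *southern* edge (matching
:class:`~hydrofowl.grid.GridSpec`); the ASCII grid format stores rows
north-to-south, so reading/writing flips the row order.  NaN represents
nodata in memory.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec

DEFAULT_NODATA = -9999.0


def write_ascii_grid(path, layer: np.ndarray, grid: GridSpec, nodata: float = DEFAULT_NODATA) -> None:
    layer = np.asarray(layer, dtype=float)
    if layer.shape != grid.shape:
        raise ValueError(f"layer shape {layer.shape} does not match grid {grid.shape}")
    out = np.where(np.isnan(layer), nodata, layer)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.lon_origin!r}\n")
        fh.write(f"yllcorner {grid.lat_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out[::-1]:  # north to south
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {req}")
    arr = np.array(rows, dtype=float)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {arr.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr[arr == nodata] = np.nan
    grid = GridSpec(
        lat_origin=header["yllcorner"],
        lon_origin=header["xllcorner"],
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    return arr[::-1].copy(), grid  # back to row 0 = south
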