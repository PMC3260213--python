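"""Regular lat/lon analysis grid and great-circle geometry.

Banding and encounter locations are only known to 10-minute (1/6 degree)
precision, so every spatial quantity in the package lives on a regular
grid of half-open cells: ``[edge, edge + cell_size)`` in both latitude and
longitude, with row 0 at the southern edge and column 0 at the western
edge.  Distances between records are always computed between cell centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

#: IUGG mean Earth radius, kilometres.
EARTH_RADIUS_KM = 6371.0088

#: 10 minutes of arc in degrees.
TEN_MINUTES = 1.0 / 6.0


class CellIndex(NamedTuple):
    """Row/column index of one grid cell (row 0 = southern edge)."""

    row: int
    col: int


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid of half-open cells.

    Parameters
    ----------
    lat_origin, lon_origin:
        Southern and western edges of the grid, decimal degrees.
    cell_size:
        Cell edge length in degrees; default 1/6 degree (10 minutes).
    n_rows, n_cols:
        Grid shape.
    """

    lat_origin: float
    lon_origin: float
    n_rows: int
    n_cols: int
    cell_size: float = TEN_MINUTES

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def lat_max(self) -> float:
        return self.lat_origin + self.n_rows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_origin + self.n_cols * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_centers(self) -> np.ndarray:
        """Latitudes of all row centers (length ``n_rows``)."""
        return self.lat_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def col_centers(self) -> np.ndarray:
        """Longitudes of all column centers (length ``n_cols``)."""
        return self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.lat_origin <= lat < self.lat_max
            and self.lon_origin <= lon < self.lon_max
        )

    def to_dict(self) -> dict:
        return {
            "lat_origin": self.lat_origin,
            "lon_origin": self.lon_origin,
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            lat_origin=float(d["lat_origin"]),
            lon_origin=float(d["lon_origin"]),
            cell_size=float(d.get("cell_size", TEN_MINUTES)),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
        )


def _validate_coords(lat: float, lon: float) -> None:
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")


def bin_to_grid(lat: float, lon: float, grid: GridSpec) -> CellIndex:
    """Bin a point into its half-open grid cell.

    Raises
    ------
    ValueError
        If the point lies outside the grid bounding box; the message names
        the offending coordinate.
    """
    _validate_coords(lat, lon)
    if not grid.lat_origin <= lat < grid.lat_max:
        raise ValueError(
            f"latitude {lat} outside grid range [{grid.lat_origin}, {grid.lat_max})"
        )
    if not grid.lon_origin <= lon < grid.lon_max:
        raise ValueError(
            f"longitude {lon} outside grid range [{grid.lon_origin}, {grid.lon_max})"
        )
    row = int(math.floor((lat - grid.lat_origin) / grid.cell_size))
    col = int(math.floor((lon - grid.lon_origin) / grid.cell_size))
    # guard against floating-point edge landing exactly on the upper bound
    row = min(row, grid.n_rows - 1)
    col = min(col, grid.n_cols - 1)
    return CellIndex(row, col)


def cell_center(cell: CellIndex, grid: GridSpec) -> tuple[float, float]:
    """(lat, lon) of a cell's center."""
    row, col = cell
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise ValueError(f"cell {cell!r} outside grid of shape {grid.shape}")
    lat = grid.lat_origin + (row + 0.5) * grid.cell_size
    lon = grid.lon_origin + (col + 0.5) * grid.cell_size
    return lat, lon


def great_circle_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine great-circle distance in km on a sphere of IUGG mean radius."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    _validate_coords(lat1, lon1)
    _validate_coords(lat2, lon2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    a = min(1.0, a)
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))
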