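"""Banding / band-recovery records: data model and CSV I/O.

Each record is one event in the life of one banded bird — either the
banding itself or a subsequent encounter (almost always a terminal,
hunter-reported recovery).  Every event location is a known presence of
the species at the analysis-grid resolution.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .grid import CellIndex, GridSpec, bin_to_grid

EVENT_TYPES = ("banding", "recovery")

CSV_HEADER = ["band_id", "species", "event", "date", "lat", "lon"]


@dataclass(frozen=True)
class EncounterRecord:
    """One banding or recovery event of one banded individual."""

    band_id: str
    species: str
    event: str  # "banding" | "recovery"
    date: _dt.date
    lat: float
    lon: float
    cell: CellIndex | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", float(self.lat))
        object.__setattr__(self, "lon", float(self.lon))
        if self.event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event!r}; expected one of {EVENT_TYPES}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")

    @property
    def day_number(self) -> int:
        """Proleptic-Gregorian ordinal day — makes day arithmetic exact."""
        return self.date.toordinal()

    @property
    def doy(self) -> int:
        """Day of year, with Dec 31 of leap years folded onto day 365."""
        return min(self.date.timetuple().tm_yday, 365)

    def with_cell(self, grid: GridSpec) -> "EncounterRecord":
        return replace(self, cell=bin_to_grid(self.lat, self.lon, grid))


def assign_cells(records: Iterable[EncounterRecord], grid: GridSpec) -> list[EncounterRecord]:
    """Derive the grid cell of every record."""
    return [r.with_cell(grid) for r in records]


def read_records(path, grid: GridSpec | None = None) -> list[EncounterRecord]:
    """Read records from CSV (header ``band_id,species,event,date,lat,lon``).

    Dates are ISO-8601.  A malformed row raises ``ValueError`` naming the
    line number.  If *grid* is given, each record's cell index is derived.
    """
    records: list[EncounterRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = EncounterRecord(
                    band_id=row["band_id"],
                    species=row["species"],
                    event=row["event"],
                    date=_dt.date.fromisoformat(row["date"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            records.append(rec.with_cell(grid) if grid is not None else rec)
    return records


def write_records(records: Sequence[EncounterRecord], path) -> None:
    """Write records to CSV; round-trips with :func:`read_records` up to the derived cell."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow(
                [r.band_id, r.species, r.event, r.date.isoformat(), repr(r.lat), repr(r.lon)]
            )


def filter_study_window(
    records: Iterable[EncounterRecord], start: _dt.date, end: _dt.date
) -> list[EncounterRecord]:
    """Keep records with ``start <= date <= end`` (both ends inclusive)."""
    if start > end:
        raise ValueError(f"inverted study window: {start} > {end}")
    return [r for r in records if start <= r.date <= end]
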