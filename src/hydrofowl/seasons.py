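"""Species-specific annual-cycle delineation from band-recovery velocities.

Migration shows up in banding data as a burst of movement: birds recovered
within 30 days of banding have travelled far when banded during migration
and hardly at all otherwise.  Averaging the daily travel rate by calendar
week therefore produces a velocity series with two peaks — spring and fall
migration.  This module turns those peaks into four season windows
(spring, summer/breeding, fall, winter/non-breeding) that partition the
circular year.

Conventions
-----------
* Velocity pairs use recoveries 1–30 days after banding; same-day
  recoveries are dropped (velocity undefined).
* An observation is assigned to the calendar week of the pair's midpoint
  date; week 51 absorbs days 358–365.
* Peaks are maximal runs of weeks whose 3-week circular moving average
  exceeds mean + 0.5 sd of the smoothed series; the strongest run with
  midpoint in Jan–Jun becomes spring, in Jul–Dec becomes fall.  A half
  with no qualifying run falls back to prior windows from natural history.
* Season windows are day-of-year intervals, inclusive of the start and
  exclusive of the end, on a 365-day circular calendar.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .banding import EncounterRecord
from .grid import GridSpec, cell_center, great_circle_km

logger = logging.getLogger(__name__)

YEAR_DAYS = 365
N_WEEKS = 52

SEASONS = ("spring", "summer", "fall", "winter")


@dataclass(frozen=True)
class VelocityObservation:
    species: str
    midpoint_date: _dt.date
    km_per_day: float

    def __post_init__(self) -> None:
        if self.km_per_day < 0:
            raise ValueError("km_per_day must be non-negative")


@dataclass
class WeeklyVelocitySeries:
    """52 weekly mean daily-travel rates; weeks without data are NaN."""

    species: str
    values: np.ndarray  # length 52, NaN where count == 0
    counts: np.ndarray  # length 52, int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != (N_WEEKS,) or self.counts.shape != (N_WEEKS,):
            raise ValueError("weekly series must have exactly 52 entries")

    @property
    def n_informative_weeks(self) -> int:
        return int(np.sum(self.counts > 0))


@dataclass(frozen=True)
class SeasonWindows:
    """Four day-of-year intervals partitioning the circular year.

    ``spring`` and ``fall`` are the primary (detected or prior) migration
    windows as ``(start_doy, end_doy)``, inclusive start / exclusive end,
    circular.  Summer spans fall-back from spring end to fall start; winter
    wraps from fall end to spring start.
    """

    species: str
    spring: tuple[int, int]
    fall: tuple[int, int]
    source: str = "prior"  # detected | prior | adjusted

    def __post_init__(self) -> None:
        for name, (s, e) in (("spring", self.spring), ("fall", self.fall)):
            if not (1 <= s <= YEAR_DAYS and 1 <= e <= YEAR_DAYS + 1):
                raise ValueError(f"{name} window {s, e} outside day-of-year range")
        # spring must end before fall begins (circular order spring<summer<fall<winter)
        if not _circular_le(self.spring[1], self.fall[0], self.spring[0]):
            raise ValueError("spring window must precede fall window")

    @property
    def summer(self) -> tuple[int, int]:
        return (self.spring[1], self.fall[0])

    @property
    def winter(self) -> tuple[int, int]:
        return (self.fall[1], self.spring[0])

    def interval(self, season: str) -> tuple[int, int]:
        return {
            "spring": self.spring,
            "summer": self.summer,
            "fall": self.fall,
            "winter": self.winter,
        }[season]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "spring": list(self.spring),
            "fall": list(self.fall),
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeasonWindows":
        return cls(
            species=d["species"],
            spring=tuple(d["spring"]),
            fall=tuple(d["fall"]),
            source=d.get("source", "prior"),
        )


def _circular_le(a: int, b: int, ref: int) -> bool:
    """True if a occurs no later than b when the year is cut at ref."""
    return (a - ref) % YEAR_DAYS <= (b - ref) % YEAR_DAYS


def in_circular_interval(doy: int, start: int, end: int) -> bool:
    """Membership in the circular half-open interval [start, end)."""
    doy = (doy - 1) % YEAR_DAYS + 1
    if start == end:  # full year degenerate interval
        return True
    if start < end:
        return start <= doy < end
    return doy >= start or doy < end


def assign_season(date: _dt.date | int, windows: SeasonWindows) -> str:
    """Map a date (or day-of-year) to its season label."""
    doy = date if isinstance(date, int) else min(date.timetuple().tm_yday, YEAR_DAYS)
    for season in SEASONS:
        s, e = windows.interval(season)
        if in_circular_interval(doy, s, e):
            return season
    raise AssertionError("season windows do not partition the year")  # pragma: no cover


# ---------------------------------------------------------------------------
# velocity observations


def paired_recoveries(
    records: Iterable[EncounterRecord], max_days: int = 30
) -> list[tuple[EncounterRecord, EncounterRecord, int]]:
    """Match each recovery to its banding; keep pairs 1–max_days apart.

    Same-day recoveries are excluded (velocity undefined); recoveries with
    no matching banding are skipped with a logged count.
    """
    bandings: dict[str, EncounterRecord] = {}
    for r in records:
        if r.event == "banding" and r.band_id not in bandings:
            bandings[r.band_id] = r
    pairs = []
    unmatched = 0
    for r in records:
        if r.event != "recovery":
            continue
        b = bandings.get(r.band_id)
        if b is None:
            unmatched += 1
            continue
        elapsed = r.day_number - b.day_number
        if 1 <= elapsed <= max_days:
            pairs.append((b, r, elapsed))
    if unmatched:
        logger.info("paired_recoveries: %d recoveries had no matching banding", unmatched)
    return pairs


def daily_velocity(
    pair: tuple[EncounterRecord, EncounterRecord, int], grid: GridSpec
) -> VelocityObservation:
    """Great-circle distance between cell centers divided by elapsed days."""
    banding, recovery, elapsed = pair
    if elapsed < 1:
        raise ValueError("daily velocity requires at least one elapsed day")
    if banding.cell is None or recovery.cell is None:
        raise ValueError("records must carry derived cells; use assign_cells first")
    dist = great_circle_km(cell_center(banding.cell, grid), cell_center(recovery.cell, grid))
    midpoint = banding.date + _dt.timedelta(days=elapsed // 2)
    return VelocityObservation(
        species=banding.species, midpoint_date=midpoint, km_per_day=dist / elapsed
    )


def week_of_doy(doy: int) -> int:
    """Calendar week 0–51; week 51 absorbs days 358–365/366."""
    return min((doy - 1) // 7, N_WEEKS - 1)


def weekly_mean_series(observations: Sequence[VelocityObservation]) -> WeeklyVelocitySeries:
    """Average the daily-travel observations by calendar week of their midpoint."""
    if not observations:
        raise ValueError("weekly_mean_series requires at least one observation")
    sums = np.zeros(N_WEEKS)
    counts = np.zeros(N_WEEKS, dtype=int)
    species = observations[0].species
    for obs in observations:
        doy = min(obs.midpoint_date.timetuple().tm_yday, YEAR_DAYS)
        w = week_of_doy(doy)
        sums[w] += obs.km_per_day
        counts[w] += 1
    values = np.full(N_WEEKS, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    return WeeklyVelocitySeries(species=species, values=values, counts=counts)


# ---------------------------------------------------------------------------
# peak detection


def _circular_interpolate(values: np.ndarray) -> np.ndarray:
    """Fill NaNs by linear interpolation on the circle."""
    out = values.astype(float).copy()
    nan = np.isnan(out)
    if not nan.any():
        return out
    if nan.all():
        raise ValueError("cannot interpolate an all-missing series")
    n = len(out)
    idx = np.arange(n)
    good = idx[~nan]
    # unwrap onto a line covering one full period on each side
    x = np.concatenate([good - n, good, good + n])
    y = np.tile(out[good], 3)
    out[nan] = np.interp(idx[nan], x, y)
    return out


def _circular_moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    extended = np.concatenate([values[-pad:], values, values[:pad]])
    return np.convolve(extended, kernel, mode="valid")


def _circular_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of consecutive True weeks, joined across the wrap."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # cut the circle at a False position
    start = int(np.argmin(mask))
    order = (np.arange(n) + start) % n
    runs: list[np.ndarray] = []
    current: list[int] = []
    for i in order:
        if mask[i]:
            current.append(i)
        elif current:
            runs.append(np.array(current))
            current = []
    if current:
        runs.append(np.array(current))
    return runs


def _run_mid_week(run: np.ndarray) -> float:
    """Circular midpoint of a run of week indices (run is in circular order)."""
    first, length = run[0], len(run)
    return (first + (length - 1) / 2.0) % N_WEEKS


def _weeks_to_doy_window(run: np.ndarray) -> tuple[int, int]:
    start = int(run[0]) * 7 + 1
    # week 51 runs through day 365, so a run ending there wraps to doy 1
    end = 1 if run[-1] == N_WEEKS - 1 else (int(run[-1]) + 1) * 7 + 1
    return (start, end)


MIN_INFORMATIVE_WEEKS = 26


def detect_migration_windows(
    series: WeeklyVelocitySeries, prior: SeasonWindows
) -> SeasonWindows:
    """Delineate spring and fall migration from the weekly velocity series.

    Candidate migration periods are maximal runs of weeks whose smoothed
    velocity exceeds mean + 0.5 sd.  The run with the highest peak and
    midpoint in the first calendar half becomes spring; the highest in the
    second half becomes fall.  A half with no qualifying run — no clear
    migration signal — falls back to the *prior* window from natural
    history, and ``source`` records the mixture.
    """
    if series.n_informative_weeks < MIN_INFORMATIVE_WEEKS:
        logger.warning(
            "only %d informative weeks (<%d); using prior windows for %s",
            series.n_informative_weeks,
            MIN_INFORMATIVE_WEEKS,
            series.species,
        )
        return SeasonWindows(
            species=series.species, spring=prior.spring, fall=prior.fall, source="prior"
        )

    filled = _circular_interpolate(series.values)
    smoothed = _circular_moving_average(filled, window=3)
    mu, sigma = float(np.mean(smoothed)), float(np.std(smoothed))
    threshold = mu + 0.5 * sigma
    runs = _circular_runs(smoothed > threshold)

    spring_run = None
    fall_run = None
    spring_peak = fall_peak = -np.inf
    for run in runs:
        peak = float(np.max(smoothed[run]))
        mid = _run_mid_week(run)
        if mid < N_WEEKS / 2:  # midpoint in Jan–Jun
            if peak > spring_peak:
                spring_peak, spring_run = peak, run
        else:  # Jul–Dec
            if peak > fall_peak:
                fall_peak, fall_run = peak, run

    spring = _weeks_to_doy_window(spring_run) if spring_run is not None else prior.spring
    fall = _weeks_to_doy_window(fall_run) if fall_run is not None else prior.fall
    if spring_run is not None and fall_run is not None:
        source = "detected"
    elif spring_run is None and fall_run is None:
        source = "prior"
    else:
        source = "adjusted"
    return SeasonWindows(species=series.species, spring=spring, fall=fall, source=source)


def delineate_from_records(
    records: Sequence[EncounterRecord],
    grid: GridSpec,
    prior: SeasonWindows,
    max_days: int = 30,
) -> tuple[SeasonWindows, WeeklyVelocitySeries]:
    """Full delineation for one species: pairs -> velocities -> windows."""
    pairs = paired_recoveries(records, max_days=max_days)
    if not pairs:
        return (
            SeasonWindows(species=prior.species, spring=prior.spring, fall=prior.fall,
                          source="prior"),
            WeeklyVelocitySeries(
                species=prior.species,
                values=np.full(N_WEEKS, np.nan),
                counts=np.zeros(N_WEEKS, dtype=int),
            ),
        )
    observations = [daily_velocity(p, grid) for p in pairs]
    series = weekly_mean_series(observations)
    return detect_migration_windows(series, prior), series
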