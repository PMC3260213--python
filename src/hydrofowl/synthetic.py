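"""Synthetic landscapes and banding records with known ground truth.

Real waterfowl banding data and continental covariate rasters are access-
restricted or too large for tests, so this module generates statistically
analogous stand-ins in which the truth is known by construction:

* a covariate stack (temperature, precipitation, elevation, depth to water
  table, percent wetland) on the analysis grid, in which DWT is the
  equilibrium of climate recharge against topographic drainage
  (:mod:`hydrofowl.watertable`) and percent wetland is a noisy, negatively
  correlated proxy of shallow DWT;
* multi-species banding/recovery records with survey-effort bias (bandings
  cluster at stations), hunter-style terminal recoveries, and
  season-dependent daily movement, so migration timing, wetland affinity
  and sampling bias are all recoverable downstream.

Each species' habitat suitability is
``s = exp(-dwt/delta) * N(temp; opt, sd) * N(lat; seasonal center, sd)``:
``delta`` (metres) is the single wetland-affinity parameter — small
``delta`` means the species is tightly confined to shallow water tables.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .banding import EncounterRecord
from .grid import CellIndex, GridSpec, bin_to_grid
from .seasons import SeasonWindows, week_of_doy
from .watertable import Landscape, solve_equilibrium

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

COVARIATE_NAMES = ("temperature", "precipitation", "elevation", "dwt", "percent_wetland")
BASE_COVARIATES = ("temperature", "precipitation", "elevation")


def default_grid() -> GridSpec:
    """60 x 100 cells of 10 minutes: a ~10 x 16.7 degree mid-latitude window."""
    return GridSpec(lat_origin=28.0, lon_origin=-98.0, n_rows=60, n_cols=100)


@dataclass(frozen=True)
class LandscapeParams:
    """Knobs of the synthetic covariate stack (units in field comments)."""

    relief_sd: float = 30.0           # m, sd of the smoothed random topography
    smooth_sigma: float = 5.0         # cells, correlation length of topography
    regional_slope: float = 150.0     # m rise from west (coast) to east edge
    temp_at_south: float = 22.0       # deg C at the southern edge at sea level
    temp_lat_gradient: float = 0.8    # deg C lost per degree latitude
    lapse_rate: float = 6.5           # deg C per km elevation
    temp_noise_sd: float = 0.4        # deg C
    precip_west: float = 1150.0       # mm/yr at the west (coastal) edge
    precip_east: float = 760.0        # mm/yr at the east edge
    precip_noise_sd: float = 80.0     # mm/yr
    runoff_fraction: float = 0.15     # fraction of (P - PET) that recharges
    pet_base: float = 240.0           # mm/yr PET at 0 deg C
    pet_per_degree: float = 14.0      # mm/yr PET per deg C
    T0: float = 2.0e8                 # m^2/yr transmissivity at zero depth
    T_min_ratio: float = 1e-3         # deep residual transmissivity, as a ratio of T0
    f_depth: float = 2.5              # m, transmissivity e-folding depth
    river_fraction: float = 0.03      # lowest-elevation fraction fixed as rivers
    river_dwt: float = 0.2            # m, prescribed water-table depth in rivers
    wetland_steepness: float = 0.4    # 1/m, logistic slope of percent wetland vs dwt
    wetland_noise_sd: float = 0.45    # sd of the percent-wetland noise


@dataclass
class CovariateStack:
    """Gridded covariates plus the hydrologic inputs that produced them."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    landscape: Landscape
    params: LandscapeParams
    seed: int

    @property
    def lat(self) -> np.ndarray:
        """2-D latitude of cell centers."""
        return np.broadcast_to(
            self.grid.row_centers()[:, None], self.grid.shape
        ).copy()

    @property
    def lon(self) -> np.ndarray:
        return np.broadcast_to(
            self.grid.col_centers()[None, :], self.grid.shape
        ).copy()

    def covariate_matrix(self, cells: list[CellIndex], names=COVARIATE_NAMES) -> np.ndarray:
        """n_cells x n_covariates matrix of layer values at the given cells."""
        rows = np.array([c.row for c in cells])
        cols = np.array([c.col for c in cells])
        return np.column_stack([self.layers[name][rows, cols] for name in names])

    def valid_cells(self) -> list[CellIndex]:
        """Cells where every covariate is finite."""
        ok = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            ok &= np.isfinite(layer)
        return [CellIndex(int(r), int(c)) for r, c in zip(*np.nonzero(ok))]


def _cell_length_m(grid: GridSpec) -> float:
    mid_lat = math.radians(grid.lat_origin + 0.5 * grid.n_rows * grid.cell_size)
    return grid.cell_size * 0.5 * (KM_PER_DEG_LAT + KM_PER_DEG_LON_EQ * math.cos(mid_lat)) * 1000.0


def generate_landscape(
    seed: int,
    grid: GridSpec | None = None,
    params: LandscapeParams | None = None,
) -> CovariateStack:
    """Generate the synthetic covariate stack; deterministic in (seed, params).

    Elevation is a smoothed Gaussian random field on a west-to-east regional
    ramp (the west edge is the coast); temperature follows latitude minus a
    lapse-rate term; precipitation follows longitude; recharge is a fixed
    fraction of precipitation minus a temperature-driven PET; DWT solves the
    groundwater equilibrium with the coast and the lowest-lying interior
    cells (rivers) as fixed-head drainage; percent wetland is a logistic
    transform of DWT around the 1 m wetland threshold plus noise, negatively
    correlated with DWT by construction.
    """
    grid = grid or default_grid()
    params = params or LandscapeParams()
    if grid.n_rows < 4 or grid.n_cols < 4:
        raise ValueError("synthetic landscape needs a grid of at least 4 x 4 cells")
    rng = np.random.default_rng(seed)

    n_rows, n_cols = grid.shape
    lat = np.broadcast_to(grid.row_centers()[:, None], grid.shape)
    col_frac = np.broadcast_to(
        (np.arange(n_cols) / max(n_cols - 1, 1))[None, :], grid.shape
    )

    noise = rng.standard_normal(grid.shape)
    rough = gaussian_filter(noise, sigma=params.smooth_sigma, mode="reflect")
    rough = rough / max(rough.std(), 1e-12) * params.relief_sd
    elevation = params.regional_slope * col_frac + rough
    elevation = elevation - elevation.min() + 1.0  # keep the coast just above sea level

    temperature = (
        params.temp_at_south
        - params.temp_lat_gradient * (lat - grid.lat_origin)
        - params.lapse_rate * elevation / 1000.0
        + rng.normal(0.0, params.temp_noise_sd, grid.shape)
    )
    precipitation = (
        params.precip_west
        + (params.precip_east - params.precip_west) * col_frac
        + gaussian_filter(rng.standard_normal(grid.shape), sigma=3.0, mode="reflect")
        * params.precip_noise_sd
        * 3.0
    )
    precipitation = np.clip(precipitation, 50.0, None)

    pet = params.pet_base + params.pet_per_degree * np.clip(temperature, 0.0, None)
    recharge = params.runoff_fraction * (precipitation - pet) / 1000.0  # m/yr

    fixed = np.zeros(grid.shape, dtype=bool)
    fixed[:, 0] = True  # west-edge coast
    fixed_dwt = np.zeros(grid.shape)
    interior_elev = elevation.copy()
    interior_elev[:, 0] = np.inf
    n_rivers = int(round(params.river_fraction * grid.n_rows * grid.n_cols))
    if n_rivers > 0:
        river_idx = np.argsort(interior_elev, axis=None)[:n_rivers]
        rr, rc = np.unravel_index(river_idx, grid.shape)
        fixed[rr, rc] = True
        fixed_dwt[rr, rc] = params.river_dwt

    landscape = Landscape(
        elevation=elevation,
        recharge=recharge,
        T0=params.T0,
        T_min=params.T0 * params.T_min_ratio,
        f=params.f_depth,
        cell_length=_cell_length_m(grid),
        fixed_head_mask=fixed,
        fixed_dwt=fixed_dwt,
    )
    state = solve_equilibrium(landscape)
    dwt = state.dwt

    wetland_signal = 1.0 / (1.0 + np.exp(params.wetland_steepness * (dwt - 1.0)))
    percent_wetland = np.clip(
        wetland_signal + rng.normal(0.0, params.wetland_noise_sd, grid.shape), 0.0, 1.0
    )

    layers = {
        "temperature": temperature,
        "precipitation": precipitation,
        "elevation": elevation,
        "dwt": dwt,
        "percent_wetland": percent_wetland,
    }
    return CovariateStack(grid=grid, layers=layers, landscape=landscape, params=params, seed=seed)


# ---------------------------------------------------------------------------
# species niches and survey effort


@dataclass(frozen=True)
class SpeciesNiche:
    """Ground-truth habitat preference and movement phenology of one species."""

    species: str
    dwt_scale: float                     # delta, m; suitability ~ exp(-dwt/delta)
    temp_opt: float                      # deg C
    temp_sd: float
    seasonal_center: dict                # season -> preferred latitude, deg
    range_sd: float                      # deg latitude
    spring_weeks: tuple[int, int] = (12, 16)   # inclusive week indices
    fall_weeks: tuple[int, int] = (38, 42)
    base_velocity: float = 3.0           # km/day outside migration
    migration_velocity: float = 16.0     # km/day during migration

    def __post_init__(self) -> None:
        if self.dwt_scale <= 0 or self.temp_sd <= 0 or self.range_sd <= 0:
            raise ValueError("dwt_scale, temp_sd and range_sd must be positive")
        if self.migration_velocity <= self.base_velocity:
            raise ValueError("migration velocity must exceed base velocity")

    def migration_week(self, week: int) -> str | None:
        if self.spring_weeks[0] <= week <= self.spring_weeks[1]:
            return "spring"
        if self.fall_weeks[0] <= week <= self.fall_weeks[1]:
            return "fall"
        return None

    def true_windows(self) -> SeasonWindows:
        """Season windows implied by the true migration weeks."""
        return SeasonWindows(
            species=self.species,
            spring=(self.spring_weeks[0] * 7 + 1, (self.spring_weeks[1] + 1) * 7 + 1),
            fall=(self.fall_weeks[0] * 7 + 1, (self.fall_weeks[1] + 1) * 7 + 1),
            source="detected",
        )


def default_niches() -> list[SpeciesNiche]:
    """Four co-sampled waterfowl-like species spanning weak to strong wetland affinity."""
    centers = lambda winter, summer: {
        "winter": winter,
        "summer": summer,
        "spring": (winter + summer) / 2.0,
        "fall": (winter + summer) / 2.0,
    }
    return [
        SpeciesNiche("SPEC", 0.3, 16.0, 4.0, centers(30.0, 36.0), 2.5),
        SpeciesNiche("AFFN", 0.5, 17.0, 4.0, centers(30.5, 36.5), 2.5),
        SpeciesNiche("INTR", 1.0, 18.0, 4.5, centers(31.0, 36.0), 3.0),
        SpeciesNiche("GENL", 3.0, 17.5, 5.0, centers(31.5, 35.5), 3.5),
    ]


@dataclass
class SurveyEffort:
    """Where and how intensely banding happens (shared across species)."""

    station_cells: list
    station_sd: float = 0.7      # degrees; kernel width of banding around stations
    n_banding: int = 200         # bandings per species per season

    def __post_init__(self) -> None:
        if not self.station_cells:
            raise ValueError("need at least one survey station")
        if self.n_banding < 0:
            raise ValueError("n_banding must be non-negative")


def default_effort(stack: CovariateStack, seed: int, n_stations: int = 12) -> SurveyEffort:
    """Place stations preferentially in habitat used by any of the default species."""
    rng = np.random.default_rng(seed)
    niches = default_niches()
    total = np.zeros(stack.grid.shape)
    for niche in niches:
        total += suitability(niche, stack, "winter") + suitability(niche, stack, "summer")
    flat = total.ravel()
    flat = np.where(np.isfinite(flat), flat, 0.0)
    p = flat / flat.sum()
    idx = rng.choice(flat.size, size=n_stations, replace=False, p=p)
    cells = [CellIndex(int(r), int(c)) for r, c in zip(*np.unravel_index(idx, stack.grid.shape))]
    return SurveyEffort(station_cells=cells)


# ---------------------------------------------------------------------------
# presences and records


def suitability(niche: SpeciesNiche, stack: CovariateStack, season: str) -> np.ndarray:
    """Ground-truth suitability surface of a species in a season."""
    dwt = stack.layers["dwt"]
    temp = stack.layers["temperature"]
    lat = stack.lat
    center = niche.seasonal_center[season]
    s = (
        np.exp(-dwt / niche.dwt_scale)
        * np.exp(-((temp - niche.temp_opt) ** 2) / (2.0 * niche.temp_sd**2))
        * np.exp(-((lat - center) ** 2) / (2.0 * niche.range_sd**2))
    )
    return np.where(np.isfinite(s), s, 0.0)


@dataclass
class PresenceSample:
    """Sampled presence cells plus the truth surface they were drawn from."""

    cells: list
    suitability: np.ndarray


def simulate_presences(
    niche: SpeciesNiche,
    stack: CovariateStack,
    season: str,
    n: int,
    seed: int,
) -> PresenceSample:
    """Draw presence cells with probability proportional to true suitability."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s = suitability(niche, stack, season)
    total = s.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; niche incompatible with landscape")
    rng = np.random.default_rng(seed)
    p = (s / total).ravel()
    idx = rng.choice(p.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(idx, stack.grid.shape)
    cells = [CellIndex(int(r), int(c)) for r, c in zip(rows, cols)]
    return PresenceSample(cells=cells, suitability=s)


def _station_kernel(stack: CovariateStack, effort: SurveyEffort) -> np.ndarray:
    lat, lon = stack.lat, stack.lon
    kernel = np.zeros(stack.grid.shape)
    for cell in effort.station_cells:
        clat = stack.grid.lat_origin + (cell.row + 0.5) * stack.grid.cell_size
        clon = stack.grid.lon_origin + (cell.col + 0.5) * stack.grid.cell_size
        d2 = (lat - clat) ** 2 + (lon - clon) ** 2
        kernel += np.exp(-d2 / (2.0 * effort.station_sd**2))
    return kernel


def simulate_banding_records(
    niches: list[SpeciesNiche],
    effort: SurveyEffort,
    stack: CovariateStack,
    seed: int,
    years: tuple[int, int] = (1990, 1999),
) -> list[EncounterRecord]:
    """Generate banding events plus one terminal recovery per banded bird.

    Bandings are drawn from each species' suitability re-weighted by a
    Gaussian kernel around survey stations (effort bias).  Each bird is
    recovered after a geometric number of days (mean 20, truncated at 60),
    displaced by ``elapsed * velocity`` along the seasonal movement
    direction — northward in spring migration weeks, southward in fall,
    and in a random direction otherwise, at the slow base velocity.
    """
    if len(niches) < 2:
        raise ValueError("need at least two species (target-group background requires them)")
    rng = np.random.default_rng(seed)
    kernel = _station_kernel(stack, effort)
    grid = stack.grid
    records: list[EncounterRecord] = []
    counter = 0
    margin = grid.cell_size / 2.0

    for niche in niches:
        for season in ("winter", "spring", "summer", "fall"):
            s = suitability(niche, stack, season) * kernel
            total = s.sum()
            if total <= 0:
                continue
            p = (s / total).ravel()
            n = effort.n_banding
            if n == 0:
                continue
            idx = rng.choice(p.size, size=n, replace=True, p=p)
            rows, cols = np.unravel_index(idx, grid.shape)
            window = niche.true_windows().interval(season)
            for r, c in zip(rows, cols):
                counter += 1
                band_id = f"{niche.species}{counter:06d}"
                year = int(rng.integers(years[0], years[1] + 1))
                span = (window[1] - window[0]) % 365 or 365
                doy = (window[0] - 1 + int(rng.integers(0, span))) % 365 + 1
                date = _dt.date(year, 1, 1) + _dt.timedelta(days=doy - 1)
                blat = grid.lat_origin + (r + 0.5) * grid.cell_size
                blon = grid.lon_origin + (c + 0.5) * grid.cell_size
                banding = EncounterRecord(
                    band_id=band_id, species=niche.species, event="banding",
                    date=date, lat=blat, lon=blon,
                ).with_cell(grid)
                records.append(banding)

                elapsed = min(int(rng.geometric(1.0 / 20.0)), 60)
                mid_doy = min((date + _dt.timedelta(days=elapsed // 2)).timetuple().tm_yday, 365)
                phase = niche.migration_week(week_of_doy(mid_doy))
                if phase == "spring":
                    bearing = (1.0, 0.0)  # northward
                    speed = niche.migration_velocity
                elif phase == "fall":
                    bearing = (-1.0, 0.0)
                    speed = niche.migration_velocity
                else:
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    bearing = (math.sin(theta), math.cos(theta))
                    speed = niche.base_velocity
                dist_km = elapsed * speed
                rlat = blat + dist_km * bearing[0] / KM_PER_DEG_LAT
                rlon = blon + dist_km * bearing[1] / (
                    KM_PER_DEG_LON_EQ * math.cos(math.radians(blat))
                )
                rlat = float(np.clip(rlat, grid.lat_origin + margin, grid.lat_max - margin))
                rlon = float(np.clip(rlon, grid.lon_origin + margin, grid.lon_max - margin))
                recovery = EncounterRecord(
                    band_id=band_id, species=niche.species, event="recovery",
                    date=date + _dt.timedelta(days=elapsed), lat=rlat, lon=rlon,
                ).with_cell(grid)
                records.append(recovery)
    return records
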