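# Methods

This note documents the models implemented in `hydrofowl`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Analysis grid and record model

All spatial data live on a regular latitude/longitude grid of half-open
cells, by default 10 minutes (1/6°) on a side — the locational precision of
banding archives.  Row 0 is the southern edge; a point exactly on an
interior edge belongs to the higher-index cell.  Distances are haversine
great circles on a sphere of IUGG mean radius 6371.0088 km, always between
cell centers, since record positions are only known to the cell.  Dates are
ISO-8601 externally and proleptic-Gregorian ordinal days internally, so day
arithmetic is exact; day-of-year folds Dec 31 of leap years onto day 365,
giving a 365-day circular calendar.

Every banding or recovery event is a presence of its species.  Recoveries
without a matching banding record remain presences but are excluded from
velocity pairing.

## Season delineation

Migration shows up as a burst of daily travel among birds recovered within
30 days of banding (longer gaps confound within-season wandering with
migration; same-day recoveries have undefined velocity and are dropped).
Each pair contributes distance/elapsed-days, assigned to the calendar week
of the pair's midpoint date (52 weeks; week 51 absorbs days 358–365).

Peak detection is deliberately simple and deterministic: missing weeks are
filled by circular linear interpolation, the series is smoothed with a
3-week circular moving average, and candidate migration periods are maximal
runs of weeks above mean + 0.5 sd of the smoothed series.  The threshold is
scale-free (a species' absolute travel rates cancel out), and 0.5 sd keeps
runs contiguous for bump-shaped peaks without admitting baseline noise.
The strongest run with midpoint in the first calendar half becomes spring,
in the second half fall (Northern-Hemisphere phenology); a half with no
qualifying run falls back to the supplied natural-history prior and the
`source` field records the mixture (`detected` / `adjusted` / `prior`).
Fewer than 26 informative weeks triggers a full fallback to the prior.
Winter and summer fill the circular complement; season intervals are
inclusive of their start and exclusive of their end.

## Equilibrium depth to water table

The water table sits where net recharge balances lateral drainage.  Each
cell carries a head `h = z − d` (elevation minus depth); flow between
4-neighbours is Darcian with transmissivity decaying with water-table
depth,

    T(d) = T0 · exp(−d/f) + T_min ,

evaluated at the mean depth of the two cells.  `f` (metres) is the
e-folding depth of the conductive regolith; `T_min` is a residual deep
(basement) transmissivity — without it, steep terrain can have no finite
equilibrium, because a cell whose drawdown outruns the exponential decay
disconnects itself from the drainage network.  The negative part of
recharge is treated as an evapotranspiration demand drawn from the water
table and decays as `exp(−d/f_et)` (default `f_et = f`): ET cannot extract
groundwater the roots cannot reach.  River and ocean cells hold a
prescribed fixed head.  Where the balance would push water above the land
surface, the depth is clipped to zero and the excess is shed (ponded
wetlands); a landscape with no fixed-head cell is treated as a closed basin
anchored at its lowest cell.

The solver is a damped, step-capped Newton iteration on the head system
with active-set handling of ponded cells (a ponded cell shedding a
non-negative excess is clamped to the surface and leaves the system for
that iteration), a backtracking line search on the complementarity
residual, and under-relaxation `ω = 0.5`.  Steps are capped at two
transmissivity e-folds so the linearization never runs far ahead of the
conductances.  Iteration stops when no depth moves more than `tol` (1 mm
by default) and the raw Newton correction is below `tol` with a stable
active set.  The scheme is deterministic and typically converges in 20–60
iterations on the default 60×100 landscape (< 1 s).

`mass_balance_residual` checks closure: recharge over drained cells minus
boundary outflow minus the lateral excess shed at ponded cells, relative to
total absolute recharge; converged cases close to well under 1%.  The
wetland mask thresholds depth at ≤ 1.0 m.

**Not modelled:** transient dynamics, pumping/management, surface routing of
ponded water, process-level evapotranspiration, and continental-scale
validation against observation wells — the solver reproduces the *balance
structure* of large-scale water-table simulations, not any particular
dataset.

## Synthetic study system

`generate_landscape` builds a humid, gently rolling coastal plain on the
default 60×100 ten-minute grid (~10° × 16.7°): elevation is a smoothed
Gaussian random field (sd 30 m, correlation length 5 cells) on a 150 m
west-to-east ramp with the coast along the west edge; temperature follows
latitude (−0.8 °C/°) minus a 6.5 °C/km lapse; precipitation declines from
1150 to 760 mm/yr eastward; recharge is 15% of precipitation minus a
temperature-driven PET.  The lowest 3% of interior cells are rivers with
fixed 0.2 m depth.  With `T0 = 2·10⁸ m²/yr`, `f = 2.5 m`,
`T_min = 10⁻³·T0`, the equilibrium DWT has median ≈ 5 m, ≈ 15–20% of cells
wetter than 1 m, and wet valleys against drier interfluves.  Percent
wetland is a logistic transform of DWT about the 1 m threshold (slope
0.4 m⁻¹) plus N(0, 0.45) noise, clipped to [0,1]; the noise level is set so
the DWT/percent-wetland correlation lands near −0.35 — percent wetland is
deliberately a *noisy* proxy of the same quantity, which is what makes the
two wetland covariates distinguishable in the models.

Four co-sampled species span the affinity range: δ = 0.3 (`SPEC`), 0.5
(`AFFN`), 1.0 (`INTR`), 3.0 m (`GENL`), with species-specific temperature
optima and seasonal latitude centers (southern in winter, northern in
summer).  All species share true migration weeks 12–16 (spring) and 38–42
(fall).  Banding effort is concentrated around 12 survey stations
(Gaussian kernel, sd 0.7°, 200 bandings per species-season); every banded
bird receives one terminal recovery after a geometric number of days (mean
20, truncated at 60), displaced at 16 km/day along the seasonal direction
inside migration weeks and 3 km/day in a random direction otherwise.
These velocities give a ~5× contrast, comfortably recoverable through the
~18.5 km cell quantization.

**What passing tests show, and what they do not.**  The generator encodes
wetland affinity, migration timing, and effort bias as recoverable truth;
tests demonstrate that the estimators recover *exactly these structures* —
they say nothing about detection probability, hunter-reporting biases,
multi-encounter band histories, inter-annual population trends, or any
real archive's idiosyncrasies, none of which are simulated.

## Background, model fitting, evaluation

Target-group background for a focal species-season is the union of other
species' presence cells (each under its *own* season windows) minus the
focal presences; absence is evaluated at the cell level per season.  The
default background draw is min(10,000, candidates), resampled per
replicate.

Maxent features follow the standard auto-selection by presence count
(linear; +quadratic ≥ 10; +hinge ≥ 15, ten evenly spaced knots per
covariate in both orientations; +product ≥ 80), each scaled to [0,1] over
the fitting cells with out-of-range prediction values clamped.  Penalties
are `β_j = rate(class, m)·sd(f_j)/√m` with the conventional class rate
tables interpolated by sample size.  Presence cells are appended to the
background for normalization (samples-with-data).  Optimization is
monotone ISTA with backtracking and mild step re-growth; convergence is an
objective improvement below 1e-5.  The replicate protocol derives all run
seeds from one master seed so that two covariate sets evaluated with the
same seed see identical splits and backgrounds — the paired t-test on
per-replicate AUC differences then isolates the covariate effect.  The
AUC-difference test is a paired two-sided t-test at α = 0.05 with a
flagged zero-variance path.

Variable importance grows bagged `sklearn` decision trees (`max_features
= sqrt`, fully grown) on bootstrap samples; per tree, OOB accuracy minus
OOB accuracy after permuting one covariate among that tree's OOB rows;
importance is the mean over trees divided by its standard error.  Note
this z-style normalization grows as √n_trees for any fixed bias, so
magnitudes are comparable only at a fixed ensemble size.

Response curves sample 1000 valid surface cells without replacement, bin
DWT into 20 equal-width bins, and fit a cubic smoothing spline to the bin
means with smoothing chosen by generalized cross-validation (bin means
rather than a running mean of the raw points: with skewed DWT
distributions, bins equalize leverage along the depth axis).  The
half-maximum depth (where the spline first falls to half its peak)
summarizes affinity strength; for suitability `e^(−d/δ)` its target value
is `δ·ln 2`.

## Problem sizes

Tests and the acceptance script run the full study at desk scale: the
60×100-cell landscape, four species, 200 bandings per species-season
(~630 within-30-day pairs per species), 100 paired maxent replicates with
1000-cell backgrounds, and 300–500-tree forests.  These sizes give stable
detection (season midpoints recovered exactly across seeds) and decisive
paired comparisons (p ≪ 10⁻¹⁰) while keeping any single check under a
minute.

## Known limitations

* The water-table solver is a structural stand-in: one-layer, steady-state,
  4-neighbour, with a single global `T0`/`f`; it is validated against
  closed forms and internal balance, not field data.
* Season detection reports the threshold-crossing window; the manual,
  judgment-based adjustment of dates against natural histories is out of
  scope (both the detected window and its provenance are recorded instead).
* Maxent omits cumulative output, categorical features, jackknife
  contributions, and projection diagnostics (MESS/clamping maps).
* The paired AUC protocol evaluates against sampled background, not true
  absences; AUC levels are therefore relative measures, meaningful in
  comparison, not as absolute discrimination against the species' true
  distribution.
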