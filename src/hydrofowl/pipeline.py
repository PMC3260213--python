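"""Configuration, orchestration and reproducible end-to-end runs.

A run is described by one YAML config with a mandatory master seed; every
stage derives its own sub-seed deterministically from it, so re-running
the same config reproduces every numeric output byte for byte.  The
stages: simulate (landscape + records) -> delineate (season windows) ->
background (presences + target-group candidates) -> fit (replicated
maxent, base vs base+DWT) -> evaluate (AUC comparison, forest importance,
response curve).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .background import OccurrenceSet, presence_cells, sample_background, target_group_background
from .evaluate import compare_models, fit_bagged_trees, importance_table, response_curve
from .grid import GridSpec
from .maxent import fit_maxent, predict_surface, replicate_fit
from .rasters import write_ascii_grid
from .seasons import SeasonWindows, delineate_from_records
from .synthetic import (
    BASE_COVARIATES,
    COVARIATE_NAMES,
    SpeciesNiche,
    SurveyEffort,
    default_effort,
    default_niches,
    generate_landscape,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    seed: int
    grid: dict = field(default_factory=lambda: synthetic.default_grid().to_dict())
    effort: dict = field(
        default_factory=lambda: {"n_stations": 12, "station_sd": 0.7, "n_banding": 200}
    )
    season_source: str = "detect"          # detect | file
    season_file: str | None = None
    focal: str = "AFFN"
    season: str = "winter"
    n_runs: int = 100
    train_frac: float = 0.7
    n_background: int = 10_000
    classes: str = "auto"
    beta_multiplier: float = 1.0
    n_trees: int = 1000
    response_points: int = 1000
    response_bins: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a master seed")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError(f"{path}: config must set a master seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def grid_spec(self) -> GridSpec:
        return GridSpec.from_dict(self.grid)

    def stage_seeds(self) -> dict:
        """Named per-stage sub-seeds, a pure function of the master seed."""
        rng = np.random.default_rng(self.seed)
        names = ("landscape", "effort", "records", "fit", "importance", "response")
        vals = rng.integers(0, 2**31 - 1, size=len(names))
        return {n: int(v) for n, v in zip(names, vals)}


# ---------------------------------------------------------------------------
# raster resampling


def resample_to_grid(
    src: np.ndarray, src_grid: GridSpec, dst_grid: GridSpec, method: str = "mean"
) -> np.ndarray:
    """Aggregate a finer raster onto the analysis grid.

    ``mean``: average of source cell centers falling in each target cell
    (continuous layers).  ``fraction``: fraction of source cells that are
    truthy — the percent-wetland derivation from a fine land-cover mask.
    ``nearest``: source value at each target cell center.  NaN-aware.
    """
    src = np.asarray(src, dtype=float)
    if src.shape != src_grid.shape:
        raise ValueError("source raster shape does not match its grid")
    if (
        src_grid.lat_max <= dst_grid.lat_origin
        or dst_grid.lat_max <= src_grid.lat_origin
        or src_grid.lon_max <= dst_grid.lon_origin
        or dst_grid.lon_max <= src_grid.lon_origin
    ):
        raise ValueError("source raster does not overlap the target grid")

    if method == "nearest":
        out = np.full(dst_grid.shape, np.nan)
        lats = dst_grid.row_centers()
        lons = dst_grid.col_centers()
        rows = np.floor((lats - src_grid.lat_origin) / src_grid.cell_size).astype(int)
        cols = np.floor((lons - src_grid.lon_origin) / src_grid.cell_size).astype(int)
        rok = (rows >= 0) & (rows < src_grid.n_rows)
        cok = (cols >= 0) & (cols < src_grid.n_cols)
        out[np.ix_(rok, cok)] = src[np.ix_(rows[rok], cols[cok])]
        return out

    if method not in ("mean", "fraction"):
        raise ValueError(f"unknown resampling method {method!r}")
    src_lat = src_grid.row_centers()
    src_lon = src_grid.col_centers()
    r_dst = np.floor((src_lat - dst_grid.lat_origin) / dst_grid.cell_size).astype(int)
    c_dst = np.floor((src_lon - dst_grid.lon_origin) / dst_grid.cell_size).astype(int)
    rok = (r_dst >= 0) & (r_dst < dst_grid.n_rows)
    cok = (c_dst >= 0) & (c_dst < dst_grid.n_cols)
    vals = src[np.ix_(rok, cok)]
    rr = np.broadcast_to(r_dst[rok][:, None], vals.shape).ravel()
    cc = np.broadcast_to(c_dst[cok][None, :], vals.shape).ravel()
    v = vals.ravel()
    ok = np.isfinite(v)
    if method == "fraction":
        v = (v != 0).astype(float)
    flat = rr[ok] * dst_grid.n_cols + cc[ok]
    sums = np.bincount(flat, weights=v[ok], minlength=dst_grid.n_rows * dst_grid.n_cols)
    counts = np.bincount(flat, minlength=dst_grid.n_rows * dst_grid.n_cols)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    return out.reshape(dst_grid.shape)


# ---------------------------------------------------------------------------
# the end-to-end run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    grid = config.grid_spec()
    manifest: dict = {
        "config_hash": config.config_hash,
        "seeds": seeds,
        "stages": {},
    }
    (outdir / "config.yaml").write_text(config.to_yaml())

    def record_stage(name: str, files: list[Path]) -> None:
        manifest["stages"][name] = {
            "status": "ok",
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # --- simulate -----------------------------------------------------------
    try:
        stack = generate_landscape(seeds["landscape"], grid=grid)
        niches = default_niches()
        effort = default_effort(
            stack, seeds["effort"], n_stations=config.effort.get("n_stations", 12)
        )
        effort.station_sd = float(config.effort.get("station_sd", 0.7))
        effort.n_banding = int(config.effort.get("n_banding", 200))
        records = synthetic.simulate_banding_records(niches, effort, stack, seeds["records"])
        files = []
        for name, layer in stack.layers.items():
            p = outdir / f"{name}.asc"
            write_ascii_grid(p, layer, grid)
            files.append(p)
        from .banding import write_records

        rec_path = outdir / "records.csv"
        write_records(records, rec_path)
        files.append(rec_path)
        truth = {
            "species": [
                {
                    "species": n.species,
                    "dwt_scale": n.dwt_scale,
                    "spring_weeks": list(n.spring_weeks),
                    "fall_weeks": list(n.fall_weeks),
                }
                for n in niches
            ]
        }
        truth_path = outdir / "truth.yaml"
        truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
        files.append(truth_path)
        record_stage("simulate", files)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- delineate ----------------------------------------------------------
    try:
        windows_by_species: dict[str, SeasonWindows] = {}
        rows = []
        for niche in niches:
            sp_records = [r for r in records if r.species == niche.species]
            prior = niche.true_windows()
            if config.season_source == "file":
                with open(config.season_file) as fh:
                    data = yaml.safe_load(fh)
                win = SeasonWindows.from_dict(
                    next(d for d in data if d["species"] == niche.species)
                )
                series = None
            else:
                win, series = delineate_from_records(sp_records, grid, prior)
            windows_by_species[niche.species] = win
            rows.append(win.to_dict())
        win_path = outdir / "season_windows.yaml"
        win_path.write_text(yaml.safe_dump(rows, sort_keys=True))
        record_stage("delineate", [win_path])
    except Exception as exc:
        raise PipelineError("delineate", str(exc)) from exc

    # --- background ---------------------------------------------------------
    try:
        pres = presence_cells(
            records, config.focal, config.season, windows_by_species[config.focal]
        )
        candidates = target_group_background(
            records, config.focal, config.season, windows_by_species
        )
        occ = OccurrenceSet(
            species=config.focal,
            season=config.season,
            presence_cells=pres,
            background_cells=candidates,
        )
        rows = [
            {"role": "presence", "row": c.row, "col": c.col} for c in sorted(pres)
        ] + [
            {"role": "background", "row": c.row, "col": c.col}
            for c in sorted(candidates)
        ]
        bg_path = outdir / "occurrences.csv"
        _write_df(pd.DataFrame(rows), bg_path)
        record_stage("background", [bg_path])
    except Exception as exc:
        raise PipelineError("background", str(exc)) from exc

    # --- fit ----------------------------------------------------------------
    try:
        values_at = lambda cells, names: stack.covariate_matrix(list(cells), names)
        cov_sets = {
            "base": tuple(BASE_COVARIATES),
            "base_dwt": tuple(BASE_COVARIATES) + ("dwt",),
        }
        auc_frames = []
        for label, names in cov_sets.items():
            reps = replicate_fit(
                sorted(pres),
                candidates,
                lambda cells, names=names: values_at(cells, names),
                names,
                n_runs=config.n_runs,
                train_frac=config.train_frac,
                n_background=config.n_background,
                classes=config.classes,
                beta_multiplier=config.beta_multiplier,
                seed=seeds["fit"],
            )
            auc_frames.append(
                pd.DataFrame(
                    {"model": label, "run": [r.run for r in reps], "auc": [r.auc for r in reps]}
                )
            )
        auc_df = pd.concat(auc_frames, ignore_index=True)
        auc_path = outdir / "auc_replicates.csv"
        _write_df(auc_df, auc_path)

        # full-data model for the map and the response curve
        full_names = cov_sets["base_dwt"]
        bg_full = sorted(
            sample_background(candidates, min(config.n_background, len(candidates)), seeds["fit"])
        )
        X_pres = values_at(sorted(pres), full_names)
        X_bg = values_at(bg_full, full_names)
        model = fit_maxent(
            X_pres,
            np.vstack([X_bg, X_pres]),
            full_names,
            classes=config.classes,
            beta_multiplier=config.beta_multiplier,
        )
        surface = predict_surface(model, stack.layers)
        surf_path = outdir / "prediction_surface.asc"
        write_ascii_grid(surf_path, surface, grid)
        record_stage("fit", [auc_path, surf_path])
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    # --- evaluate -----------------------------------------------------------
    try:
        a = auc_df[auc_df.model == "base_dwt"].auc.to_numpy()
        b = auc_df[auc_df.model == "base"].auc.to_numpy()
        k = min(len(a), len(b))
        comparison = compare_models(a[:k], b[:k])
        comp_path = outdir / "model_comparison.json"
        comp_path.write_text(
            json.dumps(
                {
                    "better": comparison.better,
                    "mean_diff": comparison.mean_diff,
                    "p_value": comparison.p_value,
                    "mean_auc_base_dwt": float(a.mean()),
                    "mean_auc_base": float(b.mean()),
                },
                indent=2,
                sort_keys=True,
            )
        )

        bg_imp = sorted(
            sample_background(candidates, min(len(candidates), config.n_background), seeds["importance"])
        )
        X = np.vstack(
            [values_at(sorted(pres), COVARIATE_NAMES), values_at(bg_imp, COVARIATE_NAMES)]
        )
        y = np.concatenate([np.ones(len(pres), dtype=int), np.zeros(len(bg_imp), dtype=int)])
        forest = fit_bagged_trees(
            X, y, COVARIATE_NAMES, n_trees=config.n_trees, seed=seeds["importance"]
        )
        imp = importance_table(forest, X, y, seed=seeds["importance"])
        imp.insert(0, "season", config.season)
        imp.insert(0, "species", config.focal)
        imp_path = outdir / "importance.csv"
        _write_df(imp, imp_path)

        curve = response_curve(
            surface,
            stack.layers["dwt"],
            n=config.response_points,
            n_bins=config.response_bins,
            seed=seeds["response"],
        )
        curve_df = pd.DataFrame(
            {"bin_center": curve.bin_centers, "bin_mean": curve.bin_means}
        )
        spline_df = pd.DataFrame({"dwt": curve.spline_x, "spline": curve.spline_y})
        curve_path = outdir / "response_bins.csv"
        spline_path = outdir / "response_spline.csv"
        _write_df(curve_df, curve_path)
        _write_df(spline_df, spline_path)
        record_stage("evaluate", [comp_path, imp_path, curve_path, spline_path])
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
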