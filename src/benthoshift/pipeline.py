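"""End-to-end orchestration: synthetic inputs -> bottom projection ->
climatologies -> collinearity screening -> current stack -> SDM ensemble ->
future forcing (bias correction, GCM averaging, downscaling) -> monthly
suitability -> spatiotemporal attribute tables.

The run is a pure function of (config, seed): stage seeds are derived from
the run seed by hashing stable stage tags, every output file is written
with fixed float formatting, and the provenance record carries the config
hash and seed, so identical runs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy import ndimage

from . import __version__
from .attributes import build_attribute_table, seasonality_table
from .forcing import apply_downscaler, delta_bias_correct, ensemble_mean, fit_downscalers
from .grids import DomainGrid, default_depth_levels
from .io import save_csv, save_netcdf
from .preprocess import (
    annual_mean_stack,
    assemble_stack,
    collinearity_filter,
    monthly_climatology,
)
from .projection import project_to_bottom
from .scenarios import CURRENT, ScenarioSpec, all_scenarios
from .sdm import (
    binarize,
    features_at_points,
    fit_sdm,
    generate_pseudoabsences,
    predict_suitability,
    variable_importance,
)
from .synth import (
    FutureFieldSpec,
    SeasonalCycle,
    TrueHabitatModel,
    block_aggregate,
    generate_bathymetry,
    generate_env_cube,
    generate_future_fields,
    sample_occurrences,
)

DECADE_WEIGHT = {"2030": 0.5, "2050": 1.0}


@dataclass
class VariableConfig:
    """One synthetic environmental variable.

    kind: "cube" (lon, lat, depth, month; bottom-projected), "surface"
    (lon, lat, month) or "derived" (a linear function of another surface
    layer, used to exercise the collinearity screen).

    The vertical profile is ``base + depth_slope * z`` when
    ``profile_scale`` is 0, otherwise an exponential approach to a deep
    value, ``deep_value + (base - deep_value) * exp(-z / profile_scale)``
    — the thermocline/halocline shape that keeps bottom-projected values
    from being a linear alias of bathymetry. ``delta`` is the additive
    climate signal reached at SSP 8.5 in 2050, scaled down linearly for
    milder pathways and the nearer decade; ``bias`` is the synthetic GCM's
    known additive bias.
    """

    name: str
    kind: str = "cube"
    base: float = 0.0
    depth_slope: float = 0.0
    deep_value: float = 0.0
    profile_scale: float = 0.0
    season_kind: str = "flat"
    season_peaks: tuple[int, ...] = ()
    season_amplitude: float = 0.0
    gradient_amplitude: float = 0.0
    noise_sd: float = 0.0
    delta: float = 0.0
    bias: float = 0.0
    units: str = ""
    source: str = ""  # for derived layers
    scale: float = 1.0  # for derived layers
    source2: str = ""  # optional second driver of a derived layer
    mix: float = 0.0  # weight of source2, in units of sd(source)

    def season(self) -> SeasonalCycle:
        return SeasonalCycle(
            kind=self.season_kind,
            peaks=tuple(self.season_peaks),
            amplitude=self.season_amplitude,
        )

    def profile(self, z):
        z = np.asarray(z, dtype=float)
        if self.profile_scale > 0:
            return self.deep_value + (self.base - self.deep_value) * np.exp(
                -z / self.profile_scale
            )
        return self.base + self.depth_slope * z


@dataclass
class SpeciesConfig:
    """A species' known habitat model and occurrence sample size."""

    name: str
    n_occurrences: int
    coefficients: dict[str, float]
    intercept: float
    threshold: float = 0.5

    def truth(self) -> TrueHabitatModel:
        return TrueHabitatModel(
            coefficients=dict(self.coefficients),
            intercept=self.intercept,
            threshold=self.threshold,
        )


@dataclass
class RunConfig:
    """Every tunable of the pipeline, YAML round-trippable."""

    # grid
    lon_min: float = -80.0
    lon_max: float = -76.0
    lat_min: float = 1.46
    lat_max: float = 7.21
    resolution: float = 0.08
    n_depth_levels: int = 24
    max_depth: float = 1200.0
    # synthetic inputs
    n_years: int = 2
    bathymetry_noise_sd: float = 25.0
    land_cells: int = 3
    variables: list[VariableConfig] = field(default_factory=list)
    species: list[SpeciesConfig] = field(default_factory=list)
    # scenarios
    decades: tuple[str, ...] = ("2030", "2050")
    ssps: tuple[float, ...] = (2.6, 4.5, 7.0, 8.5)
    n_gcms: int = 2
    coarse_factor: int = 10
    gcm_noise_sd: float = 0.0
    # stage parameters
    collinearity_threshold: float = 0.70
    binarize_threshold: float = 0.75
    change_band: float = 0.10
    seasonality_alpha: float = 0.05
    downscale_methods: tuple[str, ...] = ("rr", "mars", "rf")
    n_pseudoabsence_sets: int = 3
    sdm_n_estimators: int = 1000
    sdm_max_features: int = 8
    sdm_min_samples_leaf: int = 5
    sdm_n_repeats: int = 10
    sdm_test_size: float = 0.25
    eval_threshold: float = 0.5
    seed: int = 0

    def grid(self) -> DomainGrid:
        return DomainGrid(
            lon_min=self.lon_min,
            lon_max=self.lon_max,
            lat_min=self.lat_min,
            lat_max=self.lat_max,
            resolution=self.resolution,
            depth_levels=default_depth_levels(self.n_depth_levels, self.max_depth),
        )

    def scenarios(self) -> list[ScenarioSpec]:
        return all_scenarios(tuple(self.decades), tuple(self.ssps))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decades"] = list(d["decades"])
        d["ssps"] = list(d["ssps"])
        d["downscale_methods"] = list(d["downscale_methods"])
        for v in d["variables"]:
            v["season_peaks"] = list(v["season_peaks"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["variables"] = [
            VariableConfig(**{**v, "season_peaks": tuple(v.get("season_peaks", ()))})
            for v in d.get("variables", [])
        ]
        d["species"] = [SpeciesConfig(**s) for s in d.get("species", [])]
        for key in ("decades", "ssps", "downscale_methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_config(seed: int = 0) -> RunConfig:
    """The reference synthetic study: a 50 x 60-cell shelf at 0.08 degrees,
    six predictor layers plus one deliberately collinear candidate, five
    species with occurrence counts matching the real compilation, 3
    pseudoabsence sets x 10 repeats, 1000-tree forests."""
    variables = [
        VariableConfig(
            name="BT", kind="cube", base=28.0, deep_value=4.0, profile_scale=60.0,
            season_kind="monomodal", season_peaks=(6,), season_amplitude=1.5,
            gradient_amplitude=0.8, noise_sd=0.4, delta=2.0, bias=0.5, units="degC",
        ),
        VariableConfig(
            name="BS", kind="cube", base=33.7, deep_value=34.5, profile_scale=150.0,
            season_kind="bimodal", season_peaks=(5, 12), season_amplitude=0.6,
            gradient_amplitude=0.6, noise_sd=0.15, delta=-1.0, bias=-0.3, units="PSU",
        ),
        VariableConfig(
            name="SSH", kind="surface", base=0.0, season_kind="monomodal",
            season_peaks=(10,), season_amplitude=0.08, gradient_amplitude=0.05,
            noise_sd=0.02, delta=0.1, bias=0.05, units="m",
        ),
        VariableConfig(
            name="PP", kind="surface", base=300.0, season_kind="bimodal",
            season_peaks=(5, 11), season_amplitude=150.0, gradient_amplitude=60.0,
            noise_sd=20.0, delta=-50.0, bias=20.0, units="mm",
        ),
        # net primary productivity integrates precipitation (riverine
        # nutrient input) with a second driver; it tracks PP above the 0.70
        # screen and the filter is expected to drop it, mirroring how
        # highly collinear candidates are excluded before modeling
        VariableConfig(
            name="NPP", kind="derived", source="PP", scale=0.8,
            source2="SSH", mix=0.25, noise_sd=10.0, units="mg C m-2 day-1",
        ),
    ]
    # steep logistic niches: tolerance envelopes are nearly binary, so
    # occurrences concentrate inside a well-delimited range, as in the
    # dense real compilations the generator stands in for
    species = [
        SpeciesConfig("white_shrimp", 2381, {"BT": 2.0}, intercept=-30.0),
        SpeciesConfig("titi_shrimp", 237, {"BT": 1.6}, intercept=-22.4),
        SpeciesConfig("coliflor_shrimp", 288, {"PP": 0.08}, intercept=-37.6),
        SpeciesConfig("pink_shrimp", 432, {"PP": 0.06, "BT": 0.4}, intercept=-30.8),
        SpeciesConfig("brown_shrimp", 94, {"BAT": 0.02}, intercept=-10.0),
    ]
    return RunConfig(
        lon_max=-80.0 + 50 * 0.08,
        lat_max=1.46 + 60 * 0.08,
        variables=variables,
        species=species,
        seed=seed,
    )


def demo_config(seed: int = 7) -> RunConfig:
    """A scaled-down configuration for the end-to-end demo: two species,
    smaller occurrence samples and forests, linear/spline downscalers only.
    The stage structure is identical to the reference configuration."""
    cfg = default_config(seed)
    cfg.species = [
        SpeciesConfig("white_shrimp", 250, {"BT": 2.0}, intercept=-30.0),
        SpeciesConfig("coliflor_shrimp", 200, {"PP": 0.08}, intercept=-37.6),
    ]
    cfg.sdm_n_estimators = 100
    cfg.sdm_n_repeats = 2
    cfg.downscale_methods = ("rr", "mars")
    cfg.n_years = 2
    return cfg


def enumerate_outputs(config: RunConfig) -> list[tuple[str, str, int]]:
    """The deterministic task list: species x (current + decade x SSP) x
    month."""
    if not config.species:
        raise ValueError("empty species list")
    if not config.scenarios():
        raise ValueError("empty scenario list")
    return [
        (sp.name, sc.name, m)
        for sp in config.species
        for sc in config.scenarios()
        for m in range(1, 13)
    ]


def _seed(run_seed: int, tag: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{run_seed}:{tag}".encode()) & 0x7FFFFFFF


def _surface_grid(grid: DomainGrid) -> DomainGrid:
    return dataclasses.replace(grid, depth_levels=(0.0,))


def _gradient(amplitude: float, seed: int):
    """A fixed smooth random spatial field (unit variance, mesoscale
    correlation length), scaled by ``amplitude``. Each variable gets its
    own field, so horizontal structure is not shared across predictors."""
    cache: dict[tuple[int, int], np.ndarray] = {}

    def f(lon2d, lat2d):
        key = lon2d.shape
        if key not in cache:
            rng = np.random.default_rng(seed)
            field = ndimage.gaussian_filter(rng.normal(size=key), sigma=6.0, mode="wrap")
            sd = field.std()
            cache[key] = field / (sd if sd > 0 else 1.0)
        return amplitude * cache[key]

    return f


def _climatology_from_years(
    config: RunConfig, grid: DomainGrid, var: VariableConfig, run_seed: int
) -> xr.DataArray:
    """Simulate config.n_years years of monthly fields and average them into
    a per-calendar-month climatology."""
    g = grid if var.kind == "cube" else _surface_grid(grid)
    gradient = _gradient(var.gradient_amplitude, _seed(run_seed, f"grad:{var.name}"))
    years = []
    for y in range(config.n_years):
        cube = generate_env_cube(
            g,
            profile=var.profile,
            season=var.season(),
            noise_sd=var.noise_sd,
            seed=_seed(run_seed, f"env:{var.name}:{y}"),
            gradient=gradient,
            name=var.name,
            units=var.units,
        )
        years.append(cube)
    series = xr.concat(years, dim="time")
    series = series.rename({"month": "month_of_year"})
    series = series.stack(t=("time", "month_of_year"))
    month_coord = series["month_of_year"].values
    series = series.drop_vars(["t", "time", "month_of_year"])
    series = series.rename({"t": "time"})
    series = series.assign_coords(month=("time", month_coord))
    clim = monthly_climatology(series)
    clim.name = var.name
    clim.attrs["units"] = var.units
    return clim


def run_pipeline(config: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full synthetic study and write all outputs under
    ``outdir``. Returns the in-memory results (grid, stacks, models, maps,
    tables) for further analysis."""
    run_seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = config.grid()

    # --- synthetic static rasters -------------------------------------------
    bathymetry = generate_bathymetry(
        grid, _seed(run_seed, "bathy"), noise_sd=config.bathymetry_noise_sd,
        land_cells=config.land_cells,
    )
    rng_bh = np.random.default_rng(_seed(run_seed, "bh"))
    bh = ndimage.gaussian_filter(rng_bh.normal(size=(grid.n_lon, grid.n_lat)), sigma=4.0)
    bh = 100.0 * (bh - bh.min()) / max(bh.max() - bh.min(), 1e-12)
    bottom_hardness = bathymetry.copy(data=np.where(np.isfinite(bathymetry.values), bh, np.nan))
    bottom_hardness.name = "BH"
    bottom_hardness.attrs = {"units": "%"}

    # --- current climatologies and bottom projection ------------------------
    cubes: dict[str, xr.DataArray] = {}
    bottom: dict[str, xr.DataArray] = {}
    surface: dict[str, xr.DataArray] = {}
    for var in config.variables:
        if var.kind == "derived":
            continue
        clim = _climatology_from_years(config, grid, var, run_seed)
        if var.kind == "cube":
            cubes[var.name] = clim
            bottom[var.name] = project_to_bottom(clim, bathymetry)["value"].rename(var.name)
        elif var.kind == "surface":
            layer = clim.isel(depth=0, drop=True)
            land = ~np.isfinite(bathymetry.values)
            layer = layer.where(~xr.DataArray(land, dims=("lon", "lat"),
                                              coords={"lon": layer["lon"], "lat": layer["lat"]}))
            surface[var.name] = layer.rename(var.name)
        else:
            raise ValueError(f"unknown variable kind {var.kind!r}")
    for var in config.variables:
        if var.kind != "derived":
            continue
        src = surface.get(var.source, bottom.get(var.source))
        if src is None:
            raise ValueError(f"derived layer {var.name} needs source {var.source!r}")
        rng = np.random.default_rng(_seed(run_seed, f"derived:{var.name}"))
        derived = var.scale * src
        if var.source2:
            src2 = surface.get(var.source2, bottom.get(var.source2))
            if src2 is None:
                raise ValueError(f"derived layer {var.name} needs source {var.source2!r}")
            s1 = float(src.std(skipna=True))
            s2 = float(src2.std(skipna=True))
            derived = derived + var.mix * (s1 / max(s2, 1e-12)) * src2
        noise = rng.normal(0.0, var.noise_sd, size=src.shape)
        surface[var.name] = (derived + noise).rename(var.name)

    static = {"BAT": bathymetry.rename("BAT"), "BH": bottom_hardness}

    # --- collinearity screen on annual means --------------------------------
    candidates = {name: da.mean("month", skipna=True) for name, da in {**bottom, **surface}.items()}
    candidates.update(static)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained, corr = collinearity_filter(candidates, config.collinearity_threshold)
    dropped = [n for n in candidates if n not in retained]
    save_csv(corr.round(10).reset_index(names="layer"), outdir / "correlation_matrix.csv")

    bottom_r = {n: v for n, v in bottom.items() if n in retained}
    surface_r = {n: v for n, v in surface.items() if n in retained}
    static_r = {n: v for n, v in static.items() if n in retained or n == "BAT"}
    current_stack = assemble_stack(bottom_r, surface_r, static_r, CURRENT)

    # --- occurrences and SDM ensembles --------------------------------------
    models = {}
    occurrences = {}
    metrics_rows = []
    importance_rows = []
    feature_names = list(current_stack.data_vars)
    for sp in config.species:
        occ = sample_occurrences(
            sp.truth(), current_stack, sp.n_occurrences,
            _seed(run_seed, f"occ:{sp.name}"), species=sp.name,
        )
        table = generate_pseudoabsences(
            occ, grid, bathymetry, n_sets=config.n_pseudoabsence_sets,
            seed=_seed(run_seed, f"pa:{sp.name}"),
        )
        occurrences[sp.name] = table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_sdm(
                table,
                current_stack,
                n_estimators=config.sdm_n_estimators,
                max_features=config.sdm_max_features,
                min_samples_leaf=config.sdm_min_samples_leaf,
                n_repeats=config.sdm_n_repeats,
                test_size=config.sdm_test_size,
                eval_threshold=config.eval_threshold,
                random_state=_seed(run_seed, f"sdm:{sp.name}"),
            )
        models[sp.name] = model
        perf = model.performance_.assign(species=sp.name)
        metrics_rows.append(perf)
        imp = variable_importance(model, feature_names)
        importance_rows.append(imp.rename(sp.name))
    save_csv(pd.concat(metrics_rows, ignore_index=True), outdir / "metrics.csv")
    save_csv(
        pd.concat(importance_rows, axis=1).reset_index(names="layer"),
        outdir / "importance.csv",
    )

    # --- future forcing ------------------------------------------------------
    dynamic_names = list(bottom_r) + list(surface_r)
    covariates = {"BAT": bathymetry}
    selectors: dict[tuple[str, int], object] = {}
    downscaler_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in dynamic_names:
            fine = bottom_r.get(name, surface_r.get(name))
            for m in range(1, 13):
                fine_m = fine.sel(month=m, drop=True)
                coarse_m = block_aggregate(fine_m, config.coarse_factor)
                sel = fit_downscalers(
                    coarse_m, fine_m, covariates, grid,
                    methods=tuple(config.downscale_methods),
                    split_seed=_seed(run_seed, f"ds:{name}:{m}"),
                )
                selectors[(name, m)] = sel
                for rep in sel.reports_:
                    downscaler_rows.append(
                        {"layer": name, "month": m, "method": rep.method,
                         "rmse": rep.rmse, "selected": rep.selected}
                    )
    save_csv(pd.DataFrame(downscaler_rows), outdir / "downscaler_reports.csv")

    future_stacks: dict[str, xr.Dataset] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sc in config.scenarios():
            if sc.is_current:
                continue
            dyn_b: dict[str, xr.DataArray] = {}
            dyn_s: dict[str, xr.DataArray] = {}
            for name in dynamic_names:
                var = next(v for v in config.variables if v.name == name)
                fine = bottom_r.get(name, surface_r.get(name))
                scaled_delta = var.delta * (sc.ssp / 8.5) * DECADE_WEIGHT[sc.decade]
                months = []
                for m in range(1, 13):
                    fine_m = fine.sel(month=m, drop=True)
                    obs_coarse = block_aggregate(fine_m, config.coarse_factor)
                    corrected = []
                    for g in range(config.n_gcms):
                        gcm_bias = var.bias * (1.0 if g == 0 else -0.5)
                        hist, fut = generate_future_fields(
                            fine_m,
                            FutureFieldSpec(
                                climate_delta=scaled_delta,
                                known_bias=gcm_bias,
                                coarse_factor=config.coarse_factor,
                            ),
                            seed=_seed(run_seed, f"gcm:{name}:{m}:{g}:{sc.name}"),
                            model_noise_sd=config.gcm_noise_sd,
                        )
                        corrected.append(delta_bias_correct(obs_coarse, hist, fut))
                    assembled = ensemble_mean(corrected)
                    fine_future = apply_downscaler(
                        selectors[(name, m)], assembled, covariates, grid
                    )
                    months.append(fine_future.expand_dims(month=[m]))
                layer = xr.concat(months, dim="month").transpose("lon", "lat", "month")
                layer.name = name
                if name in bottom_r:
                    dyn_b[name] = layer
                else:
                    dyn_s[name] = layer
            future_stacks[sc.name] = assemble_stack(dyn_b, dyn_s, static_r, sc)

    # --- monthly suitability, binarization, attributes -----------------------
    suitability: dict[tuple[str, str, int], xr.DataArray] = {}
    binary: dict[tuple[str, str, int], xr.DataArray] = {}
    stacks = {"current": current_stack, **future_stacks}
    for sp in config.species:
        model = models[sp.name]
        for sc_name, stack in stacks.items():
            for m in range(1, 13):
                cp = predict_suitability(model, stack, month=m)
                bp = binarize(cp, config.binarize_threshold)
                suitability[(sp.name, sc_name, m)] = cp
                binary[(sp.name, sc_name, m)] = bp
        ds = xr.Dataset(
            {
                "cp": xr.concat(
                    [
                        xr.concat(
                            [suitability[(sp.name, s, m)].expand_dims(month=[m]) for m in range(1, 13)],
                            dim="month",
                        ).expand_dims(scenario=[s])
                        for s in stacks
                    ],
                    dim="scenario",
                ),
                "bp": xr.concat(
                    [
                        xr.concat(
                            [binary[(sp.name, s, m)].expand_dims(month=[m]) for m in range(1, 13)],
                            dim="month",
                        ).expand_dims(scenario=[s])
                        for s in stacks
                    ],
                    dim="scenario",
                ),
            }
        )
        ds.attrs = {"species": sp.name, "config_hash": config.config_hash(), "seed": run_seed}
        save_netcdf(ds, outdir / f"suitability_{sp.name}.nc")

    attrs_df = build_attribute_table(
        suitability, binary, bathymetry, grid,
        change_band=config.change_band, presence_threshold=config.binarize_threshold,
    )
    save_csv(attrs_df, outdir / "attributes.csv")
    seas = pd.concat(
        [
            seasonality_table(attrs_df, value_col=col, alpha=config.seasonality_alpha)
            for col in ("area_km2", "depth_mean_m", "aggregation_index")
        ],
        ignore_index=True,
    )
    save_csv(seas, outdir / "seasonality.csv")

    provenance = {
        "config_hash": config.config_hash(),
        "seed": run_seed,
        "package_version": __version__,
        "tasks": len(enumerate_outputs(config)),
        "dropped_collinear_layers": dropped,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return {
        "grid": grid,
        "bathymetry": bathymetry,
        "current_stack": current_stack,
        "future_stacks": future_stacks,
        "occurrences": occurrences,
        "models": models,
        "suitability": suitability,
        "binary": binary,
        "attributes": attrs_df,
        "seasonality": seas,
        "retained_layers": retained,
        "dropped_layers": dropped,
        "correlations": corr,
        "selectors": selectors,
    }
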