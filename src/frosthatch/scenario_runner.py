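"""Compose weather, soil, surface layers and solver into named management
scenarios and sensitivity sweeps.

Scenarios represent winter surface states after fall harvest: conventional
tillage leaves bare soil (MAIZE+TILL); no-till leaves a 5 cm maize stover
layer (MAIZE+NOTILL); miscanthus harvest leaves straw layers of 1, 2.5 or
5 cm (MISCAN+R_1cm / MISCAN+R_2.5cm / MISCAN+R_5cm).  Crop growth itself is
not simulated: all analysed statistics are wintertime extremes, so each
scenario is reduced to its post-harvest surface configuration, with the
residue layer persisting year-round.

Sweeps follow a common-random-numbers design: every member of a sweep
consumes the identical weather realisation, so member differences are
purely parametric.

Fractional residue cover (< 1) is handled by parallel two-column
averaging: the covered and bare columns are simulated independently under
the same forcing and their outputs combined by area weight.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import _kernel
from .constants import (
    FREEZING_RANGE,
    SNOW_ALBEDO,
    SNOW_DENSITY,
    SNOW_FULL_COVER_DEPTH,
    SNOW_ROUGHNESS,
    SOIL_ALBEDO,
    SOIL_ROUGHNESS,
    SURFACE_EMISSIVITY,
    WIND_REF_HEIGHT,
    snow_conductivity,
    snow_heat_capacity,
)
from .soil_column import SoilGrid, texture_lookup
from .surface_layers import ResidueSpec, residue_preset
from .synthetic_weather import (
    ClimateParams,
    SITE_PRESETS,
    disaggregate_series,
    generate_daily_series,
    read_weather_csv,
)

DAILY_COLUMNS = ["date", "t10cm_daily_mean", "snow_depth", "swe", "surface_albedo"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one model run."""

    scenario_name: str
    climate: ClimateParams | str  # parameters or a weather CSV path
    texture_profile: tuple[str, ...] = ("silt_loam",) * 11
    residue: ResidueSpec | None = None
    albedo_override: float | None = None
    porosity_override: float | None = None
    n_years: int = 30
    spinup_years: int = 1
    seed: int = 0

    def resolved_residue(self) -> ResidueSpec | None:
        """The residue spec with any albedo/porosity override applied.

        A porosity override adjusts bulk density at fixed cellulose
        density (rho_b = rho_cell * (1 - porosity))."""
        res = self.residue
        if res is None:
            return None
        if self.albedo_override is not None:
            res = replace(res, albedo=float(self.albedo_override))
        if self.porosity_override is not None:
            p = float(self.porosity_override)
            if not 0.0 < p < 1.0:
                raise ValueError("porosity_override must be in (0, 1)")
            res = replace(res, porosity=p, bulk_density=res.cellulose_density * (1.0 - p))
        return res


_SCENARIO_RESIDUE: dict[str, tuple[str, float] | None] = {
    "MAIZE+TILL": None,  # bare soil post harvest
    "MAIZE+NOTILL": ("maize", 0.05),
    "MISCAN+R_1CM": ("miscanthus", 0.01),
    "MISCAN+R_2.5CM": ("miscanthus", 0.025),
    "MISCAN+R_5CM": ("miscanthus", 0.05),
}


def scenario_names() -> tuple[str, ...]:
    return tuple(_SCENARIO_RESIDUE)


def make_scenario(
    name: str,
    climate: ClimateParams | str,
    **kwargs,
) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a registered scenario name.

    ``climate`` may be a :class:`ClimateParams`, a site preset label, or a
    weather CSV path.  Unknown names are rejected unless an explicit
    ``residue`` keyword is supplied (custom scenario).
    """
    if isinstance(climate, str) and climate in SITE_PRESETS:
        climate = SITE_PRESETS[climate]
    key = name.upper().replace(" ", "")
    if key in _SCENARIO_RESIDUE:
        entry = _SCENARIO_RESIDUE[key]
        residue = None
        if entry is not None:
            preset_name, thickness = entry
            residue = residue_preset(preset_name, thickness=thickness)
        kwargs.setdefault("residue", residue)
        return ScenarioConfig(scenario_name=key, climate=climate, **kwargs)
    if "residue" in kwargs:
        return ScenarioConfig(scenario_name=name, climate=climate, **kwargs)
    raise ValueError(
        f"unknown scenario {name!r} without explicit components; "
        f"registered scenarios: {sorted(_SCENARIO_RESIDUE)}"
    )


# ---------------------------------------------------------------------------
# Core run machinery
# ---------------------------------------------------------------------------


def _soil_arrays(texture_profile):
    grid = SoilGrid(texture_by_layer=tuple(texture_profile))
    params = grid.layer_params()
    dz = np.asarray(grid.layer_thicknesses) / 100.0  # m
    return grid, {
        "dz_soil": dz,
        "porosity": np.array([p.porosity for p in params]),
        "field_cap": np.array([p.field_capacity for p in params]),
        "wilt": np.array([p.wilting_point for p in params]),
        "k_dry": np.array([p.dry_conductivity for p in params]),
        "k_solids": np.array([p.solids_conductivity for p in params]),
        "c_solids_vol": np.array([p.solids_heat_capacity for p in params]),
    }


def _run_column(forcing, soil, residue: ResidueSpec | None, t_init: float,
                fc: np.ndarray, allow_soil_evap: bool, substeps: int):
    """Run the numba kernel for one column; returns (daily arrays, ledger)."""
    n = soil["dz_soil"].size
    if residue is not None and residue.thickness > 0:
        dz_res = residue.thickness
        k_res = residue.thermal_conductivity
        c_res = residue.bulk_density * residue.specific_heat
        alb_res = residue.albedo
        z0_res = max(residue.roughness_length, 1e-4)
    else:
        dz_res, k_res, c_res, alb_res, z0_res = 0.0, 0.1, 1e5, 0.2, SOIL_ROUGHNESS

    out = _kernel.simulate_column(
        forcing["air_temp"], forcing["precip"], forcing["is_snow"],
        forcing["shortwave"], forcing["longwave_down"],
        forcing["rel_humidity"], forcing["wind"],
        soil["dz_soil"], soil["porosity"], soil["field_cap"], soil["wilt"],
        soil["k_dry"], soil["k_solids"], soil["c_solids_vol"],
        dz_res, k_res, c_res, alb_res, z0_res,
        SNOW_DENSITY, snow_conductivity(SNOW_DENSITY),
        snow_heat_capacity(SNOW_DENSITY), SNOW_FULL_COVER_DEPTH,
        SNOW_ALBEDO, SNOW_ROUGHNESS,
        SOIL_ALBEDO, SOIL_ROUGHNESS, SURFACE_EMISSIVITY, allow_soil_evap,
        3600.0, 1.0, FREEZING_RANGE, WIND_REF_HEIGHT, substeps,
        np.full(n, float(t_init)), fc.copy(), np.zeros(n),
        0.0, 0.0, float(t_init),
    )
    (t10, snowdepth, swe, albedo,
     _ts, _lq, _ic, _swe, _tsn, _tre,
     e_err, cum_flux, w_err, swe_err, w_step_err) = out
    if not np.isfinite(t10).all():
        raise RuntimeError("simulation produced non-finite 10 cm temperatures")
    daily = {"t10": t10, "snow_depth": snowdepth, "swe": swe, "albedo": albedo}
    ledger = {
        "energy_closure_err_j": float(e_err),
        "cum_abs_surface_flux_j": float(cum_flux),
        "water_closure_err_mm": float(w_err),
        "swe_closure_err_mm": float(swe_err),
        "max_water_step_err_mm": float(w_step_err),
    }
    return daily, ledger


def _resolve_weather(config: ScenarioConfig) -> tuple[pd.DataFrame, float, float]:
    """Weather DataFrame, latitude, and initial soil temperature for a run."""
    total_years = config.n_years + config.spinup_years
    if isinstance(config.climate, ClimateParams):
        daily = generate_daily_series(config.climate, total_years, config.seed)
        lat = config.climate.latitude
        t_init = config.climate.annual_mean_temp
    else:
        daily = read_weather_csv(config.climate)
        lat = 43.0
        t_init = float((daily["tmax_c"] + daily["tmin_c"]).mean() / 2.0)
    return daily, lat, t_init


def run_scenario(
    config: ScenarioConfig,
    daily_weather: pd.DataFrame | None = None,
    substeps: int = 1,
) -> pd.DataFrame:
    """Run one scenario and return daily output after spin-up.

    Columns: ``date, t10cm_daily_mean, snow_depth (m), swe (mm),
    surface_albedo``.  Deterministic under a fixed seed.  Conservation
    ledgers for each simulated column are attached as ``.attrs['ledgers']``.
    ``daily_weather`` lets sweep drivers share one weather realisation
    (common random numbers); when omitted it is generated from the config.
    """
    if config.n_years == 0:
        return pd.DataFrame(columns=DAILY_COLUMNS)
    if isinstance(config.climate, ClimateParams):
        lat = config.climate.latitude
        t_init = config.climate.annual_mean_temp
    if daily_weather is None:
        daily_weather, lat, t_init = _resolve_weather(config)
    else:
        if not isinstance(config.climate, ClimateParams):
            lat = 43.0
            t_init = float((daily_weather["tmax_c"] + daily_weather["tmin_c"]).mean() / 2.0)

    grid, soil = _soil_arrays(config.texture_profile)
    fc = soil["field_cap"]
    forcing = disaggregate_series(daily_weather, lat)
    residue = config.resolved_residue()

    ledgers = []
    if residue is not None and residue.thickness > 0:
        covered, led_c = _run_column(forcing, soil, residue, t_init, fc, False, substeps)
        ledgers.append(led_c)
        f = residue.fractional_cover
        if f < 1.0:
            bare, led_b = _run_column(forcing, soil, None, t_init, fc, True, substeps)
            ledgers.append(led_b)
            daily = {k: f * covered[k] + (1.0 - f) * bare[k] for k in covered}
        else:
            daily = covered
    else:
        daily, led = _run_column(forcing, soil, None, t_init, fc, True, substeps)
        ledgers.append(led)

    out = pd.DataFrame(
        {
            "date": pd.DatetimeIndex(daily_weather["date"]),
            "t10cm_daily_mean": daily["t10"],
            "snow_depth": daily["snow_depth"],
            "swe": daily["swe"],
            "surface_albedo": daily["albedo"],
        }
    )
    skip = config.spinup_years * 365
    out = out.iloc[skip:].reset_index(drop=True)
    out.attrs["ledgers"] = ledgers
    out.attrs["scenario_name"] = config.scenario_name
    out.attrs["seed"] = config.seed
    return out


# ---------------------------------------------------------------------------
# Sensitivity sweeps (common random numbers)
# ---------------------------------------------------------------------------


def _annual_extremes(daily: pd.DataFrame) -> pd.DataFrame:
    from .risk_analysis import annual_extreme_minima

    return annual_extreme_minima(daily)


def thickness_sweep(
    base: ScenarioConfig, thicknesses: list[float]
) -> dict[float, pd.DataFrame]:
    """Paired runs over residue thicknesses (cm), plus the bare reference.

    Every member consumes the identical weather realisation.  Returns a map
    thickness (cm) -> annual-extreme records (the 0 cm bare reference is
    always included).
    """
    th = [float(t) for t in thicknesses]
    if any(t < 0 for t in th):
        raise ValueError("thicknesses must be non-negative")
    if sorted(set(th)) != th:
        raise ValueError("thicknesses must be sorted and unique")
    if base.residue is None:
        raise ValueError("base scenario must carry a residue spec to sweep")
    daily_weather, lat, t_init = _resolve_weather(base)

    out: dict[float, pd.DataFrame] = {}
    for t in sorted(set(th) | {0.0}):
        if t == 0.0:
            cfg = replace(base, residue=None,
                          scenario_name=f"{base.scenario_name}_bare")
        else:
            cfg = replace(base, residue=replace(base.residue, thickness=t / 100.0),
                          scenario_name=f"{base.scenario_name}_{t:g}cm")
        daily = run_scenario(cfg, daily_weather=daily_weather)
        out[t] = _annual_extremes(daily)
    return out


def property_sweep(
    base: ScenarioConfig, field: str, values: list[float]
) -> dict[float, pd.DataFrame]:
    """Paired runs varying residue ``albedo`` or ``porosity``.

    Porosity variation adjusts bulk density with cellulose density held
    fixed.  Weather is shared across members.
    """
    if field not in ("albedo", "porosity"):
        raise ValueError("field must be 'albedo' or 'porosity'")
    if base.residue is None:
        raise ValueError("base scenario must carry a residue spec to sweep")
    vals = [float(v) for v in values]
    if any(not 0.0 < v < 1.0 for v in vals):
        raise ValueError(f"{field} values must lie in (0, 1)")
    daily_weather, lat, t_init = _resolve_weather(base)

    out: dict[float, pd.DataFrame] = {}
    for v in vals:
        if field == "albedo":
            cfg = replace(base, albedo_override=v,
                          scenario_name=f"{base.scenario_name}_alb{v:g}")
        else:
            cfg = replace(base, porosity_override=v,
                          scenario_name=f"{base.scenario_name}_por{v:g}")
        daily = run_scenario(cfg, daily_weather=daily_weather)
        out[v] = _annual_extremes(daily)
    return out


# ---------------------------------------------------------------------------
# Output files with provenance
# ---------------------------------------------------------------------------


def _config_manifest(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(config.climate, ClimateParams):
        d["climate"] = dataclasses.asdict(config.climate)
    return {"config": d, "seed": config.seed, "version": _pkg_version}


def write_daily_csv(daily: pd.DataFrame, path, config: ScenarioConfig) -> None:
    """Write a daily-output CSV with a provenance header (config, seed,
    software version) in leading comment lines."""
    manifest = _config_manifest(config)
    with open(path, "w") as fh:
        fh.write(f"# frosthatch {_pkg_version} scenario={config.scenario_name} "
                 f"seed={config.seed}\n")
        fh.write("# " + json.dumps(manifest, default=str) + "\n")
        daily.to_csv(fh, index=False)


def read_daily_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["date"] = pd.to_datetime(df["date"])
    return df
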