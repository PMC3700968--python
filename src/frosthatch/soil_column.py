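"""Soil column: 11-layer grid, texture look-up, bucket hydrology, and
moisture/ice-dependent thermal properties.

The mineral soil is discretised into 11 layers to 250 cm with the standard
thicknesses (5, 5, 10, 10, 10, 20, 20, 20, 50, 50, 50 cm).  Each layer
carries a USDA texture class whose hydraulic and thermal parameters come
from a versioned look-up table shipped as CSV.  Hydrology is a
field-capacity cascade bucket (excess above field capacity drains downward
instantly); this replaces a Richards-equation solution, a deliberate
simplification because winter extreme minima respond mainly to antecedent
moisture.  Thermal conductivity uses Johansen-style interpolation between
dry and saturated conductivities with liquid/frozen Kersten numbers, and
freezing is handled by an apparent-heat-capacity (enthalpy) scheme over a
0.5 K freezing range.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    FREEZING_RANGE,
    HEAT_CAPACITY_ICE_VOL,
    HEAT_CAPACITY_WATER_VOL,
    K_ICE,
    K_WATER,
    LATENT_HEAT_FUSION,
    RHO_WATER,
)

STANDARD_LAYER_THICKNESSES_CM = (5.0, 5.0, 10.0, 10.0, 10.0, 20.0, 20.0, 20.0, 50.0, 50.0, 50.0)


@dataclass(frozen=True)
class SoilTextureParams:
    """Physical parameter bundle for one USDA texture class.

    Hydraulic: porosity, field capacity, wilting point (m3 m-3), saturated
    hydraulic conductivity (mm h-1), air-entry potential magnitude (kPa),
    Campbell moisture-release ``b``.  Thermal: dry and solids conductivity
    (W m-1 K-1) and volumetric heat capacity of the solid fraction
    (J m-3 K-1).
    """

    texture_class: str
    porosity: float
    field_capacity: float
    wilting_point: float
    sat_hydraulic_conductivity: float
    air_entry_potential: float
    campbell_b: float
    dry_conductivity: float
    solids_conductivity: float
    solids_heat_capacity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.wilting_point < self.field_capacity < self.porosity < 1.0:
            raise ValueError(
                f"{self.texture_class}: require 0 < wilting_point < field_capacity"
                " < porosity < 1"
            )
        if self.campbell_b <= 0:
            raise ValueError("campbell_b must be > 0")


@functools.lru_cache(maxsize=1)
def _texture_table() -> dict[str, SoilTextureParams]:
    ref = importlib.resources.files("frosthatch") / "data" / "texture_table.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, comment="#")
    out = {}
    for _, row in table.iterrows():
        p = SoilTextureParams(**row.to_dict())
        out[p.texture_class] = p
    return out


def texture_classes() -> tuple[str, ...]:
    """The 11 supported USDA-style texture class labels."""
    return tuple(_texture_table())


def texture_lookup(texture_class: str) -> SoilTextureParams:
    """Look up the parameter bundle for a texture class label.

    Labels are case-insensitive; spaces and hyphens map to underscores.
    """
    key = texture_class.strip().lower().replace(" ", "_").replace("-", "_")
    table = _texture_table()
    if key not in table:
        raise KeyError(
            f"unknown texture class {texture_class!r}; valid classes: {sorted(table)}"
        )
    return table[key]


@dataclass(frozen=True)
class SoilGrid:
    """The fixed 11-layer soil grid to 250 cm with per-layer texture."""

    layer_thicknesses: tuple[float, ...] = STANDARD_LAYER_THICKNESSES_CM  # cm
    texture_by_layer: tuple[str, ...] = ("silt_loam",) * 11

    def __post_init__(self) -> None:
        if len(self.layer_thicknesses) != len(self.texture_by_layer):
            raise ValueError("one texture class required per layer")
        if abs(sum(self.layer_thicknesses) - 250.0) > 1e-9:
            raise ValueError("layer thicknesses must sum to 250 cm")
        for t in self.texture_by_layer:
            texture_lookup(t)  # validates

    @property
    def n_layers(self) -> int:
        return len(self.layer_thicknesses)

    @property
    def node_depths(self) -> np.ndarray:
        """Layer midpoint depths, cm (2.5, 7.5, 15, ... 225)."""
        dz = np.asarray(self.layer_thicknesses)
        return np.cumsum(dz) - dz / 2.0

    def layer_params(self) -> list[SoilTextureParams]:
        return [texture_lookup(t) for t in self.texture_by_layer]


@dataclass
class SoilColumnState:
    """Per-layer temperature (degC), liquid water and ice content (m3 m-3)."""

    temperature: np.ndarray
    liquid_water: np.ndarray
    ice: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.liquid_water = np.asarray(self.liquid_water, dtype=float)
        self.ice = np.asarray(self.ice, dtype=float)
        if (self.liquid_water < -1e-12).any() or (self.ice < -1e-12).any():
            raise ValueError("liquid_water and ice must be non-negative")

    def copy(self) -> "SoilColumnState":
        return SoilColumnState(
            self.temperature.copy(), self.liquid_water.copy(), self.ice.copy()
        )


def initial_state(grid: SoilGrid, temperature: float) -> SoilColumnState:
    """Default initial condition: uniform temperature, moisture at field
    capacity, no ice."""
    fc = np.array([p.field_capacity for p in grid.layer_params()])
    n = grid.n_layers
    return SoilColumnState(np.full(n, float(temperature)), fc, np.zeros(n))


# ---------------------------------------------------------------------------
# Thermal properties (Johansen-style mixing)
# ---------------------------------------------------------------------------


def soil_thermal_properties(
    layer_params: SoilTextureParams, liquid: float, ice: float
) -> tuple[float, float]:
    """Thermal conductivity (W m-1 K-1) and volumetric heat capacity
    (J m-3 K-1) of a soil layer at the given water contents.

    Conductivity interpolates between the dry and saturated values with a
    Kersten number: ``Ke = log10(Sr) + 1`` (unfrozen, clipped at 0) and
    ``Ke = Sr`` (frozen), blended by the liquid share; the saturated
    conductivity is the geometric mean of solids, water and ice
    conductivities weighted by volume fraction.  Heat capacity is the
    volume-weighted sum of solids, liquid water, ice and (negligibly) air.
    """
    if liquid < 0 or ice < 0:
        raise ValueError("water contents must be non-negative")
    por = layer_params.porosity
    total = liquid + ice
    if total > por + 1e-9:
        raise ValueError(f"liquid + ice = {total:.4f} exceeds porosity {por}")

    c_air = 1250.0  # J m-3 K-1
    heat_capacity = (
        layer_params.solids_heat_capacity * (1.0 - por)
        + liquid * HEAT_CAPACITY_WATER_VOL
        + ice * HEAT_CAPACITY_ICE_VOL
        + max(0.0, por - total) * c_air
    )

    if total <= 1e-12:
        return layer_params.dry_conductivity, heat_capacity

    sr = min(1.0, total / por)
    fl = liquid / total
    k_sat = (
        layer_params.solids_conductivity ** (1.0 - por)
        * K_WATER ** (por * fl)
        * K_ICE ** (por * (1.0 - fl))
    )
    ke_unfrozen = max(0.0, np.log10(sr) + 1.0) if sr > 1e-6 else 0.0
    ke_frozen = sr
    ke = fl * ke_unfrozen + (1.0 - fl) * ke_frozen
    k = layer_params.dry_conductivity + ke * (k_sat - layer_params.dry_conductivity)
    return float(k), float(heat_capacity)


# ---------------------------------------------------------------------------
# Bucket hydrology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterFluxes:
    """Boundary fluxes of one bucket update, mm water equivalent."""

    infiltration: float
    runoff: float
    evaporation: float
    drainage: float


ICE_BLOCK_TOL = 1e-6  # m3 m-3 of ice above which a layer refuses infiltration


def update_soil_moisture(
    state: SoilColumnState,
    grid: SoilGrid,
    infiltration: float,
    surface_evap: float,
    dt: float,
) -> tuple[SoilColumnState, WaterFluxes]:
    """Field-capacity cascade bucket update.

    Water (mm) infiltrates the top layer and cascades: each layer fills to
    porosity, and anything above field capacity drains to the layer below
    within the step.  Frozen layers (ice > 0) are hydrologically inert: they
    accept no infiltration, and percolation reaching one backs water up into
    the layers above (to porosity), with the remainder leaving as surface
    runoff.  Evaporation draws the top layer down no further than the
    wilting point.  Returns the new state and the boundary fluxes; storage
    change equals ``infiltration - runoff - evaporation - drainage`` to
    round-off.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if infiltration < 0 or surface_evap < 0:
        raise ValueError("infiltration and surface_evap must be >= 0")

    params = grid.layer_params()
    dz_mm = np.asarray(grid.layer_thicknesses) * 10.0  # cm -> mm
    liq = state.liquid_water.copy()
    ice = state.ice
    n = grid.n_layers

    runoff = 0.0

    # evaporation from the top layer (only if unfrozen)
    evap = 0.0
    if ice[0] <= ICE_BLOCK_TOL and surface_evap > 0:
        avail = max(0.0, (liq[0] - params[0].wilting_point)) * dz_mm[0]
        evap = min(surface_evap, avail)
        liq[0] -= evap / dz_mm[0]

    def _back_up(excess_mm: float, below: int) -> float:
        """Push water blocked at layer `below` back up into layers above."""
        for j in range(below - 1, -1, -1):
            room = max(0.0, (params[j].porosity - liq[j] - ice[j])) * dz_mm[j]
            take = min(excess_mm, room)
            liq[j] += take / dz_mm[j]
            excess_mm -= take
            if excess_mm <= 0:
                break
        return excess_mm  # remainder becomes runoff

    inflow = infiltration
    if inflow > 0 and ice[0] > ICE_BLOCK_TOL:
        runoff += inflow
        inflow = 0.0

    drainage = 0.0
    for i in range(n):
        if inflow > 0:
            if ice[i] > ICE_BLOCK_TOL:
                runoff += _back_up(inflow, i)
                inflow = 0.0
            else:
                room = max(0.0, (params[i].porosity - liq[i] - ice[i])) * dz_mm[i]
                absorbed = min(inflow, room)
                liq[i] += absorbed / dz_mm[i]
                overflow = inflow - absorbed
                inflow = overflow
        # gravity drainage of excess above field capacity (unfrozen layers)
        if ice[i] <= ICE_BLOCK_TOL:
            excess = max(0.0, liq[i] - params[i].field_capacity) * dz_mm[i]
            if excess > 0:
                liq[i] -= excess / dz_mm[i]
                inflow += excess
        if i == n - 1 and inflow > 0:
            drainage = inflow
            inflow = 0.0

    new = SoilColumnState(state.temperature.copy(), liq, ice.copy())
    return new, WaterFluxes(infiltration, runoff, evap, drainage)


def column_water_mm(state: SoilColumnState, grid: SoilGrid) -> float:
    """Total column water mass (liquid + ice), mm water equivalent."""
    dz_mm = np.asarray(grid.layer_thicknesses) * 10.0
    return float(np.sum((state.liquid_water + state.ice) * dz_mm))


# ---------------------------------------------------------------------------
# Freeze/thaw enthalpy scheme
# ---------------------------------------------------------------------------


def enthalpy_curve(temp: float, theta_total: float, dry_heat_capacity: float) -> float:
    """Equilibrium volumetric enthalpy h(T), J m-3, liquid-at-0degC reference.

    Piecewise: linear above 0 degC with the fully liquid heat capacity,
    quadratic inside the freezing range [-FREEZING_RANGE, 0] where the
    liquid fraction ramps linearly and latent heat is released, and linear
    below with the fully frozen capacity.
    """
    cw, ci = HEAT_CAPACITY_WATER_VOL, HEAT_CAPACITY_ICE_VOL
    lvol = LATENT_HEAT_FUSION * RHO_WATER * theta_total
    delta = FREEZING_RANGE
    if temp >= 0.0:
        return (dry_heat_capacity + theta_total * cw) * temp
    alpha = theta_total * (cw - ci) / (2.0 * delta)
    beta = dry_heat_capacity + theta_total * cw + lvol / delta
    if temp >= -delta:
        return alpha * temp * temp + beta * temp
    h_bottom = alpha * delta * delta - beta * delta
    return h_bottom + (dry_heat_capacity + theta_total * ci) * (temp + delta)


def enthalpy_inverse(h: float, theta_total: float, dry_heat_capacity: float) -> float:
    """Invert :func:`enthalpy_curve`: temperature (degC) at enthalpy h."""
    cw, ci = HEAT_CAPACITY_WATER_VOL, HEAT_CAPACITY_ICE_VOL
    lvol = LATENT_HEAT_FUSION * RHO_WATER * theta_total
    delta = FREEZING_RANGE
    if h >= 0.0:
        return h / (dry_heat_capacity + theta_total * cw)
    alpha = theta_total * (cw - ci) / (2.0 * delta)
    beta = dry_heat_capacity + theta_total * cw + lvol / delta
    h_bottom = alpha * delta * delta - beta * delta
    if h >= h_bottom:
        if alpha <= 0.0:
            return h / beta
        return (-beta + np.sqrt(beta * beta + 4.0 * alpha * h)) / (2.0 * alpha)
    return -delta + (h - h_bottom) / (dry_heat_capacity + theta_total * ci)


def liquid_fraction(temp: float) -> float:
    """Equilibrium unfrozen fraction of soil water at temperature T."""
    if temp >= 0.0:
        return 1.0
    if temp <= -FREEZING_RANGE:
        return 0.0
    return (temp + FREEZING_RANGE) / FREEZING_RANGE


def freeze_thaw_partition(
    layer_temp: float,
    liquid: float,
    ice: float,
    energy_residual: float,
    dz: float = 0.05,
    dry_heat_capacity: float = 1.2e6,
) -> tuple[float, float, float]:
    """Apply an energy residual (J m-2, positive warms) to one soil layer,
    exchanging latent heat across the freezing range.

    Total water mass is conserved exactly; while both phases coexist the
    temperature stays inside the freezing range.  Repeated equal-and-
    opposite applications return the initial state to round-off, because
    the update is an exact inversion of the piecewise enthalpy curve.
    """
    theta = liquid + ice
    if theta < 0:
        raise ValueError("negative total water")
    if theta <= 1e-15:
        # nothing to freeze: pure sensible change
        t_new = layer_temp + energy_residual / (dz * dry_heat_capacity)
        return 0.0, 0.0, t_new

    # current enthalpy: use the equilibrium curve when the phase split is
    # consistent with the temperature, else a mass-consistent projection
    fl_expected = liquid_fraction(layer_temp)
    if abs(liquid - theta * fl_expected) <= 1e-9 * max(theta, 1e-9):
        h0 = enthalpy_curve(layer_temp, theta, dry_heat_capacity)
    else:
        ceff = dry_heat_capacity + liquid * HEAT_CAPACITY_WATER_VOL + ice * HEAT_CAPACITY_ICE_VOL
        h0 = ceff * layer_temp - LATENT_HEAT_FUSION * RHO_WATER * ice

    h1 = h0 + energy_residual / dz
    t_new = enthalpy_inverse(h1, theta, dry_heat_capacity)
    fl = liquid_fraction(t_new)
    return theta * fl, theta * (1.0 - fl), t_new
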