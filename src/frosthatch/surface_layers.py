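"""Insulating covers above the mineral soil: snowpack and prostrate residue.

The snowpack is a single bulk layer with constant density: snow water
equivalent (SWE), depth, bulk temperature, and a fractional cover that
ramps linearly with depth up to a full-cover depth.  Precipitation phase
follows a fixed air-temperature threshold (1.1 degC, at-or-below = snow).

The residue layer is a prostrate slab of dead plant matter (maize stover or
miscanthus straw) described by its biophysical properties: thickness,
roughness length, bulk and cellulose density, thermal conductivity,
specific heat, porosity, albedo, and fractional cover.  Once established it
persists year-round (no decomposition or wind redistribution in scope).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

from .constants import (
    LATENT_HEAT_FUSION,
    SNOW_DENSITY,
    SNOW_FULL_COVER_DEPTH,
    SNOW_RAIN_THRESHOLD_C,
    RHO_WATER,
    snow_conductivity,
    snow_heat_capacity,
)


@dataclass(frozen=True)
class ResidueSpec:
    """Biophysical description of a prostrate crop-residue layer.

    Shipped presets (:data:`RESIDUE_PRESETS`) carry field-measured values
    for maize stover and miscanthus straw; any field can be overridden per
    scenario.  ``porosity`` is the tabulated air-filled fraction; note it
    need not equal ``1 - bulk_density / cellulose_density`` (see
    :func:`porosity_consistency`).
    """

    residue_type: str  # 'maize' | 'miscanthus' | custom label
    thickness: float  # m
    roughness_length: float  # m
    bulk_density: float  # kg m-3
    cellulose_density: float  # kg m-3
    thermal_conductivity: float  # W m-1 K-1
    specific_heat: float  # J kg-1 K-1
    porosity: float
    albedo: float
    fractional_cover: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if not 0.0 < self.albedo < 1.0:
            raise ValueError("albedo must be in (0, 1)")
        if not self.bulk_density < self.cellulose_density:
            raise ValueError("bulk_density must be below cellulose_density")
        if not 0.0 <= self.fractional_cover <= 1.0:
            raise ValueError("fractional_cover must be in [0, 1]")


RESIDUE_PRESETS: dict[str, ResidueSpec] = {
    "maize": ResidueSpec(
        residue_type="maize",
        thickness=0.05,
        roughness_length=0.012,
        bulk_density=36.4,
        cellulose_density=1450.0,
        thermal_conductivity=0.126,
        specific_heat=1900.0,
        porosity=0.975,
        albedo=0.25,
        fractional_cover=0.95,
    ),
    "miscanthus": ResidueSpec(
        residue_type="miscanthus",
        thickness=0.05,  # scenario-dependent; 1-5 cm in the named runs
        roughness_length=0.0065,
        bulk_density=22.0,
        cellulose_density=1350.0,
        thermal_conductivity=0.08,
        specific_heat=1335.0,
        porosity=0.96,
        albedo=0.32,
        fractional_cover=0.90,
    ),
}


def residue_preset(residue_type: str, **overrides) -> ResidueSpec:
    """A shipped residue preset, optionally with fields overridden."""
    try:
        spec = RESIDUE_PRESETS[residue_type]
    except KeyError:
        raise KeyError(
            f"unknown residue preset {residue_type!r}; available: {sorted(RESIDUE_PRESETS)}"
        ) from None
    return replace(spec, **overrides) if overrides else spec


def porosity_consistency(spec: ResidueSpec) -> tuple[float, float]:
    """Diagnostic: tabulated porosity vs. 1 - bulk/cellulose density.

    The two need not agree for field-measured values; the tabulated porosity
    is what the model uses wherever porosity is required.
    """
    return spec.porosity, 1.0 - spec.bulk_density / spec.cellulose_density


@dataclass(frozen=True)
class SnowState:
    """Bulk snowpack state: SWE (mm), depth (m), fractional cover, bulk
    temperature (degC, <= 0 whenever snow is present)."""

    swe: float = 0.0
    depth: float = 0.0
    frac_cover: float = 0.0
    bulk_temp: float = 0.0

    def __post_init__(self) -> None:
        if self.swe < 0:
            raise ValueError("swe must be >= 0")
        if self.swe > 0 and self.bulk_temp > 1e-9:
            raise ValueError("bulk_temp must be <= 0 degC while snow is present")


def snow_state_from_swe(swe: float, bulk_temp: float = 0.0,
                        density: float = SNOW_DENSITY) -> SnowState:
    """Construct a consistent SnowState from SWE (mm) at constant density."""
    if swe <= 0:
        return SnowState()
    depth = swe / 1000.0 * RHO_WATER / density
    return SnowState(
        swe=swe,
        depth=depth,
        frac_cover=min(1.0, depth / SNOW_FULL_COVER_DEPTH),
        bulk_temp=min(0.0, bulk_temp),
    )


def partition_precipitation(air_temp: float) -> str:
    """Rain/snow phase: snow at or below the 1.1 degC threshold."""
    return "snow" if air_temp <= SNOW_RAIN_THRESHOLD_C else "rain"


def update_snowpack(
    state: SnowState,
    forcing,
    surface_energy: float,
    dt: float,
    density: float = SNOW_DENSITY,
) -> tuple[SnowState, float]:
    """Advance the bulk snowpack by one forcing interval.

    Snowfall (phase from the forcing record) adds SWE at the air temperature
    (capped at 0 degC), mixing enthalpy with the existing pack.  Positive
    ``surface_energy`` (W m-2) first warms the bulk temperature to 0 degC,
    then melts at the latent heat of fusion; negative energy cools the pack.
    Returns the new state and the meltwater (mm) routed to infiltration.
    Rain falls through (returned as melt/throughfall); SWE never goes
    negative and depth follows from the constant density.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    swe = state.swe
    temp = state.bulk_temp
    melt_out = 0.0

    precip = getattr(forcing, "precip", 0.0) * dt  # mm over the interval
    phase = getattr(forcing, "precip_phase", "rain")
    if precip > 0 and phase == "snow":
        t_new_snow = min(0.0, getattr(forcing, "air_temp", 0.0))
        temp = (swe * temp + precip * t_new_snow) / (swe + precip) if swe + precip > 0 else 0.0
        swe += precip
    elif precip > 0:
        melt_out += precip  # rain-through

    if swe > 0:
        energy = surface_energy * dt * 3600.0  # J m-2
        c_vol = snow_heat_capacity(density)
        dz = swe / 1000.0 * RHO_WATER / density
        if energy > 0:
            warm_need = -temp * c_vol * dz  # J m-2 to reach 0 degC
            if energy <= warm_need:
                temp += energy / (c_vol * dz)
            else:
                temp = 0.0
                melt_energy = energy - warm_need
                melt = min(swe, melt_energy / (LATENT_HEAT_FUSION * RHO_WATER) * 1000.0)
                swe -= melt
                melt_out += melt
        elif energy < 0:
            temp += energy / (c_vol * dz)

    if swe <= 1e-12:
        return SnowState(), melt_out
    return snow_state_from_swe(swe, temp, density), melt_out


def snow_thermal_properties(state: SnowState,
                            density: float = SNOW_DENSITY) -> tuple[float, float]:
    """Conductivity (W m-1 K-1) and volumetric heat capacity (J m-3 K-1) of
    the bulk snow layer; with constant density both are constants.  A
    zero-SWE state has no layer (the conduction stack omits it)."""
    if state.swe < 0:
        raise ValueError("swe must be >= 0")
    return snow_conductivity(density), snow_heat_capacity(density)


def residue_thermal_properties(spec: ResidueSpec) -> tuple[float, float]:
    """Conductivity (pass-through) and volumetric heat capacity
    (bulk density x specific heat) of the residue slab."""
    return spec.thermal_conductivity, spec.bulk_density * spec.specific_heat


def composite_albedo(
    soil_albedo: float,
    residue: ResidueSpec | None,
    snow: SnowState,
    snow_albedo: float = 0.75,
) -> float:
    """Area-weighted land-surface albedo of the snow/residue/soil mosaic.

    The snow-covered fraction takes the snow albedo; the remainder splits
    between residue (by its fractional cover) and bare soil.  Always a
    convex combination of its components.
    """
    for a in (soil_albedo, snow_albedo) + ((residue.albedo,) if residue else ()):
        if not 0.0 < a < 1.0:
            raise ValueError("component albedos must be in (0, 1)")
    fr = residue.fractional_cover if residue is not None and residue.thickness > 0 else 0.0
    under = fr * (residue.albedo if residue else 0.0) + (1.0 - fr) * soil_albedo
    return snow.frac_cover * snow_albedo + (1.0 - snow.frac_cover) * under


def thatch_mass_for_thickness(bulk_density: float, thickness: float) -> float:
    """Aboveground biomass (Mg ha-1) needed for a thatch layer.

    ``bulk_density`` in kg m-3, ``thickness`` in cm.  A 1 cm layer over one
    hectare at rho kg m-3 weighs rho * 0.01 m * 10^4 m2 kg = rho/10 Mg.
    """
    if bulk_density < 0 or thickness < 0:
        raise ValueError("inputs must be >= 0")
    return bulk_density * (thickness / 100.0) * 1e4 / 1000.0
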