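"""Physical constants shared across the soil/snow/residue thermal model.

All values SI unless noted. Temperatures are degrees Celsius throughout the
package; Kelvin conversions happen locally where radiation laws need them.
"""

# Water substance
LATENT_HEAT_FUSION = 334_000.0  # J kg-1
LATENT_HEAT_VAPOR = 2.501e6  # J kg-1
RHO_WATER = 1000.0  # kg m-3
HEAT_CAPACITY_WATER_VOL = 4.18e6  # J m-3 K-1 (liquid water)
HEAT_CAPACITY_ICE_VOL = 1.9e6  # J m-3 K-1 (ice)
SPECIFIC_HEAT_ICE = 2100.0  # J kg-1 K-1

# Thermal conductivities of soil constituents (W m-1 K-1)
K_WATER = 0.57
K_ICE = 2.2

# Freezing-point depression range for the apparent-heat-capacity scheme.
# Liquid fraction ramps linearly from 1 at 0 degC to 0 at -FREEZING_RANGE.
FREEZING_POINT = 0.0  # degC
FREEZING_RANGE = 0.5  # K

# Atmosphere
STEFAN_BOLTZMANN = 5.67e-8  # W m-2 K-4
VON_KARMAN = 0.4
AIR_PRESSURE = 101_325.0  # Pa
SPECIFIC_HEAT_AIR = 1005.0  # J kg-1 K-1
GAS_CONSTANT_DRY_AIR = 287.05  # J kg-1 K-1
T0_KELVIN = 273.15

# Rain/snow partition threshold: precipitation at or below this air
# temperature falls as snow.
SNOW_RAIN_THRESHOLD_C = 1.1  # degC

# Snowpack (constant-density bulk layer).  The constant density represents
# a seasonal bulk pack (settled, not fresh) rather than new snowfall.
SNOW_DENSITY = 250.0  # kg m-3
SNOW_FULL_COVER_DEPTH = 0.05  # m of snow depth for full fractional cover
SNOW_ALBEDO = 0.75
SNOW_EMISSIVITY = 0.97

# Bare mineral surface
SOIL_ALBEDO = 0.15
SOIL_ROUGHNESS = 0.005  # m
SNOW_ROUGHNESS = 0.002  # m
SURFACE_EMISSIVITY = 0.97

WIND_REF_HEIGHT = 10.0  # m
MIN_WIND = 0.5  # m s-1, free-convection floor for bulk transfer


def snow_conductivity(density: float) -> float:
    """Snow thermal conductivity from density, k = 0.021 + 2.5 (rho/1000)^2.

    Quadratic density relation of the Sturm/Yen family; strictly increasing
    in density. W m-1 K-1.
    """
    return 0.021 + 2.5 * (density / 1000.0) ** 2


def snow_heat_capacity(density: float) -> float:
    """Volumetric heat capacity of snow, J m-3 K-1."""
    return density * SPECIFIC_HEAT_ICE
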