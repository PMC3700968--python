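"""Surface energy balance and 1-D heat conduction through the
snow-residue-soil stack.

The conduction stack is an ordered sequence of slabs: an optional snow
slab, an optional residue slab, then the 11 soil layers.  Temperatures
advance by an unconditionally stable implicit scheme (backward Euler by
default, Crank-Nicolson selectable via ``theta``) with interface
conductances from harmonic means of slab resistances, a zero-flux base at
250 cm, and an enthalpy treatment of soil freezing.  A Dirichlet "test
mode" (prescribed top/bottom temperatures) exists so analytic conduction
oracles are expressible.

The surface boundary condition comes from a skin-temperature energy
balance: net shortwave and longwave radiation, neutral bulk-aerodynamic
sensible and latent heat, and conduction into the top slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .constants import FREEZING_RANGE, SURFACE_EMISSIVITY, WIND_REF_HEIGHT
from .soil_column import liquid_fraction


@dataclass
class ConductionStack:
    """Ordered slab stack for 1-D conduction.

    Arrays run top to bottom.  ``n_soil`` soil slabs sit at the bottom of
    the stack; slabs above them (snow, residue) do not take part in the
    soil depth coordinate or in phase change.  For soil slabs,
    ``soil_theta_total`` (total volumetric water) and
    ``soil_dry_heat_capacity`` (J m-3 K-1 of the non-water matrix) drive
    the freezing enthalpy curve; set ``phase_change=False`` to treat every
    slab as purely sensible (used by the analytic test modes).
    """

    thickness: np.ndarray  # m
    conductivity: np.ndarray  # W m-1 K-1
    heat_capacity: np.ndarray  # J m-3 K-1 (sensible, unfrozen)
    temperature: np.ndarray  # degC
    n_soil: int = 0
    soil_theta_total: np.ndarray | None = None
    soil_dry_heat_capacity: np.ndarray | None = None
    phase_change: bool = True

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.conductivity = np.asarray(self.conductivity, dtype=float)
        self.heat_capacity = np.asarray(self.heat_capacity, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        n = self.thickness.size
        for name in ("conductivity", "heat_capacity", "temperature"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must match thickness length {n}")
        if (self.thickness <= 0).any():
            raise ValueError("slab thicknesses must be > 0")
        if self.n_soil > n:
            raise ValueError("n_soil exceeds slab count")

    @property
    def n_slabs(self) -> int:
        return self.thickness.size

    def soil_node_depths_cm(self) -> np.ndarray:
        """Midpoint depths of the soil slabs, cm below the mineral surface."""
        dz_cm = self.thickness[self.n_slabs - self.n_soil:] * 100.0
        return np.cumsum(dz_cm) - dz_cm / 2.0

    def copy(self) -> "ConductionStack":
        return ConductionStack(
            self.thickness.copy(), self.conductivity.copy(),
            self.heat_capacity.copy(), self.temperature.copy(),
            self.n_soil,
            None if self.soil_theta_total is None else self.soil_theta_total.copy(),
            None if self.soil_dry_heat_capacity is None else self.soil_dry_heat_capacity.copy(),
            self.phase_change,
        )


@dataclass(frozen=True)
class SurfaceEnergyResult:
    """Components of the skin-temperature energy balance, W m-2.

    ``ground_heat_flux`` is positive downward; at convergence it equals
    ``net_shortwave + net_longwave - sensible - latent``.
    """

    net_shortwave: float
    net_longwave: float
    sensible: float
    latent: float
    ground_heat_flux: float
    skin_temp: float  # degC


def surface_energy_balance(
    forcing,
    albedo: float,
    roughness_length: float,
    top_slab: tuple[float, float, float],
    beta: float = 0.0,
    emissivity: float = SURFACE_EMISSIVITY,
) -> SurfaceEnergyResult:
    """Solve the surface flux balance for the skin temperature.

    ``top_slab`` is ``(thickness_m, conductivity, temperature)`` of the
    uppermost stack slab; ``beta`` the soil-moisture factor for latent heat
    (0 disables evaporation, the winter default).  Converges to
    |residual| < 0.1 W m-2 or raises naming the forcing record.
    """
    if not 0.0 < albedo < 1.0:
        raise ValueError("albedo must be in (0, 1)")
    if getattr(forcing, "wind", 0.0) < 0:
        raise ValueError("wind must be >= 0")
    dz, k, t_top = top_slab
    g_top = 2.0 * k / dz
    ts, net_sw, net_lw, sens, lat, ghf, ok = _kernel.solve_surface_energy(
        float(forcing.shortwave), float(forcing.longwave_down),
        float(forcing.air_temp), float(forcing.rel_humidity),
        float(forcing.wind), float(albedo), float(roughness_length),
        float(emissivity), g_top, float(t_top), float(beta),
        WIND_REF_HEIGHT,
    )
    if not ok:
        raise RuntimeError(
            f"surface energy balance failed to converge for forcing at "
            f"{getattr(forcing, 'timestamp', '<unknown time>')}"
        )
    return SurfaceEnergyResult(net_sw, net_lw, sens, lat, ghf, ts)


def step_heat_conduction(
    stack: ConductionStack,
    ground_heat_flux: float,
    dt: float,
    theta: float = 1.0,
    top_temperature: float | None = None,
    bottom_temperature: float | None = None,
) -> ConductionStack:
    """Advance the stack one conduction step of ``dt`` hours.

    The default boundary conditions are a prescribed downward flux
    ``ground_heat_flux`` (W m-2) at the top and zero flux at the base.
    Dirichlet test mode: passing ``top_temperature`` / ``bottom_temperature``
    replaces the corresponding flux condition with a prescribed surface
    temperature.  ``theta=1`` is backward Euler, ``theta=0.5``
    Crank-Nicolson.  Energy is conserved to iteration tolerance:
    sum(H(T') - H(T)) equals the applied boundary fluxes times dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    n = stack.n_slabs
    cdry = stack.heat_capacity.astype(float).copy()
    theta_w = np.zeros(n)
    if stack.phase_change and stack.n_soil > 0:
        if stack.soil_theta_total is None or stack.soil_dry_heat_capacity is None:
            raise ValueError(
                "phase_change stacks need soil_theta_total and soil_dry_heat_capacity"
            )
        s0 = n - stack.n_soil
        theta_w[s0:] = stack.soil_theta_total
        cdry[s0:] = stack.soil_dry_heat_capacity

    t_new, _qt, _qb, converged = _kernel.conduct_step(
        stack.thickness, stack.conductivity, stack.temperature,
        cdry, theta_w, FREEZING_RANGE,
        float(ground_heat_flux), dt * 3600.0, float(theta),
        top_temperature is not None,
        0.0 if top_temperature is None else float(top_temperature),
        bottom_temperature is not None,
        0.0 if bottom_temperature is None else float(bottom_temperature),
    )
    if not converged or not np.isfinite(t_new).all():
        raise RuntimeError(
            f"conduction step failed: converged={converged}, "
            f"temperatures={t_new}"
        )
    out = stack.copy()
    out.temperature = t_new
    return out


def stack_liquid_ice(stack: ConductionStack) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium liquid/ice split of the soil slabs implied by their
    temperatures (apparent-heat-capacity scheme)."""
    if stack.soil_theta_total is None:
        raise ValueError("stack has no soil water description")
    s0 = stack.n_slabs - stack.n_soil
    temps = stack.temperature[s0:]
    fl = np.array([liquid_fraction(t) for t in temps])
    liquid = stack.soil_theta_total * fl
    return liquid, stack.soil_theta_total - liquid


def temperature_at_depth(stack: ConductionStack, depth: float) -> float:
    """Soil temperature (degC) at a depth (cm) by linear interpolation
    between soil node (slab midpoint) temperatures.

    Snow/residue slabs are excluded from the soil depth coordinate.  Above
    the first node and below the last the nearest node value is used.
    """
    if not 0.0 <= depth <= 250.0:
        raise ValueError(f"depth must be within [0, 250] cm, got {depth}")
    if stack.n_soil < 1:
        raise ValueError("stack has no soil slabs")
    nodes = stack.soil_node_depths_cm()
    temps = stack.temperature[stack.n_slabs - stack.n_soil:]
    return float(np.interp(depth, nodes, temps))
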