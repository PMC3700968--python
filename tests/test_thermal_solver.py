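"""Conduction solver and surface energy balance against analytic oracles."""

import numpy as np
import pandas as pd
import pytest

import frosthatch as fh
from frosthatch import _kernel, constants
from frosthatch.soil_column import enthalpy_curve
from frosthatch.thermal_solver import ConductionStack, stack_liquid_ice


def test_kernel_constants_in_sync():
    """The numba kernel duplicates physical constants as plain floats;
    they must match the package-level definitions."""
    assert _kernel.LF == constants.LATENT_HEAT_FUSION
    assert _kernel.CW == constants.HEAT_CAPACITY_WATER_VOL
    assert _kernel.CI == constants.HEAT_CAPACITY_ICE_VOL
    assert _kernel.KW == constants.K_WATER
    assert _kernel.KICE == constants.K_ICE
    assert _kernel.SIGMA == constants.STEFAN_BOLTZMANN
    assert _kernel.C_ICE_MASS == constants.SPECIFIC_HEAT_ICE


def uniform_stack(n=11, t=10.0, k=1.0, c=2.5e6, dz=0.05, phase=False):
    return ConductionStack(
        thickness=np.full(n, dz),
        conductivity=np.full(n, k),
        heat_capacity=np.full(n, c),
        temperature=np.full(n, t),
        n_soil=n,
        phase_change=phase,
    )


class TestConduction:
    def test_equilibrium_unchanged(self):
        stack = uniform_stack()
        out = fh.step_heat_conduction(stack, 0.0, 1.0)
        np.testing.assert_allclose(out.temperature, stack.temperature, atol=1e-12)

    def test_steady_state_matches_resistance_network(self):
        """Dirichlet 0/10 degC ends on a heterogeneous stack: the converged
        profile must match the series thermal-resistance closed form."""
        dz = np.array([0.03, 0.05, 0.10, 0.10, 0.20])
        k = np.array([0.08, 0.3, 1.2, 0.6, 2.0])
        stack = ConductionStack(dz, k, np.full(5, 2.0e6), np.full(5, 5.0),
                                n_soil=5, phase_change=False)
        for _ in range(4000):
            stack = fh.step_heat_conduction(stack, 0.0, 1.0,
                                            top_temperature=0.0,
                                            bottom_temperature=10.0)
        r_total = np.sum(dz / k)
        q = (10.0 - 0.0) / r_total
        # node temperatures from cumulative resistance top -> node centre
        r_cum = np.cumsum(dz / k) - dz / (2 * k)
        expected = 0.0 + q * r_cum
        np.testing.assert_allclose(stack.temperature, expected, atol=1e-6)

    def test_sinusoidal_damping_depth(self):
        """Daily sinusoid on a homogeneous unfrozen column: amplitude at
        depth z decays as exp(-z/d), d = sqrt(2 kappa / omega), within 5%."""
        n, dz = 100, 0.02
        k, c = 1.2, 2.4e6
        kappa = k / c
        omega = 2 * np.pi / 86400.0
        d = np.sqrt(2 * kappa / omega)
        stack = ConductionStack(np.full(n, dz), np.full(n, k), np.full(n, c),
                                np.full(n, 10.0), n_soil=n, phase_change=False)
        dt_h = 1.0 / 6.0  # 10-min steps, Crank-Nicolson
        n_steps = int(8 * 24 / dt_h)
        probe_depth_cm = 11.0  # a node centre
        record = []
        for i in range(n_steps):
            t_surf = 10.0 + 5.0 * np.sin(omega * i * dt_h * 3600.0)
            stack = fh.step_heat_conduction(stack, 0.0, dt_h, theta=0.5,
                                            top_temperature=t_surf)
            record.append(fh.temperature_at_depth(stack, probe_depth_cm))
        last_day = np.array(record[-int(24 / dt_h):])
        amp = (last_day.max() - last_day.min()) / 2.0
        expected = 5.0 * np.exp(-probe_depth_cm / 100.0 / d)
        assert amp == pytest.approx(expected, rel=0.05)

    def test_flux_step_conserves_energy_with_phase_change(self):
        """H(T') - H(T) summed over slabs equals the applied boundary flux
        times dt, including latent exchange, using the enthalpy curve as the
        independent energy meter."""
        grid = fh.SoilGrid()
        params = grid.layer_params()
        theta = np.array([p.field_capacity for p in params])
        cdry = np.array([p.solids_heat_capacity * (1 - p.porosity)
                         + 1250.0 * (p.porosity - t)
                         for p, t in zip(params, theta)])
        dz = np.asarray(grid.layer_thicknesses) / 100.0
        stack = ConductionStack(
            dz, np.full(11, 1.2), np.full(11, 2.8e6), np.full(11, 0.3),
            n_soil=11, soil_theta_total=theta, soil_dry_heat_capacity=cdry,
            phase_change=True)
        q = -80.0  # strong cooling, drives the top layers into freezing
        h_before = sum(z * enthalpy_curve(t, th, cd)
                       for z, t, th, cd in zip(dz, stack.temperature, theta, cdry))
        out = stack
        hours = 48
        for _ in range(hours):
            out = fh.step_heat_conduction(out, q, 1.0)
        h_after = sum(z * enthalpy_curve(t, th, cd)
                      for z, t, th, cd in zip(dz, out.temperature, theta, cdry))
        applied = q * hours * 3600.0
        assert h_after - h_before == pytest.approx(applied, rel=1e-3)
        liquid, ice = stack_liquid_ice(out)
        assert ice[0] > 0  # freezing actually happened

    def test_zero_curtain(self):
        """A wet freezing layer stays inside the freezing range until its
        ice fraction saturates (latent-heat plateau)."""
        grid = fh.SoilGrid()
        params = grid.layer_params()
        theta = np.array([p.field_capacity for p in params])
        cdry = np.array([p.solids_heat_capacity * (1 - p.porosity) for p in params])
        dz = np.asarray(grid.layer_thicknesses) / 100.0
        stack = ConductionStack(
            dz, np.full(11, 1.2), np.full(11, 2.8e6), np.full(11, 0.2),
            n_soil=11, soil_theta_total=theta, soil_dry_heat_capacity=cdry,
            phase_change=True)
        saw_mixed = False
        for _ in range(400):
            stack = fh.step_heat_conduction(stack, 0.0, 1.0, top_temperature=-10.0)
            liquid, ice = stack_liquid_ice(stack)
            t1 = stack.temperature[0]
            if 1e-9 < ice[0] < theta[0] - 1e-9:
                saw_mixed = True
                assert -constants.FREEZING_RANGE <= t1 <= 0.0
        assert saw_mixed
        # by now the top layer has frozen through and left the curtain
        liquid, ice = stack_liquid_ice(stack)
        assert ice[0] == pytest.approx(theta[0])
        assert stack.temperature[0] < -constants.FREEZING_RANGE

    def test_rejects_bad_inputs(self):
        stack = uniform_stack()
        with pytest.raises(ValueError, match="dt"):
            fh.step_heat_conduction(stack, 0.0, 0.0)
        with pytest.raises(ValueError, match="theta"):
            fh.step_heat_conduction(stack, 0.0, 1.0, theta=0.0)


class TestTemperatureAtDepth:
    def test_uniform_field(self):
        stack = uniform_stack(t=3.0)
        assert fh.temperature_at_depth(stack, 10.0) == pytest.approx(3.0)

    def test_linear_interpolation(self):
        grid = fh.SoilGrid()
        dz = np.asarray(grid.layer_thicknesses) / 100.0
        temps = np.zeros(11)
        temps[1] = -4.0  # node at 7.5 cm
        temps[2] = -1.0  # node at 15 cm
        stack = ConductionStack(dz, np.full(11, 1.0), np.full(11, 2e6), temps,
                                n_soil=11, phase_change=False)
        assert fh.temperature_at_depth(stack, 10.0) == pytest.approx(-3.0)
        assert fh.temperature_at_depth(stack, 7.5) == pytest.approx(-4.0)

    def test_excludes_cover_slabs_from_depth(self):
        grid = fh.SoilGrid()
        dz = np.concatenate([[0.05], np.asarray(grid.layer_thicknesses) / 100.0])
        temps = np.concatenate([[-20.0], np.full(11, 2.0)])
        stack = ConductionStack(dz, np.full(12, 1.0), np.full(12, 2e6), temps,
                                n_soil=11, phase_change=False)
        assert fh.temperature_at_depth(stack, 10.0) == pytest.approx(2.0)

    def test_rejects_out_of_range(self):
        stack = uniform_stack()
        with pytest.raises(ValueError, match="depth"):
            fh.temperature_at_depth(stack, 300.0)


class SimpleForcing:
    def __init__(self, **kw):
        self.timestamp = kw.get("timestamp", pd.Timestamp("2000-01-15 12:00"))
        self.air_temp = kw.get("air_temp", 0.0)
        self.precip = 0.0
        self.precip_phase = "rain"
        self.shortwave = kw.get("shortwave", 0.0)
        self.longwave_down = kw.get("longwave_down", 250.0)
        self.rel_humidity = kw.get("rel_humidity", 70.0)
        self.wind = kw.get("wind", 3.0)


class TestSurfaceEnergyBalance:
    TOP = (0.05, 1.2, -1.0)  # dz, k, temperature of the top slab

    def test_net_shortwave_arithmetic(self):
        f = SimpleForcing(shortwave=500.0, air_temp=5.0)
        res = fh.surface_energy_balance(f, 0.25, 0.005, self.TOP)
        assert res.net_shortwave == pytest.approx(375.0)

    def test_radiative_equilibrium_all_fluxes_zero(self):
        """Night, skin at air temperature, emissivity-balanced longwave:
        every flux component vanishes."""
        t = 2.0
        lw = constants.STEFAN_BOLTZMANN * (t + 273.15) ** 4
        f = SimpleForcing(shortwave=0.0, air_temp=t, longwave_down=lw, wind=0.0)
        res = fh.surface_energy_balance(f, 0.2, 0.005, (0.05, 1.2, t))
        assert res.skin_temp == pytest.approx(t, abs=0.01)
        for flux in (res.net_shortwave, res.net_longwave, res.sensible,
                     res.latent, res.ground_heat_flux):
            assert abs(flux) < 0.5

    def test_flux_balance_residual(self):
        f = SimpleForcing(shortwave=300.0, air_temp=-5.0, longwave_down=200.0)
        res = fh.surface_energy_balance(f, 0.3, 0.01, self.TOP)
        residual = (res.net_shortwave + res.net_longwave - res.sensible
                    - res.latent - res.ground_heat_flux)
        assert abs(residual) < 0.1

    def test_higher_albedo_reduces_daily_ground_heat_flux(self):
        """Two full balance evaluations over a sunny day: the 0.50 albedo
        surface absorbs less and conducts strictly less heat downward."""
        day = {"date": pd.Timestamp("2000-03-01"), "tmax_c": 5.0, "tmin_c": -5.0,
               "precip_mm": 0.0, "rh_pct": 60.0, "wind_ms": 3.0, "solar_mj": 14.0}
        hours = fh.disaggregate_to_hourly(pd.Series(day), pd.Series(day),
                                          pd.Series(day), latitude=43.0)
        means = {}
        for albedo in (0.15, 0.50):
            ghf = [fh.surface_energy_balance(h, albedo, 0.005, self.TOP).ground_heat_flux
                   for h in hours]
            means[albedo] = np.mean(ghf)
        assert means[0.50] < means[0.15]

    def test_rejects_bad_albedo(self):
        with pytest.raises(ValueError, match="albedo"):
            fh.surface_energy_balance(SimpleForcing(), 1.2, 0.005, self.TOP)
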