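"""Numba inner loops for the hourly snow-residue-soil simulation.

The public modules (:mod:`thermal_solver`, :mod:`scenario_runner`) are thin
wrappers over these kernels, so the per-operation API and the fast
multi-year path share one numerical implementation.

Numerics: the conduction step is an implicit (theta-weighted, backward
Euler by default) finite-volume solve on the slab stack with an enthalpy
(apparent-heat-capacity) treatment of soil freezing.  Each step solves
``H(T') - H(T) = dt * F(T')`` by Newton iteration on the enthalpy form;
steps that would cross an enthalpy kink are clamped just inside the
destination piece, which prevents latent-heat overshoot oscillation.  At
convergence the step conserves energy to iteration tolerance.  The surface
energy balance solves for skin temperature by Newton iteration with a
bisection fallback.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Constants duplicated here as plain floats for numba (kept in sync with
# frosthatch.constants; see tests/test_thermal_solver.py).
LF = 334_000.0
LV = 2.501e6
RHOW = 1000.0
CW = 4.18e6
CI = 1.9e6
C_ICE_MASS = 2100.0
KW = 0.57
KICE = 2.2
SIGMA = 5.67e-8
KARMAN = 0.4
P_AIR = 101_325.0
CP_AIR = 1005.0
R_DRY = 287.05
T0K = 273.15
C_AIR_VOL = 1250.0


# ---------------------------------------------------------------------------
# Enthalpy curve (volumetric, J m-3, liquid-at-0degC reference)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _hvol(t, cdry, theta, frange):
    """Equilibrium volumetric enthalpy of a slab; theta=0 -> pure sensible."""
    if theta <= 0.0:
        return cdry * t
    if t >= 0.0:
        return (cdry + theta * CW) * t
    lvol = LF * RHOW * theta
    alpha = theta * (CW - CI) / (2.0 * frange)
    beta = cdry + theta * CW + lvol / frange
    if t >= -frange:
        return alpha * t * t + beta * t
    h_bottom = alpha * frange * frange - beta * frange
    return h_bottom + (cdry + theta * CI) * (t + frange)


@njit(cache=True)
def _hvol_inv(h, cdry, theta, frange):
    if theta <= 0.0:
        return h / cdry
    if h >= 0.0:
        return h / (cdry + theta * CW)
    lvol = LF * RHOW * theta
    alpha = theta * (CW - CI) / (2.0 * frange)
    beta = cdry + theta * CW + lvol / frange
    h_bottom = alpha * frange * frange - beta * frange
    if h >= h_bottom:
        return (-beta + np.sqrt(beta * beta + 4.0 * alpha * h)) / (2.0 * alpha)
    return -frange + (h - h_bottom) / (cdry + theta * CI)


@njit(cache=True)
def _dhdT(t, cdry, theta, frange):
    if theta <= 0.0:
        return cdry
    if t >= 0.0:
        return cdry + theta * CW
    if t >= -frange:
        lvol = LF * RHOW * theta
        alpha = theta * (CW - CI) / (2.0 * frange)
        beta = cdry + theta * CW + lvol / frange
        return 2.0 * alpha * t + beta
    return cdry + theta * CI


@njit(cache=True)
def _clamp_to_breakpoint(t_cur, t_prop, theta, frange):
    """Newton safeguarding across the enthalpy kinks: a step that crosses a
    piece boundary (0 or -frange) stops just inside the destination piece,
    so the next iteration linearises with the correct slope and the latent
    plateau cannot be overshot."""
    if theta <= 0.0:
        return t_prop
    eps = 1e-9
    if t_prop < t_cur:  # moving down
        if t_cur > 0.0 and t_prop < 0.0:
            return -eps
        if t_cur >= -frange and t_prop < -frange:
            return -frange - eps
    else:  # moving up
        if t_cur < -frange and t_prop > -frange:
            return -frange + eps
        if t_cur <= 0.0 and t_prop > 0.0:
            return eps
    return t_prop


@njit(cache=True)
def _liquid_fraction(t, frange):
    if t >= 0.0:
        return 1.0
    if t <= -frange:
        return 0.0
    return (t + frange) / frange


# ---------------------------------------------------------------------------
# Tridiagonal (Thomas) solver
# ---------------------------------------------------------------------------


@njit(cache=True)
def _thomas(lower, diag, upper, rhs):
    n = diag.shape[0]
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = upper[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        m = diag[i] - lower[i] * cp[i - 1]
        cp[i] = upper[i] / m
        dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / m
    x = np.empty(n)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


# ---------------------------------------------------------------------------
# Implicit conduction step with phase change
# ---------------------------------------------------------------------------


@njit(cache=True)
def conduct_step(dz, k, t_old, cdry, theta_w, frange, q_top, dt, theta_scheme,
                 dirichlet_top, t_top_bc, dirichlet_bot, t_bot_bc):
    """One theta-weighted implicit conduction step on the slab stack.

    Returns (t_new, q_top_applied, q_bot_applied, converged_flag).
    Fluxes positive downward (into the stack at the top, out at the bottom
    negative convention: q_bot_applied is the flux INTO the bottom slab
    from below, zero for the default zero-flux base).
    """
    m = dz.shape[0]
    g = np.empty(m - 1)
    for i in range(m - 1):
        g[i] = 1.0 / (dz[i] / (2.0 * k[i]) + dz[i + 1] / (2.0 * k[i + 1]))
    g_top = 2.0 * k[0] / dz[0]
    g_bot = 2.0 * k[m - 1] / dz[m - 1]

    h_old = np.empty(m)
    for i in range(m):
        h_old[i] = dz[i] * _hvol(t_old[i], cdry[i], theta_w[i], frange)

    t_new = t_old.copy()
    lower = np.empty(m)
    diag = np.empty(m)
    upper = np.empty(m)
    rhs = np.empty(m)

    # explicit part of the theta scheme
    f_expl = np.zeros(m)
    if theta_scheme < 1.0:
        for i in range(m):
            f = 0.0
            if i == 0:
                if dirichlet_top:
                    f += g_top * (t_top_bc - t_old[0])
                else:
                    f += q_top
            else:
                f += g[i - 1] * (t_old[i - 1] - t_old[i])
            if i == m - 1:
                if dirichlet_bot:
                    f += g_bot * (t_bot_bc - t_old[i])
            else:
                f += g[i] * (t_old[i + 1] - t_old[i])
            f_expl[i] = f

    converged = False
    for _ in range(120):
        # residual at current iterate
        max_dt = 0.0
        for i in range(m):
            s = _dhdT(t_new[i], cdry[i], theta_w[i], frange) * dz[i]
            f_impl = 0.0
            gl = 0.0
            gr = 0.0
            if i == 0:
                if dirichlet_top:
                    f_impl += g_top * (t_top_bc - t_new[0])
                    gl = g_top
                else:
                    f_impl += q_top
            else:
                f_impl += g[i - 1] * (t_new[i - 1] - t_new[i])
                gl = g[i - 1]
            if i == m - 1:
                if dirichlet_bot:
                    f_impl += g_bot * (t_bot_bc - t_new[i])
                    gr = g_bot
            else:
                f_impl += g[i] * (t_new[i + 1] - t_new[i])
                gr = g[i]
            h_new = dz[i] * _hvol(t_new[i], cdry[i], theta_w[i], frange)
            resid = h_new - h_old[i] - dt * (
                theta_scheme * f_impl + (1.0 - theta_scheme) * f_expl[i]
            )
            diag[i] = s + dt * theta_scheme * (gl + gr)
            lower[i] = -dt * theta_scheme * (g[i - 1] if i > 0 else 0.0)
            upper[i] = -dt * theta_scheme * (g[i] if i < m - 1 else 0.0)
            rhs[i] = -resid
        delta = _thomas(lower, diag, upper, rhs)
        for i in range(m):
            t_prop = _clamp_to_breakpoint(t_new[i], t_new[i] + delta[i],
                                          theta_w[i], frange)
            ad = abs(t_prop - t_new[i])
            t_new[i] = t_prop
            if ad > max_dt:
                max_dt = ad
        if max_dt < 1e-9:
            converged = True
            break

    if dirichlet_top:
        q_top_applied = dt * (
            theta_scheme * g_top * (t_top_bc - t_new[0])
            + (1.0 - theta_scheme) * g_top * (t_top_bc - t_old[0])
        ) / dt
    else:
        q_top_applied = q_top
    if dirichlet_bot:
        q_bot_applied = dt * (
            theta_scheme * g_bot * (t_bot_bc - t_new[m - 1])
            + (1.0 - theta_scheme) * g_bot * (t_bot_bc - t_old[m - 1])
        ) / dt
    else:
        q_bot_applied = 0.0
    return t_new, q_top_applied, q_bot_applied, converged


# ---------------------------------------------------------------------------
# Surface energy balance
# ---------------------------------------------------------------------------


@njit(cache=True)
def _esat_kpa(t):
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


@njit(cache=True)
def _spec_humidity(e_kpa):
    e = e_kpa * 1000.0
    return 0.622 * e / (P_AIR - 0.378 * e)


@njit(cache=True)
def solve_surface_energy(sw_down, lw_down, t_air, rh, wind, albedo, z0,
                         emissivity, g_top, t_top, beta, z_ref):
    """Solve the skin-temperature flux balance.

    Returns (t_skin, net_sw, net_lw, sensible, latent, ground_heat_flux,
    converged).  Fluxes W m-2, ground heat flux positive downward.
    Sensible/latent use neutral bulk-aerodynamic transfer with roughness
    z0; latent only when beta > 0, clamped non-negative (no dew deposition).
    """
    u = max(wind, 0.5)
    ch = (KARMAN / np.log(z_ref / z0)) ** 2
    rho_a = P_AIR / (R_DRY * (t_air + T0K))
    h_coef = rho_a * CP_AIR * ch * u
    le_coef = beta * rho_a * LV * ch * u
    q_air = _spec_humidity(rh / 100.0 * _esat_kpa(t_air))
    net_sw = (1.0 - albedo) * sw_down

    ts = t_air
    converged = False
    for _ in range(50):
        tsk = ts + T0K
        lw_up = emissivity * SIGMA * tsk**4
        le = 0.0
        dle = 0.0
        if le_coef > 0.0:
            es = _esat_kpa(ts)
            qs = _spec_humidity(es)
            le = le_coef * (qs - q_air)
            if le > 0.0:
                des = es * 17.27 * 237.3 / (ts + 237.3) ** 2
                dle = le_coef * 0.622 * (des * 1000.0) / P_AIR
            else:
                le = 0.0
        f = (net_sw + emissivity * lw_down - lw_up
             - h_coef * (ts - t_air) - le - g_top * (ts - t_top))
        if abs(f) < 0.01:
            converged = True
            break
        df = -4.0 * emissivity * SIGMA * tsk**3 - h_coef - dle - g_top
        step = -f / df
        if step > 10.0:
            step = 10.0
        elif step < -10.0:
            step = -10.0
        ts = ts + step

    if not converged:
        # bisection fallback: f is strictly decreasing in ts
        lo = t_air - 80.0
        hi = t_air + 80.0
        for _ in range(80):
            ts = 0.5 * (lo + hi)
            tsk = ts + T0K
            le = 0.0
            if le_coef > 0.0:
                le = le_coef * (_spec_humidity(_esat_kpa(ts)) - q_air)
                if le < 0.0:
                    le = 0.0
            f = ((1.0 - albedo) * sw_down + emissivity * lw_down
                 - emissivity * SIGMA * tsk**4
                 - h_coef * (ts - t_air) - le - g_top * (ts - t_top))
            if abs(f) < 0.01:
                converged = True
                break
            if f > 0.0:
                lo = ts
            else:
                hi = ts

    tsk = ts + T0K
    le = 0.0
    if le_coef > 0.0:
        le = le_coef * (_spec_humidity(_esat_kpa(ts)) - q_air)
        if le < 0.0:
            le = 0.0
    net_lw = emissivity * lw_down - emissivity * SIGMA * tsk**4
    sens = h_coef * (ts - t_air)
    ghf = g_top * (ts - t_top)
    return ts, net_sw, net_lw, sens, le, ghf, converged


# ---------------------------------------------------------------------------
# Bucket hydrology (mirror of soil_column.update_soil_moisture)
# ---------------------------------------------------------------------------

ICE_TOL = 1e-6


@njit(cache=True)
def _bucket(liq, ice, dz_mm, porosity, field_cap, wilt, infiltration, evap_demand):
    """Field-capacity cascade; returns (runoff, evap_actual, drainage)."""
    n = liq.shape[0]
    runoff = 0.0
    evap = 0.0
    if ice[0] <= ICE_TOL and evap_demand > 0.0:
        avail = max(0.0, (liq[0] - wilt[0])) * dz_mm[0]
        evap = min(evap_demand, avail)
        liq[0] -= evap / dz_mm[0]

    inflow = infiltration
    if inflow > 0.0 and ice[0] > ICE_TOL:
        runoff += inflow
        inflow = 0.0

    drainage = 0.0
    for i in range(n):
        if inflow > 0.0:
            if ice[i] > ICE_TOL:
                # back water up into the layers above, rest runs off
                excess = inflow
                for j in range(i - 1, -1, -1):
                    room = max(0.0, porosity[j] - liq[j] - ice[j]) * dz_mm[j]
                    take = min(excess, room)
                    liq[j] += take / dz_mm[j]
                    excess -= take
                    if excess <= 0.0:
                        break
                runoff += excess
                inflow = 0.0
            else:
                room = max(0.0, porosity[i] - liq[i] - ice[i]) * dz_mm[i]
                absorbed = min(inflow, room)
                liq[i] += absorbed / dz_mm[i]
                inflow -= absorbed
        if ice[i] <= ICE_TOL:
            excess = max(0.0, liq[i] - field_cap[i]) * dz_mm[i]
            if excess > 0.0:
                liq[i] -= excess / dz_mm[i]
                inflow += excess
        if i == n - 1 and inflow > 0.0:
            drainage = inflow
            inflow = 0.0
    return runoff, evap, drainage


# ---------------------------------------------------------------------------
# Johansen thermal conductivity
# ---------------------------------------------------------------------------


@njit(cache=True)
def _soil_k(k_dry, k_solids, porosity, liq, ice):
    total = liq + ice
    if total <= 1e-12:
        return k_dry
    sr = min(1.0, total / porosity)
    fl = liq / total
    k_sat = (k_solids ** (1.0 - porosity)) * (KW ** (porosity * fl)) * (
        KICE ** (porosity * (1.0 - fl))
    )
    if sr > 1e-6:
        ke_u = np.log10(sr) + 1.0
        if ke_u < 0.0:
            ke_u = 0.0
    else:
        ke_u = 0.0
    ke = fl * ke_u + (1.0 - fl) * sr
    return k_dry + ke * (k_sat - k_dry)


# ---------------------------------------------------------------------------
# Column enthalpy bookkeeping (liquid-at-0degC reference for water substance)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _soil_enthalpy(dz_soil, porosity, c_solids_vol, t_soil, liq, ice):
    e = 0.0
    for i in range(dz_soil.shape[0]):
        cdry = c_solids_vol[i] * (1.0 - porosity[i]) + C_AIR_VOL * max(
            0.0, porosity[i] - liq[i] - ice[i])
        e += dz_soil[i] * ((cdry + liq[i] * CW + ice[i] * CI) * t_soil[i]
                           - LF * RHOW * ice[i])
    return e


@njit(cache=True)
def _col_enthalpy(dz_soil, porosity, c_solids_vol, t_soil, liq, ice,
                  has_res, c_res_vol, dz_res, t_res, swe, t_snow):
    e = _soil_enthalpy(dz_soil, porosity, c_solids_vol, t_soil, liq, ice)
    if has_res:
        e += c_res_vol * dz_res * t_res
    if swe > 0.0:
        e += swe * (-LF + C_ICE_MASS * t_snow)  # swe mm == kg m-2
    return e


# ---------------------------------------------------------------------------
# Main hourly simulation loop for one column
# ---------------------------------------------------------------------------


@njit(cache=True)
def simulate_column(
    # hourly forcing (n_hours,)
    ta, prec, is_snowfall, sw, lwd, rh, wind,
    # soil (11,)
    dz_soil, porosity, field_cap, wilt, k_dry, k_solids, c_solids_vol,
    # residue slab (absent if dz_res <= 0)
    dz_res, k_res, c_res_vol, alb_res, z0_res,
    # snow parameters
    rho_snow, k_snow, c_snow_vol, d_full, alb_snow, z0_snow,
    # bare surface
    alb_soil, z0_soil, emissivity, allow_soil_evap,
    # numerics
    dt_s, theta_scheme, frange, z_ref, substeps,
    # initial state
    t_soil0, liq0, ice0, swe0, t_snow0, t_res0,
):
    """Run the full hourly land-surface loop for one soil column.

    Returns daily series (t10 mean, snow depth mean, SWE at end of day,
    albedo mean), the final state, and conservation ledgers:
    (energy_closure_error, cum_abs_surface_flux, water_closure_error,
    swe_closure_error, max_water_step_error).
    """
    n_hours = ta.shape[0]
    n_days = n_hours // 24
    nsoil = dz_soil.shape[0]
    has_res = dz_res > 0.0

    t_soil = t_soil0.copy()
    liq = liq0.copy()
    ice = ice0.copy()
    swe = swe0
    t_snow = t_snow0
    t_res = t_res0

    dz_mm = dz_soil * 1000.0

    out_t10 = np.zeros(n_days)
    out_snowdepth = np.zeros(n_days)
    out_swe = np.zeros(n_days)
    out_albedo = np.zeros(n_days)

    max_slabs = nsoil + 2
    dz_st = np.empty(max_slabs)
    k_st = np.empty(max_slabs)
    t_st = np.empty(max_slabs)
    cdry_st = np.empty(max_slabs)
    thw_st = np.empty(max_slabs)

    # --- ledgers ---
    e_start = _col_enthalpy(dz_soil, porosity, c_solids_vol, t_soil, liq, ice,
                            has_res, c_res_vol, dz_res, t_res, swe, t_snow)
    e_counted = 0.0
    cum_abs_flux = 0.0

    w_start = swe
    for i in range(nsoil):
        w_start += (liq[i] + ice[i]) * dz_mm[i]
    w_in = 0.0
    w_out = 0.0
    max_water_step_err = 0.0

    swe_counted = swe  # snowfall-minus-melt running balance
    n_sub = substeps
    dt_sub = dt_s / n_sub

    for h in range(n_hours):
        day = h // 24
        rain_mm = 0.0
        snowfall_mm = 0.0
        if prec[h] > 0.0:
            if is_snowfall[h]:
                snowfall_mm = prec[h]
            else:
                rain_mm = prec[h]

        for _sub in range(n_sub):
            sub_rain = rain_mm / n_sub
            sub_snowfall = snowfall_mm / n_sub
            w_step_before = swe
            for i in range(nsoil):
                w_step_before += (liq[i] + ice[i]) * dz_mm[i]

            # --- snowfall accumulation (enthalpy-mixing at <= 0 degC) ---
            if sub_snowfall > 0.0:
                tsf = min(ta[h], 0.0)
                if swe > 0.0:
                    t_snow = (swe * t_snow + sub_snowfall * tsf) / (swe + sub_snowfall)
                else:
                    t_snow = tsf
                swe += sub_snowfall
                e_counted += sub_snowfall * (-LF + C_ICE_MASS * tsf)
                swe_counted += sub_snowfall
                w_in += sub_snowfall
            if sub_rain > 0.0:
                w_in += sub_rain

            snow_on = swe > 1e-6

            # --- assemble the conduction stack ---
            ns = 0
            if snow_on:
                dzs = swe / rho_snow  # mm (kg m-2) / (kg m-3) = m
                frac = min(1.0, dzs / d_full)
                dz_st[ns] = dzs
                k_st[ns] = k_snow / frac
                t_st[ns] = t_snow
                cdry_st[ns] = c_snow_vol
                thw_st[ns] = 0.0
                ns += 1
            if has_res:
                dz_st[ns] = dz_res
                k_st[ns] = k_res
                t_st[ns] = t_res
                cdry_st[ns] = c_res_vol
                thw_st[ns] = 0.0
                ns += 1
            ofs = ns
            for i in range(nsoil):
                dz_st[ns] = dz_soil[i]
                k_st[ns] = _soil_k(k_dry[i], k_solids[i], porosity[i], liq[i], ice[i])
                t_st[ns] = t_soil[i]
                cdry_st[ns] = c_solids_vol[i] * (1.0 - porosity[i]) + C_AIR_VOL * max(
                    0.0, porosity[i] - liq[i] - ice[i])
                thw_st[ns] = liq[i] + ice[i]
                ns += 1

            # --- surface state ---
            if has_res:
                under_alb = alb_res
                z0 = z0_res
            else:
                under_alb = alb_soil
                z0 = z0_soil
            if snow_on:
                frac = min(1.0, (swe / rho_snow) / d_full)
                albedo = frac * alb_snow + (1.0 - frac) * under_alb
                z0 = z0_snow
            else:
                albedo = under_alb

            beta = 0.0
            if allow_soil_evap and (not snow_on) and (not has_res) and ice[0] <= ICE_TOL:
                beta = (liq[0] - wilt[0]) / (field_cap[0] - wilt[0])
                if beta < 0.0:
                    beta = 0.0
                elif beta > 1.0:
                    beta = 1.0

            # --- surface energy balance coupled implicitly to conduction:
            # the skin solves against the END-of-step top-slab temperature
            # (fixed-point iteration), and enters the conduction step as a
            # Dirichlet condition through the half-slab conductance, which
            # keeps thin residue/snow slabs stable ---
            g_top = 2.0 * k_st[0] / dz_st[0]
            t_top_iter = t_st[0]
            ts = ta[h]
            melt_flux = 0.0
            le = 0.0
            t_new = t_st[:ns]
            q_applied = 0.0
            for _it in range(4):
                ts, _nsw, _nlw, _sens, le, _ghf, seb_ok = solve_surface_energy(
                    sw[h], lwd[h], ta[h], rh[h], wind[h], albedo, z0,
                    emissivity, g_top, t_top_iter, beta, z_ref)
                melt_flux = 0.0
                if snow_on and ts > 0.0:
                    # hold the skin at the melting point; the positive
                    # residual is the melt energy flux
                    tsk = T0K
                    lw_up = emissivity * SIGMA * tsk**4
                    u = max(wind[h], 0.5)
                    ch = (KARMAN / np.log(z_ref / z0)) ** 2
                    rho_a = P_AIR / (R_DRY * (ta[h] + T0K))
                    h_coef = rho_a * CP_AIR * ch * u
                    melt_flux = ((1.0 - albedo) * sw[h] + emissivity * lwd[h]
                                 - lw_up - h_coef * (0.0 - ta[h])
                                 - g_top * (0.0 - t_top_iter))
                    if melt_flux < 0.0:
                        melt_flux = 0.0
                    le = 0.0
                    ts = 0.0
                t_new, q_applied, _qb, _conv = conduct_step(
                    dz_st[:ns], k_st[:ns], t_st[:ns], cdry_st[:ns], thw_st[:ns],
                    frange, 0.0, dt_sub, theta_scheme,
                    True, ts, False, 0.0)
                if abs(t_new[0] - t_top_iter) < 0.005:
                    break
                t_top_iter = t_new[0]

            e_counted += q_applied * dt_sub
            cum_abs_flux += abs(q_applied) * dt_sub + melt_flux * dt_sub

            # --- unpack and phase-sync ---
            idx = 0
            if snow_on:
                t_snow = t_new[idx]
                idx += 1
            if has_res:
                t_res = t_new[idx]
                idx += 1
            for i in range(nsoil):
                t_soil[i] = t_new[idx + i]
                th = liq[i] + ice[i]
                fl = _liquid_fraction(t_soil[i], frange)
                liq[i] = th * fl
                ice[i] = th * (1.0 - fl)

            # --- snow melt ---
            melt_mm = 0.0
            if snow_on:
                e_avail = melt_flux * dt_sub
                e_counted += melt_flux * dt_sub
                if t_snow > 0.0:
                    dzs = swe / rho_snow
                    e_avail += c_snow_vol * dzs * t_snow
                    t_snow = 0.0
                if e_avail > 0.0:
                    melt_mm = e_avail / LF  # J m-2 / (J kg-1) = kg m-2 = mm
                    if melt_mm >= swe:
                        melt_mm = swe
                        e_left = e_avail - melt_mm * LF
                        swe = 0.0
                        # dump leftover energy into the slab below the snow
                        if has_res:
                            t_res += e_left / (c_res_vol * dz_res)
                        else:
                            cdry0 = cdry_st[ofs]
                            th0 = liq[0] + ice[0]
                            h0 = _hvol(t_soil[0], cdry0, th0, frange) + e_left / dz_soil[0]
                            t_soil[0] = _hvol_inv(h0, cdry0, th0, frange)
                            fl = _liquid_fraction(t_soil[0], frange)
                            liq[0] = th0 * fl
                            ice[0] = th0 * (1.0 - fl)
                    else:
                        swe -= melt_mm
                swe_counted -= melt_mm

            # --- hydrology ---
            infil = sub_rain + melt_mm
            evap_demand = 0.0
            if le > 0.0:
                evap_demand = le * dt_sub / LV  # kg m-2 = mm
            e_soil_before = _soil_enthalpy(dz_soil, porosity, c_solids_vol,
                                           t_soil, liq, ice)
            runoff, evap, drainage = _bucket(
                liq, ice, dz_mm, porosity, field_cap, wilt, infil, evap_demand)
            e_counted += _soil_enthalpy(dz_soil, porosity, c_solids_vol,
                                        t_soil, liq, ice) - e_soil_before
            w_out += runoff + evap + drainage

            # per-step water closure
            w_step_after = swe
            for i in range(nsoil):
                w_step_after += (liq[i] + ice[i]) * dz_mm[i]
            step_err = abs(
                (w_step_after - w_step_before)
                - (sub_rain + sub_snowfall - runoff - evap - drainage))
            if step_err > max_water_step_err:
                max_water_step_err = step_err

        # --- daily accumulation ---
        t10 = (2.0 / 3.0) * t_soil[1] + (1.0 / 3.0) * t_soil[2]
        out_t10[day] += t10 / 24.0
        depth_now = swe / rho_snow if swe > 0.0 else 0.0
        out_snowdepth[day] += depth_now / 24.0
        out_swe[day] += swe / 24.0
        alb_now = albedo
        out_albedo[day] += alb_now / 24.0

    e_end = _col_enthalpy(dz_soil, porosity, c_solids_vol, t_soil, liq, ice,
                          has_res, c_res_vol, dz_res, t_res, swe, t_snow)
    energy_closure_err = abs((e_end - e_start) - e_counted)

    w_end = swe
    for i in range(nsoil):
        w_end += (liq[i] + ice[i]) * dz_mm[i]
    water_closure_err = abs((w_end - w_start) - (w_in - w_out))
    swe_closure_err = abs(swe - swe_counted)

    return (out_t10, out_snowdepth, out_swe, out_albedo,
            t_soil, liq, ice, swe, t_snow, t_res,
            energy_closure_err, cum_abs_flux, water_closure_err,
            swe_closure_err, max_water_step_err)
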