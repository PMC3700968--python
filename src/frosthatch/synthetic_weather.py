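"""Synthetic daily weather generation and hourly disaggregation.

Generates multi-year daily weather series with the statistical structure of
mid-latitude continental (Midwest-style) winters: a sinusoidal seasonal
cycle with a mid-January minimum, lag-1 autoregressive daily anomalies,
Poisson-arriving Arctic cold outbreaks modelled as additive negative
temperature pulses, mixed-phase precipitation, and an optional linear
warming trend.  The generator stands in for gridded station-interpolated
climate data and is the only source of randomness in a simulation: a fixed
seed yields a bit-identical series.

A 365-day calendar (no leap days) is used so every year has the same length;
dates are real calendar dates with Feb 29 never emitted.

Hourly disaggregation follows standard weather-generator practice: a
piecewise cosine diurnal temperature shape with the minimum at sunrise and
the maximum in mid-afternoon, solar radiation distributed over daylight
hours by solar geometry, downwelling longwave from a clear-sky emissivity
formula with a cloud correction tied to the wet-day flag, and precipitation
spread over a contiguous block of hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import SNOW_RAIN_THRESHOLD_C, STEFAN_BOLTZMANN, T0_KELVIN

WEATHER_COLUMNS = ["date", "tmax_c", "tmin_c", "precip_mm", "rh_pct", "wind_ms", "solar_mj"]

DAYS_PER_YEAR = 365
_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_STARTS = np.concatenate([[0], np.cumsum(_MONTH_LENGTHS)])  # day-of-year offsets

# Diurnal shape: hour of the daily temperature maximum (local solar time)
PEAK_HOUR = 14.5


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the daily weather generator for one site.

    ``seasonal_amplitude`` is half the peak-to-trough range of the daily-mean
    temperature cycle (degC); ``coldest_day_of_year`` the day index (1-365) of
    the cycle minimum.  Anomalies are AR(1) with marginal SD ``anomaly_sd``
    and lag-1 autocorrelation ``anomaly_autocorr``.  Cold outbreaks arrive
    Poisson with ``outbreak_rate`` events per winter (Nov-Mar), each a
    half-sine cooling pulse of ``outbreak_duration_days`` days whose peak
    magnitude has mean ``outbreak_drop`` (degC).  The expected outbreak
    cooling is compensated by a uniform offset so the closed-form mean of the
    generated daily-mean temperature equals ``annual_mean_temp`` exactly.
    ``winter_precip_fraction`` is the fraction of annual precipitation
    falling in the 90 days centred on the coldest day.  ``trend_per_decade``
    applies a linear ramp centred on the series midpoint (mean-preserving).
    """

    annual_mean_temp: float = 9.0  # degC
    seasonal_amplitude: float = 15.5  # degC
    coldest_day_of_year: int = 15
    anomaly_sd: float = 3.5  # degC
    anomaly_autocorr: float = 0.75
    outbreak_rate: float = 3.0  # events per winter
    outbreak_drop: float = 9.0  # degC, mean peak extra cooling
    outbreak_duration_days: int = 5
    wet_day_prob: float = 0.28
    precip_mean: float = 6.0  # mm per wet day (annual mean)
    winter_precip_fraction: float = 0.18
    trend_per_decade: float = 0.0  # degC per decade
    latitude: float = 43.0  # degrees N, used for solar geometry
    site_label: str = "custom"

    def __post_init__(self) -> None:
        if not self.seasonal_amplitude > 0:
            raise ValueError("seasonal_amplitude must be > 0")
        if not 0.0 <= self.anomaly_autocorr < 1.0:
            raise ValueError("anomaly_autocorr must be in [0, 1)")
        if self.outbreak_duration_days < 1:
            raise ValueError("outbreak_duration_days must be >= 1")
        if not self.precip_mean > 0:
            raise ValueError("precip_mean must be > 0")
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet_day_prob must be in [0, 1]")


@dataclass(frozen=True)
class DailyWeather:
    """One day of weather at the land surface."""

    date: pd.Timestamp
    tmax: float  # degC
    tmin: float  # degC
    precip: float  # mm water equivalent
    rel_humidity: float  # %
    wind: float  # m s-1
    solar: float  # MJ m-2 d-1

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError("tmax must be >= tmin")
        if self.precip < 0 or self.solar < 0:
            raise ValueError("precip and solar must be non-negative")
        if not 0.0 <= self.rel_humidity <= 100.0:
            raise ValueError("rel_humidity must be in [0, 100]")

    @classmethod
    def from_row(cls, row) -> "DailyWeather":
        return cls(
            date=pd.Timestamp(row["date"]),
            tmax=float(row["tmax_c"]),
            tmin=float(row["tmin_c"]),
            precip=float(row["precip_mm"]),
            rel_humidity=float(row["rh_pct"]),
            wind=float(row["wind_ms"]),
            solar=float(row["solar_mj"]),
        )


@dataclass(frozen=True)
class HourlyForcing:
    """One hour of atmospheric drivers at the land surface."""

    timestamp: pd.Timestamp
    air_temp: float  # degC
    precip: float  # mm h-1
    precip_phase: str  # 'rain' | 'snow'
    shortwave: float  # W m-2
    longwave_down: float  # W m-2
    rel_humidity: float  # %
    wind: float  # m s-1


# ---------------------------------------------------------------------------
# Site presets spanning a continental cold/snowy-to-mild climate gradient
# ---------------------------------------------------------------------------

SITE_PRESETS: dict[str, ClimateParams] = {
    # Cold continental northern plains: severe winters, moderate snowfall
    "north-plains": ClimateParams(
        annual_mean_temp=4.0, seasonal_amplitude=18.5, anomaly_sd=4.0,
        outbreak_rate=4.0, outbreak_drop=10.0, outbreak_duration_days=6,
        wet_day_prob=0.24, precip_mean=5.0, winter_precip_fraction=0.12,
        latitude=47.5, site_label="north-plains"),
    # Northern lake-influenced: cold with persistent, heavier snow
    "northern-lakes": ClimateParams(
        annual_mean_temp=5.0, seasonal_amplitude=16.5, anomaly_sd=3.6,
        outbreak_rate=3.0, outbreak_drop=9.0, outbreak_duration_days=5,
        wet_day_prob=0.33, precip_mean=6.0, winter_precip_fraction=0.24,
        latitude=46.0, site_label="northern-lakes"),
    "west-plains": ClimateParams(
        annual_mean_temp=7.5, seasonal_amplitude=17.0, anomaly_sd=4.0,
        outbreak_rate=3.0, outbreak_drop=9.0, outbreak_duration_days=5,
        wet_day_prob=0.22, precip_mean=5.0, winter_precip_fraction=0.10,
        latitude=44.5, site_label="west-plains"),
    "sand-plains": ClimateParams(
        annual_mean_temp=6.8, seasonal_amplitude=16.0, anomaly_sd=3.6,
        outbreak_rate=3.0, outbreak_drop=9.0, outbreak_duration_days=5,
        wet_day_prob=0.30, precip_mean=5.5, winter_precip_fraction=0.16,
        latitude=44.2, site_label="sand-plains"),
    "central-cornbelt": ClimateParams(
        annual_mean_temp=9.0, seasonal_amplitude=15.5, anomaly_sd=3.5,
        outbreak_rate=2.5, outbreak_drop=8.5, outbreak_duration_days=5,
        wet_day_prob=0.29, precip_mean=6.5, winter_precip_fraction=0.15,
        latitude=42.0, site_label="central-cornbelt"),
    "east-cornbelt": ClimateParams(
        annual_mean_temp=10.0, seasonal_amplitude=14.0, anomaly_sd=3.3,
        outbreak_rate=2.0, outbreak_drop=8.0, outbreak_duration_days=4,
        wet_day_prob=0.33, precip_mean=6.5, winter_precip_fraction=0.19,
        latitude=40.5, site_label="east-cornbelt"),
    "south-plains": ClimateParams(
        annual_mean_temp=12.5, seasonal_amplitude=13.0, anomaly_sd=3.4,
        outbreak_rate=1.8, outbreak_drop=8.0, outbreak_duration_days=4,
        wet_day_prob=0.26, precip_mean=7.0, winter_precip_fraction=0.14,
        latitude=38.5, site_label="south-plains"),
    "south": ClimateParams(
        annual_mean_temp=14.0, seasonal_amplitude=12.0, anomaly_sd=3.2,
        outbreak_rate=1.5, outbreak_drop=7.0, outbreak_duration_days=3,
        wet_day_prob=0.28, precip_mean=7.5, winter_precip_fraction=0.16,
        latitude=36.5, site_label="south"),
}


def _noleap_dates(start_year: int, n_days: int) -> pd.DatetimeIndex:
    """Calendar dates for a 365-day (no Feb 29) year sequence."""
    idx = np.arange(n_days)
    year = start_year + idx // DAYS_PER_YEAR
    doy0 = idx % DAYS_PER_YEAR  # 0-based day of year
    month = np.searchsorted(_MONTH_STARTS, doy0, side="right")  # 1..12
    day = doy0 - _MONTH_STARTS[month - 1] + 1
    return pd.to_datetime(
        {"year": year, "month": month, "day": day}
    )


def expected_outbreak_cooling(params: ClimateParams) -> float:
    """Closed-form mean daily cooling (degC) from outbreak pulses.

    Each pulse is ``drop * sin(pi (i + 0.5) / d)`` over d days, so the
    expected total cooling per winter is ``rate * drop * sum(profile)`` and
    the per-day mean divides by 365.  Used both by the generator (to
    de-bias) and by tests (as the generative-model oracle).
    """
    d = params.outbreak_duration_days
    profile_sum = float(np.sum(np.sin(np.pi * (np.arange(d) + 0.5) / d)))
    return params.outbreak_rate * params.outbreak_drop * profile_sum / DAYS_PER_YEAR


def generate_daily_series(
    params: ClimateParams,
    n_years: int,
    seed: int,
    start_year: int = 1978,
) -> pd.DataFrame:
    """Generate ``n_years`` of daily weather as a DataFrame.

    Columns follow the weather CSV layout:
    ``date, tmax_c, tmin_c, precip_mm, rh_pct, wind_ms, solar_mj``.
    Identical ``(params, n_years, seed, start_year)`` give byte-identical
    output.
    """
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    rng = np.random.default_rng(seed)
    n = n_years * DAYS_PER_YEAR
    idx = np.arange(n)
    doy = idx % DAYS_PER_YEAR + 1
    phase = 2.0 * np.pi * (doy - params.coldest_day_of_year) / DAYS_PER_YEAR

    seasonal = params.annual_mean_temp - params.seasonal_amplitude * np.cos(phase)

    # AR(1) anomalies with marginal SD anomaly_sd
    phi = params.anomaly_autocorr
    eps = rng.normal(0.0, params.anomaly_sd * np.sqrt(1.0 - phi**2), n)
    anom = np.empty(n)
    anom[0] = rng.normal(0.0, params.anomaly_sd)
    for i in range(1, n):
        anom[i] = phi * anom[i - 1] + eps[i]

    # Cold outbreaks: Poisson arrivals within each Nov-Mar winter window
    outbreak = np.zeros(n)
    d = params.outbreak_duration_days
    prof = np.sin(np.pi * (np.arange(d) + 0.5) / d)
    # winter season s spans day 304 (Nov 1) of year s to day 89 (Mar 31) of
    # year s+1, in absolute day index
    for s in range(-1, n_years):
        w_lo = s * DAYS_PER_YEAR + 304
        w_hi = s * DAYS_PER_YEAR + 455
        n_events = rng.poisson(params.outbreak_rate)
        for _ in range(n_events):
            start = int(rng.integers(w_lo, w_hi))
            mag = rng.gamma(2.0, params.outbreak_drop / 2.0)
            for j in range(d):
                k = start + j
                if 0 <= k < n:
                    outbreak[k] -= mag * prof[j]

    debias = expected_outbreak_cooling(params)
    years_elapsed = (idx - (n - 1) / 2.0) / DAYS_PER_YEAR  # centred: mean-preserving
    trend = params.trend_per_decade * years_elapsed / 10.0
    tmean = seasonal + anom + outbreak + debias + trend

    # Diurnal range: wider in summer, narrower in winter and on wet days
    wet = rng.random(n) < params.wet_day_prob
    drange = 10.0 + 2.0 * np.cos(phase - np.pi)
    drange = np.where(wet, 0.6 * drange, drange)

    # Precipitation amounts with a seasonal modulation chosen so that the 90
    # days centred on the coldest day carry winter_precip_fraction of the
    # annual total
    a_p = np.clip((1.0 - DAYS_PER_YEAR * params.winter_precip_fraction / 90.0) / 0.967,
                  0.0, 0.95)
    modulation = 1.0 - a_p * np.cos(phase)  # min at coldest day... sign check below
    # cos(phase)=1 at coldest day -> modulation = 1 - a_p there (driest) OK
    amounts = rng.gamma(0.75, 1.0 / 0.75, n) * params.precip_mean * modulation
    precip = np.where(wet, amounts, 0.0)

    rh = np.where(wet, rng.normal(90.0, 5.0, n), rng.normal(68.0, 8.0, n))
    rh = np.clip(rh, 25.0, 100.0)
    wind = rng.weibull(2.0, n) * 4.5
    s_clear = 16.5 - 12.0 * np.cos(phase)
    cloud_factor = np.where(wet, 0.30 + 0.10 * rng.random(n), 0.65 + 0.25 * rng.random(n))
    solar = s_clear * cloud_factor

    return pd.DataFrame(
        {
            "date": _noleap_dates(start_year, n),
            "tmax_c": tmean + drange / 2.0,
            "tmin_c": tmean - drange / 2.0,
            "precip_mm": precip,
            "rh_pct": rh,
            "wind_ms": wind,
            "solar_mj": solar,
        }
    )


# ---------------------------------------------------------------------------
# Hourly disaggregation
# ---------------------------------------------------------------------------


def _solar_geometry(doy: np.ndarray, latitude: float):
    """Sunrise hour and daylength (hours) for each day of year."""
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284 + doy) / 365.0)
    lat = np.radians(latitude)
    cos_h0 = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    h0 = np.arccos(cos_h0)  # half daylength, radians
    daylength = 24.0 * h0 / np.pi
    sunrise = 12.0 - daylength / 2.0
    return sunrise, daylength


def _sat_vapor_pressure_kpa(t: np.ndarray) -> np.ndarray:
    """Magnus saturation vapour pressure over water, kPa."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def disaggregate_series(daily: pd.DataFrame, latitude: float) -> dict[str, np.ndarray]:
    """Disaggregate a full daily series to hourly forcing arrays.

    Returns a dict of ``(n_days * 24,)`` arrays: ``air_temp``, ``precip``
    (mm/h), ``is_snow`` (bool), ``shortwave`` (W m-2), ``longwave_down``
    (W m-2), ``rel_humidity``, ``wind``.  The first/last day use themselves
    as their missing neighbour.  Hourly values are sampled at hour centres;
    the hour containing sunrise reports the exact daily minimum, and values
    are clamped to the day's [tmin, tmax].
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude must be within [-90, 90], got {latitude}")
    n = len(daily)
    dates = pd.DatetimeIndex(daily["date"])
    doy = dates.dayofyear.to_numpy()
    tmax = daily["tmax_c"].to_numpy(float)
    tmin = daily["tmin_c"].to_numpy(float)
    precip = daily["precip_mm"].to_numpy(float)
    rh = daily["rh_pct"].to_numpy(float)
    wind = daily["wind_ms"].to_numpy(float)
    solar = daily["solar_mj"].to_numpy(float)

    tmax_prev = np.concatenate([[tmax[0]], tmax[:-1]])
    tmin_next = np.concatenate([tmin[1:], [tmin[-1]]])

    sunrise, daylength = _solar_geometry(doy, latitude)
    sunrise_next = np.concatenate([sunrise[1:], [sunrise[-1]]])

    hc = (np.arange(24) + 0.5)[None, :]  # hour centres, (1, 24)
    t_sr = sunrise[:, None]
    t_sr_next = sunrise_next[:, None]
    tmx = tmax[:, None]
    tmn = tmin[:, None]
    tmx_prev = tmax_prev[:, None]
    tmn_next = tmin_next[:, None]

    rise = tmn + (tmx - tmn) * 0.5 * (1.0 - np.cos(np.pi * (hc - t_sr) / (PEAK_HOUR - t_sr)))
    after = tmn_next + (tmx - tmn_next) * 0.5 * (
        1.0 + np.cos(np.pi * (hc - PEAK_HOUR) / (24.0 + t_sr_next - PEAK_HOUR))
    )
    before = tmn + (tmx_prev - tmn) * 0.5 * (
        1.0 + np.cos(np.pi * (hc + 24.0 - PEAK_HOUR) / (24.0 + t_sr - PEAK_HOUR))
    )
    temp = np.where(hc < t_sr, before, np.where(hc <= PEAK_HOUR, rise, after))
    # the hour containing sunrise reports the exact minimum
    sr_idx = np.clip(np.floor(sunrise).astype(int), 0, 23)
    temp[np.arange(n), sr_idx] = tmin
    temp = np.clip(temp, tmn, tmx)

    # Shortwave: half-cosine over daylight hours, normalised to the daily total
    w = np.cos(np.pi * (hc - 12.0) / daylength[:, None])
    w = np.where(np.abs(hc - 12.0) < daylength[:, None] / 2.0, np.maximum(w, 0.0), 0.0)
    wsum = w.sum(axis=1, keepdims=True)
    wsum[wsum == 0.0] = 1.0
    w /= wsum
    shortwave = solar[:, None] * 1e6 / 3600.0 * w

    # Precipitation: contiguous wet block, deterministic start hour
    dur = np.clip(1 + np.round(precip / 3.0).astype(int), 1, 10)
    start = (doy * 5) % (24 - dur)
    hour_idx = np.arange(24)[None, :]
    in_block = (hour_idx >= start[:, None]) & (hour_idx < (start + dur)[:, None])
    hprecip = np.where(in_block, (precip / dur)[:, None], 0.0)

    # Longwave down: Brutsaert clear-sky emissivity with a cloud correction
    # tied to the wet-day flag
    ea_hpa = 10.0 * (rh[:, None] / 100.0) * _sat_vapor_pressure_kpa(temp)
    t_k = temp + T0_KELVIN
    eps_clear = 1.24 * (ea_hpa / t_k) ** (1.0 / 7.0)
    cloud = np.where((precip > 0.0)[:, None], 0.8, 0.25)
    eps = np.minimum(1.0, eps_clear * (1.0 + 0.22 * cloud**2))
    longwave = eps * STEFAN_BOLTZMANN * t_k**4

    return {
        "air_temp": temp.ravel(),
        "precip": hprecip.ravel(),
        "is_snow": (temp.ravel() <= SNOW_RAIN_THRESHOLD_C),
        "shortwave": shortwave.ravel(),
        "longwave_down": longwave.ravel(),
        "rel_humidity": np.repeat(rh, 24),
        "wind": np.repeat(wind, 24),
    }


def disaggregate_to_hourly(
    day: DailyWeather | pd.Series,
    prev_day: DailyWeather | pd.Series,
    next_day: DailyWeather | pd.Series,
    latitude: float,
) -> list[HourlyForcing]:
    """Disaggregate one day (with its neighbours for midnight continuity).

    Returns 24 :class:`HourlyForcing` records.  The hourly max/min match the
    day's tmax/tmin, shortwave integrates to the daily solar total, and
    precipitation occupies a contiguous block of hours.
    """
    rows = []
    for d in (prev_day, day, next_day):
        if isinstance(d, DailyWeather):
            rows.append({"date": d.date, "tmax_c": d.tmax, "tmin_c": d.tmin,
                         "precip_mm": d.precip, "rh_pct": d.rel_humidity,
                         "wind_ms": d.wind, "solar_mj": d.solar})
        else:
            rows.append(dict(d))
    frame = pd.DataFrame(rows)
    arrays = disaggregate_series(frame, latitude)
    date = pd.Timestamp(frame.iloc[1]["date"])
    out = []
    for h in range(24):
        i = 24 + h  # middle day
        out.append(
            HourlyForcing(
                timestamp=date + pd.Timedelta(hours=h),
                air_temp=float(arrays["air_temp"][i]),
                precip=float(arrays["precip"][i]),
                precip_phase="snow" if arrays["is_snow"][i] else "rain",
                shortwave=float(arrays["shortwave"][i]),
                longwave_down=float(arrays["longwave_down"][i]),
                rel_humidity=float(arrays["rel_humidity"][i]),
                wind=float(arrays["wind"][i]),
            )
        )
    return out


def make_pseudo_observations(
    sim_extremes: Sequence[float] | np.ndarray,
    bias_poly: tuple[float, float, float],
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Pseudo-observed annual extremes from simulated ones.

    ``obs_i = a sim_i^2 + b sim_i + c + N(0, noise_sd)`` with
    ``bias_poly = (a, b, c)``.  Enables calibration tests of the quadratic
    bias-correction fit without a real station network.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sim = np.asarray(
        [getattr(s, "extreme_min_t10", s) for s in np.atleast_1d(np.asarray(sim_extremes, dtype=object))],
        dtype=float,
    )
    if sim.size == 0:
        return np.empty(0)
    a, b, c = bias_poly
    rng = np.random.default_rng(seed)
    return a * sim**2 + b * sim + c + rng.normal(0.0, noise_sd, sim.size)


# ---------------------------------------------------------------------------
# Weather CSV interface
# ---------------------------------------------------------------------------


def write_weather_csv(daily: pd.DataFrame, path) -> None:
    """Write a daily series in the documented weather CSV layout."""
    out = daily.loc[:, WEATHER_COLUMNS].copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    """Read a daily weather CSV, validating layout and basic invariants."""
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"])
    if (df["tmax_c"] < df["tmin_c"]).any():
        raise ValueError("weather CSV has rows with tmax_c < tmin_c")
    if (df["precip_mm"] < 0).any() or (df["solar_mj"] < 0).any():
        raise ValueError("weather CSV has negative precip or solar")
    return df.loc[:, WEATHER_COLUMNS]
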