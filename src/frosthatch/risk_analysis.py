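"""Risk statistics for rhizome winterkill.

The core statistic is the annual extreme minimum of the 3-day running mean
of daily-mean 10 cm soil temperature, computed per winter year (Jul 1 to
Jun 30, labelled by the ending year, so a single cold season is never
split).  From it: threshold exceedance frequencies at the lethal
temperatures (-3.5 degC and -6.0 degC for different miscanthus genotypes),
residue-thickness response curves with fraction-of-maximum warming,
quadratic bias correction against observations, and linear trend tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class ThresholdSpec:
    """A lethal soil-temperature threshold (degC at 10 cm)."""

    label: str
    value: float


#: 50% rhizome winterkill thresholds for the two genotype groups
DEFAULT_THRESHOLDS = (
    ThresholdSpec("LT50_giganteus", -3.5),
    ThresholdSpec("LT50_sinensis_hybrid", -6.0),
)


@dataclass(frozen=True)
class AnnualExtremeRecord:
    """Per-winter-year extreme minimum of the 3-day running mean 10 cm
    temperature."""

    winter_year_label: int
    extreme_min_t10: float
    date_of_min: pd.Timestamp


@dataclass(frozen=True)
class TrendResult:
    """OLS linear trend of an annual series."""

    slope: float  # degC per decade
    intercept: float
    p_value: float
    significant: bool  # p < 0.05
    total_change: float  # slope x span, degC


@dataclass
class BiasCorrectionModel:
    """Quadratic map from simulated to observed annual extremes,
    obs = a sim^2 + b sim + c."""

    coefficients: tuple[float, float, float]
    r_squared: float
    residual_sd: float
    sim_range: tuple[float, float]
    extrapolation_margin: float = 2.0  # degC beyond the fitted range


def running_mean(series, window: int = 3) -> np.ndarray:
    """Centred running mean; the (window-1)/2 boundary values are NaN.

    The 3-day running mean is deliberately conservative: smoothing damps
    single-day spikes, so its minimum is never below the raw daily minimum.
    """
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    out = np.full(x.size, np.nan)
    half = (window - 1) // 2
    if window == 1:
        return x.copy()
    kernel = np.ones(window) / window
    out[half:x.size - half] = np.convolve(x, kernel, mode="valid")
    return out


def winter_year_labels(dates: pd.DatetimeIndex, split_month: int = 7) -> np.ndarray:
    """Winter-year label (the year containing the ending spring) for each
    date; days from ``split_month`` onward belong to the next label."""
    years = dates.year.to_numpy()
    return np.where(dates.month.to_numpy() >= split_month, years + 1, years)


def annual_extreme_minima(
    daily: pd.DataFrame,
    window: int = 3,
    calendar_years: bool = False,
) -> pd.DataFrame:
    """Per-winter-year extreme minima of the running-mean 10 cm series.

    ``daily`` needs ``date`` and ``t10cm_daily_mean`` columns.  The running
    mean is computed over the continuous series; years are winter years
    (Jul 1 - Jun 30, labelled by the ending year) unless
    ``calendar_years=True``.  Incomplete boundary years (fewer than 365
    days) are dropped.  Returns columns ``winter_year_label``,
    ``extreme_min_t10``, ``date_of_min``.
    """
    if len(daily) == 0:
        return pd.DataFrame(columns=["winter_year_label", "extreme_min_t10", "date_of_min"])
    dates = pd.DatetimeIndex(daily["date"])
    rm = running_mean(daily["t10cm_daily_mean"].to_numpy(float), window)
    labels = dates.year.to_numpy() if calendar_years else winter_year_labels(dates)

    records = []
    frame = pd.DataFrame({"date": dates, "rm": rm, "label": labels})
    for label, grp in frame.groupby("label", sort=True):
        if len(grp) < 365:  # incomplete boundary year
            continue
        valid = grp.dropna(subset=["rm"])
        if valid.empty:
            continue
        i = valid["rm"].idxmin()
        records.append(
            {
                "winter_year_label": int(label),
                "extreme_min_t10": float(valid.loc[i, "rm"]),
                "date_of_min": valid.loc[i, "date"],
            }
        )
    return pd.DataFrame(records, columns=["winter_year_label", "extreme_min_t10", "date_of_min"])


def _extreme_values(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records["extreme_min_t10"].to_numpy(float)
    vals = [getattr(r, "extreme_min_t10", r) for r in records]
    return np.asarray(vals, dtype=float)


def exceedance_frequency(records, threshold) -> float:
    """Fraction of winter years at or below the threshold (ties count)."""
    vals = _extreme_values(records)
    if vals.size == 0:
        raise ValueError("exceedance fraction undefined for empty records")
    t = threshold.value if isinstance(threshold, ThresholdSpec) else float(threshold)
    return float(np.mean(vals <= t))


def response_curve(sweep_result: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Warming vs. bare and fraction-of-maximum warming per thickness.

    ``sweep_result`` maps thickness (cm) to annual-extreme records and must
    include the 0 cm bare reference plus at least two thicknesses.
    ``warming(t) = mean_extreme(t) - mean_extreme(0)``;
    ``fraction_of_max(t) = warming(t) / warming(t_max)``.  If warming at
    the maximum thickness is zero the fractions are undefined (NaN).
    """
    if 0.0 not in sweep_result:
        raise ValueError("sweep must include the 0 cm bare reference")
    thicknesses = sorted(t for t in sweep_result if t > 0)
    if len(thicknesses) < 2:
        raise ValueError("sweep needs at least two non-zero thicknesses")
    base_mean = float(_extreme_values(sweep_result[0.0]).mean())
    rows = []
    t_max = thicknesses[-1]
    warm_max = float(_extreme_values(sweep_result[t_max]).mean()) - base_mean
    for t in thicknesses:
        vals = _extreme_values(sweep_result[t])
        warming = float(vals.mean()) - base_mean
        frac = warming / warm_max if warm_max != 0.0 else np.nan
        rows.append(
            {
                "thickness_cm": t,
                "mean_extreme_min": float(vals.mean()),
                "warming_vs_bare": warming,
                "fraction_of_max": frac,
                "interannual_sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_bias_correction(sim, obs) -> BiasCorrectionModel:
    """Least-squares quadratic regression of observed on simulated annual
    extremes, used to remove the model's cold bias at the coldest sites."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.size != obs.size or sim.size < 4:
        raise ValueError("sim and obs must be equal length >= 4")
    if not (np.isfinite(sim).all() and np.isfinite(obs).all()):
        raise ValueError("sim and obs must be finite")
    if np.ptp(sim) < 1e-12:
        raise ValueError("sim values are degenerate (constant); cannot fit")
    a, b, c = np.polyfit(sim, obs, 2)
    fitted = a * sim**2 + b * sim + c
    resid = obs - fitted
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    sd = float(np.std(resid, ddof=min(3, resid.size - 1)))
    return BiasCorrectionModel(
        coefficients=(float(a), float(b), float(c)),
        r_squared=r2,
        residual_sd=sd,
        sim_range=(float(sim.min()), float(sim.max())),
    )


def apply_bias_correction(model: BiasCorrectionModel, sim) -> np.ndarray:
    """Evaluate the fitted quadratic at simulated values.

    Refuses extrapolation beyond the fitted range by more than the model's
    ``extrapolation_margin``.
    """
    sim = np.asarray(sim, dtype=float)
    lo, hi = model.sim_range
    m = model.extrapolation_margin
    if (sim < lo - m).any() or (sim > hi + m).any():
        raise ValueError(
            f"bias correction fitted on sim in [{lo:.2f}, {hi:.2f}] degC; "
            f"refusing extrapolation beyond +/- {m} degC"
        )
    a, b, c = model.coefficients
    return a * sim**2 + b * sim + c


def linear_trend(annual_values) -> TrendResult:
    """OLS linear trend of an annual series, slope in degC per decade.

    Accepts a mapping/Series indexed by year or a (years, values) pair.
    Significance is a two-sided t-test on the slope at P < 0.05 (no
    autocorrelation correction).
    """
    if isinstance(annual_values, pd.Series):
        years = np.asarray(annual_values.index, dtype=float)
        vals = annual_values.to_numpy(float)
    elif isinstance(annual_values, dict):
        years = np.array(sorted(annual_values), dtype=float)
        vals = np.array([annual_values[int(y)] if int(y) in annual_values
                         else annual_values[y] for y in years], dtype=float)
    else:
        years, vals = annual_values
        years = np.asarray(years, dtype=float)
        vals = np.asarray(vals, dtype=float)
    if years.size < 3:
        raise ValueError("linear trend needs at least 3 years")
    x = sm.add_constant(years)
    fit = sm.OLS(vals, x).fit()
    slope_per_year = float(fit.params[1])
    p = float(fit.pvalues[1])
    span = float(years.max() - years.min())
    return TrendResult(
        slope=slope_per_year * 10.0,
        intercept=float(fit.params[0]),
        p_value=p,
        significant=p < 0.05,
        total_change=slope_per_year * span,
    )


def risk_summary(
    daily: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    window: int = 3,
) -> dict:
    """Per-year extreme records plus exceedance fractions, as a JSON-ready
    dict (schema version 1)."""
    records = annual_extreme_minima(daily, window=window)
    out = {
        "schema_version": 1,
        "n_years": int(len(records)),
        "annual_extremes": [
            {
                "winter_year": int(r.winter_year_label),
                "extreme_min_t10": round(float(r.extreme_min_t10), 4),
                "date_of_min": str(pd.Timestamp(r.date_of_min).date()),
            }
            for r in records.itertuples()
        ],
        "exceedance_fractions": {},
    }
    for t in thresholds:
        spec = t if isinstance(t, ThresholdSpec) else ThresholdSpec(str(t), float(t))
        out["exceedance_fractions"][f"{spec.value:g}C"] = (
            exceedance_frequency(records, spec) if len(records) else None
        )
    return out
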