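"""Apparent temperature and monthly aggregation.

Apparent temperature (AT) is the "feels-like" heat exposure metric combining
maximum air temperature with humidity. The default variant is the dew-point
quadratic widely used in California heat-health work,

    AT = -2.653 + 0.994 * Ta + 0.0153 * Td**2        (degC)

with Ta the daily maximum temperature and Td the dew point; a vapor-pressure
variant ``AT = -1.3 + 0.92 * Ta + 2.2 * e`` (e in kPa) is available behind
the ``variant`` switch. Humidity may arrive as relative humidity (converted
to dew point with the Magnus approximation) or as dew point directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dew_point",
    "saturation_vapor_pressure",
    "apparent_temperature",
    "c_to_f",
    "f_to_c",
    "monthly_means",
    "region_monthly_means",
    "weather_to_at",
]

# Magnus approximation constants over water
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04  # degC


def dew_point(t: float | np.ndarray, rh: float | np.ndarray) -> float | np.ndarray:
    """Dew point (degC) from temperature (degC) and relative humidity (%).

    Magnus form: gamma = a*t/(b+t) + ln(rh/100), Td = b*gamma/(a - gamma).
    At rh = 100 the dew point equals the temperature.
    """
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be in (0, 100]")
    gamma = _MAGNUS_A * t / (_MAGNUS_B + t) + np.log(rh / 100.0)
    td = _MAGNUS_B * gamma / (_MAGNUS_A - gamma)
    return float(td) if td.ndim == 0 else td


def saturation_vapor_pressure(t: float | np.ndarray) -> float | np.ndarray:
    """Saturation vapor pressure (kPa) at temperature t (degC), Magnus form."""
    t = np.asarray(t, dtype=float)
    e = 0.6112 * np.exp(_MAGNUS_A * t / (_MAGNUS_B + t))
    return float(e) if e.ndim == 0 else e


def apparent_temperature(
    t_max: float | np.ndarray,
    td: float | np.ndarray,
    variant: str = "dewpoint",
) -> float | np.ndarray:
    """Apparent temperature (degC) from max temperature and dew point (degC)."""
    t_max = np.asarray(t_max, dtype=float)
    td = np.asarray(td, dtype=float)
    if not (np.all(np.isfinite(t_max)) and np.all(np.isfinite(td))):
        raise ValueError("inputs must be finite")
    if variant == "dewpoint":
        at = -2.653 + 0.994 * t_max + 0.0153 * td**2
    elif variant == "vapor_pressure":
        at = -1.3 + 0.92 * t_max + 2.2 * saturation_vapor_pressure(td)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(at) if at.ndim == 0 else at


def c_to_f(x: float | np.ndarray) -> float | np.ndarray:
    """Exact affine Celsius-to-Fahrenheit conversion."""
    x = np.asarray(x, dtype=float)
    f = 9.0 / 5.0 * x + 32.0
    return float(f) if f.ndim == 0 else f


def f_to_c(x: float | np.ndarray) -> float | np.ndarray:
    x = np.asarray(x, dtype=float)
    c = (x - 32.0) * 5.0 / 9.0
    return float(c) if c.ndim == 0 else c


def weather_to_at(frame: pd.DataFrame, variant: str = "dewpoint") -> pd.DataFrame:
    """Convert a daily weather frame to an apparent-temperature frame.

    Expects columns ``cell_id, date, t_max_c`` and either ``rh_pct`` or
    ``td_c``; returns ``cell_id, date, at_c``. When relative humidity is
    given it is bridged to dew point with the Magnus approximation. Dew
    points more than 0.5 degC above t_max are rejected as physically
    inconsistent.
    """
    cols = set(frame.columns)
    if not {"cell_id", "date", "t_max_c"} <= cols:
        raise ValueError("weather frame needs cell_id, date, t_max_c")
    if "td_c" in cols:
        td = frame["td_c"].to_numpy(dtype=float)
        if np.any(td > frame["t_max_c"].to_numpy(dtype=float) + 0.5):
            raise ValueError("dew point exceeds t_max beyond tolerance")
    elif "rh_pct" in cols:
        td = dew_point(frame["t_max_c"].to_numpy(dtype=float), frame["rh_pct"].to_numpy(dtype=float))
    else:
        raise ValueError("weather frame needs rh_pct or td_c")
    at = apparent_temperature(frame["t_max_c"].to_numpy(dtype=float), td, variant=variant)
    return pd.DataFrame({"cell_id": frame["cell_id"], "date": frame["date"], "at_c": at})


def monthly_means(frame: pd.DataFrame, policy: str = "strict") -> pd.DataFrame:
    """Arithmetic mean of a daily series per (unit, year, month).

    ``frame`` is long-format with columns ``(unit or cell_id), date, at_c``.
    Under the default strict policy, missing values or units observed on
    fewer days than the month's fullest unit raise; the lenient policy takes
    NA-skipping means instead (silent gaps would otherwise bias monthly
    means). Output columns: unit_id, year, month, mean_at_c, mean_at_f with
    mean_at_f = 9/5 * mean_at_c + 32 exactly.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError("policy must be 'strict' or 'lenient'")
    df = frame.rename(columns={"cell_id": "unit_id"}).copy()
    if not {"unit_id", "date", "at_c"} <= set(df.columns):
        raise ValueError("frame needs unit_id/cell_id, date, at_c")
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month

    if policy == "strict":
        if df["at_c"].isna().any():
            raise ValueError("missing apparent-temperature values under strict policy")
        counts = df.groupby(["unit_id", "year", "month"])["at_c"].size()
        per_month = counts.groupby(["year", "month"]).max()
        if (counts != per_month.reindex(counts.index.droplevel("unit_id")).to_numpy()).any():
            raise ValueError("incomplete unit-months under strict policy")

    grouped = (
        df.groupby(["unit_id", "year", "month"])["at_c"]
        .mean()
        .rename("mean_at_c")
        .reset_index()
    )
    if grouped.empty:
        raise ValueError("no observations to aggregate")
    grouped["mean_at_f"] = 9.0 / 5.0 * grouped["mean_at_c"] + 32.0
    return grouped


def region_monthly_means(
    series_frame: pd.DataFrame,
    labels: pd.Series | dict,
    pool_years: bool = True,
) -> pd.DataFrame:
    """Mean monthly apparent temperature per region (degC).

    ``labels`` maps cell_id to region label. Cell-days are averaged within
    each region-month; with ``pool_years`` the two (or more) seasons are
    pooled by calendar month, yielding one value per warm-season month
    (Table-style five columns for May–September), otherwise (year, month)
    pairs are kept separate.
    """
    lab = pd.Series(labels) if isinstance(labels, dict) else labels
    df = series_frame.copy()
    df["region"] = df["cell_id"].map(lab)
    if df["region"].isna().any():
        raise ValueError("every cell needs a region label")
    df["date"] = pd.to_datetime(df["date"])
    df["month"] = df["date"].dt.month
    if pool_years:
        wide = df.groupby(["region", "month"])["at_c"].mean().unstack("month")
    else:
        df["year"] = df["date"].dt.year
        wide = df.groupby(["region", "year", "month"])["at_c"].mean().unstack(["year", "month"])
    wide.index = wide.index.astype(str)
    return wide
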