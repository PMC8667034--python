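"""Growing-season heat-risk climatology from daily weather tables.

The season risk window is defined in days after sowing (defaults 20–60,
both endpoints included). Day risk is a daily maximum temperature strictly
above the day threshold (default 30 °C); night risk is a daily minimum
strictly above the night threshold (default 20 °C). Vapor pressure deficit
follows the FAO-56 daily convention built on the Tetens saturation curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd


class ClimateError(ValueError):
    pass


def saturation_vapor_pressure(T):
    """Tetens saturation vapor pressure (kPa): es(T) = 0.6108·e^(17.27T/(T+237.3))."""
    T = np.asarray(T, dtype=float)
    return 0.6108 * np.exp(17.27 * T / (T + 237.3))


def daily_vpd(tmax, tmin, rh, convention: str = "fao56"):
    """Daily vapor pressure deficit (kPa).

    fao56: mean of saturation pressures at tmax and tmin, times the RH
    deficit; 'tmean': saturation pressure at (tmax+tmin)/2 times the RH
    deficit. Zero exactly when rh = 100.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if convention == "fao56":
        es = (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin)) / 2.0
    elif convention == "tmean":
        es = saturation_vapor_pressure((tmax + tmin) / 2.0)
    else:
        raise ValueError(f"unknown VPD convention {convention!r}")
    return es * (1.0 - rh / 100.0)


def add_vpd(weather: pd.DataFrame, convention: str = "fao56") -> pd.DataFrame:
    out = weather.copy()
    out["vpd"] = daily_vpd(out["tmax"], out["tmin"], out["rh"], convention)
    return out


@dataclass(frozen=True)
class SeasonWindow:
    """Risk window of one growing season, in days after sowing (inclusive)."""

    year: int
    sowing: Date
    start_offset: int = 20
    end_offset: int = 60

    def __post_init__(self):
        if self.start_offset >= self.end_offset:
            raise ClimateError("window start must precede window end")

    @property
    def start(self) -> Date:
        return self.sowing + timedelta(days=self.start_offset)

    @property
    def end(self) -> Date:
        return self.sowing + timedelta(days=self.end_offset)


def window_days(weather: pd.DataFrame, window: SeasonWindow) -> pd.DataFrame:
    """Rows of the weather table inside the window, flagged incomplete when
    the data do not cover the full window."""
    d = weather["date"].dt.date
    sub = weather[(d >= window.start) & (d <= window.end)]
    expected = (window.end - window.start).days + 1
    sub = sub.copy()
    sub.attrs["complete"] = len(sub) == expected
    return sub


def count_threshold_days(days: pd.DataFrame, variable: str,
                         threshold: float, direction: str = "above") -> int:
    """Strict-inequality exceedance count over a window's days."""
    if len(days) == 0:
        raise ClimateError("empty window")
    if variable not in days.columns:
        raise ClimateError(f"no column {variable!r}")
    v = days[variable].to_numpy(dtype=float)
    if direction == "above":
        return int(np.count_nonzero(v > threshold))
    if direction == "below":
        return int(np.count_nonzero(v < threshold))
    raise ValueError("direction must be 'above' or 'below'")


def season_risk_summary(weather: pd.DataFrame, windows: list[SeasonWindow],
                        day_threshold: float = 30.0,
                        night_threshold: float = 20.0,
                        reference_tmax: float = 27.74) -> dict:
    """Per-season exceedance counts and across-season risk fractions.

    For every window: days with tmax > day threshold and days with
    tmin > night threshold. Across seasons: the fraction with at least one
    day/night exceedance. Additionally, per calendar year, the count of
    days whose tmax exceeds ``reference_tmax`` (the join-point construct of
    the thermal-response model applied to the climatology).
    """
    rows = []
    for w in windows:
        days = window_days(weather, w)
        if len(days) == 0:
            rows.append({"year": w.year, "n_days": 0, "day_exceed": np.nan,
                         "night_exceed": np.nan, "complete": False})
            continue
        rows.append({
            "year": w.year,
            "n_days": len(days),
            "day_exceed": count_threshold_days(days, "tmax", day_threshold),
            "night_exceed": count_threshold_days(days, "tmin", night_threshold),
            "complete": days.attrs["complete"],
        })
    per_season = pd.DataFrame(rows)
    valid = per_season.dropna(subset=["day_exceed"])
    n = len(valid)
    frac_day = float((valid["day_exceed"] >= 1).mean()) if n else np.nan
    frac_night = float((valid["night_exceed"] >= 1).mean()) if n else np.nan

    annual = (
        weather.assign(year=weather["date"].dt.year)
        .groupby("year")
        .apply(lambda g: int((g["tmax"] > reference_tmax).sum()),
               include_groups=False)
        .rename("days_above_reference")
        .reset_index()
    )
    return {
        "per_season": per_season,
        "fraction_seasons_day_exceed": frac_day,
        "fraction_seasons_night_exceed": frac_night,
        "annual_days_above_reference": annual,
    }
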