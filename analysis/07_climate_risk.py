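#!/usr/bin/env python
"""Growing-season heat-risk climatology.

For each simulated year: exceedance counts of the 30 °C day and 20 °C
night thresholds inside the 20–60 days-after-sowing window, the
across-season risk fractions, annual counts of days above the 27.74 °C
thermal-response join point, and daily vapor pressure deficit.
"""

from datetime import date as Date
from pathlib import Path

import pandas as pd

from beanheat.climate import SeasonWindow, add_vpd, season_risk_summary
from beanheat.io import read_weather_table, write_results_table

ROOT = Path(__file__).resolve().parents[1] / "results"
SOWING_DOY = 60   # early-March sowing of the main growing season

weather = read_weather_table(ROOT / "data" / "weather.csv")
years = sorted(weather["date"].dt.year.unique())
windows = [SeasonWindow(year=int(y),
                        sowing=Date(int(y), 1, 1) + pd.Timedelta(
                            days=SOWING_DOY - 1).to_pytimedelta())
           for y in years]

risk = season_risk_summary(weather, windows, day_threshold=30.0,
                           night_threshold=20.0, reference_tmax=27.74)
write_results_table(risk["per_season"], ROOT / "season_risk.csv")
write_results_table(risk["annual_days_above_reference"],
                    ROOT / "annual_hot_days.csv")
vpd = add_vpd(weather)
write_results_table(vpd[["date", "vpd"]], ROOT / "daily_vpd.csv")

hot = risk["annual_days_above_reference"]["days_above_reference"]
print(f"{len(years)} seasons, window 20-60 days after sowing:")
print(f"  fraction of seasons with a >30 C day: "
      f"{risk['fraction_seasons_day_exceed']:.2f}; with a >20 C night: "
      f"{risk['fraction_seasons_night_exceed']:.2f}")
print(f"  days/year above the 27.74 C join point: mean {hot.mean():.0f} "
      f"(range {hot.min()}-{hot.max()})")
print(f"  mean daily VPD {vpd['vpd'].mean():.2f} kPa")
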