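"""Noon-to-noon nights: solar events, nightly totals, and bout structure.

Simulates a one-badger deployment, summarizes each night (total ODBA,
active minutes, bout category), and averages weather between sunset and
sunrise for each night.
"""

import numpy as np
import pandas as pd

from odbatools.accelerometry import OdbaSeries, nightly_summary
from odbatools.ephemeris import build_night_windows, solar_events
from odbatools.synthetic import TrueParameters, make_cohort, simulate_hourly_odba

OXFORD = (51.77, -1.33)

sunset, sunrise = solar_events(*OXFORD, "2018-05-02")
print(f"Oxford, 2 May 2018 (UTC): sunset {sunset:%H:%M}, sunrise {sunrise:%H:%M}, "
      f"night {(sunrise - sunset).total_seconds() / 3600:.1f} h")

cohort = make_cohort(n_individuals=1, n_days=8, seed=4)
data, _ = simulate_hourly_odba(cohort, TrueParameters(), seed=5)

# expand hourly ODBA to flat minutes so the night summary can count activity
minutes = data.loc[data.index.repeat(60)].reset_index(drop=True)
minutes["minute_start"] = (pd.to_datetime(minutes["hour_start"])
                           + pd.to_timedelta(np.tile(np.arange(60), len(data)), unit="min"))
minute = pd.DataFrame({"minute_start": minutes["minute_start"],
                       "odba": minutes["hourly_odba"] / 60.0,
                       "n_windows": 30, "complete": True})
hourly = pd.DataFrame({"hour_start": data["hour_start"], "odba": data["hourly_odba"],
                       "n_windows": 1800, "complete": True})
odba = OdbaSeries("B000", window=pd.DataFrame(), minute=minute, hourly=hourly)

nights = build_night_windows(*OXFORD, "2018-05-01", 7)
records = nightly_summary(odba, nights, threshold=0.28, weather=cohort.weather)
print("\nnight        total ODBA  active min  bouts  category      night Temp")
for r in records:
    print(f"{r.night_id}   {r.total_odba:9.1f}  {r.active_minutes:10d}  "
          f"{r.n_bouts:5d}  {r.bout_category:12s}  {r.night_weather['Temp']:6.1f} C")
print("\n(total ODBA sums hourly ODBA noon-to-noon; an unbroken night of "
      "foraging is 'single_bout', a >=1 h rest then renewed activity is 'gap_resumed')")
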