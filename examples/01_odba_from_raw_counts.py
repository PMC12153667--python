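"""From raw tri-axial logger counts to ODBA, activity, and a threshold scan.

Builds ten minutes of synthetic raw accelerometer data (50 Hz, 2^14 counts
per g) around prescribed minute-ODBA values, runs the windowing pipeline,
and classifies activity at the 0.28 g minute-ODBA cut.
"""

import numpy as np

from odbatools.accelerometry import aggregate, compute_window_odba, threshold_sensitivity
from odbatools.synthetic import synthesize_raw_windows

# five quiet minutes, five active ones (well above the 0.28 g cut)
targets = np.array([0.02, 0.03, 0.02, 0.05, 0.04, 0.45, 0.6, 0.5, 0.55, 0.4])
raw = synthesize_raw_windows(targets, sample_rate_hz=50, seed=1)
print(f"raw samples: {len(raw.samples)} rows at 50 Hz "
      f"({raw.samples[['ax', 'ay', 'az']].abs().to_numpy().max()} max |counts|)")

odba = aggregate(compute_window_odba(raw), individual_id="demo")
print("\nminute-averaged ODBA (g) vs the prescribed targets:")
for target, value in zip(targets, odba.minute["odba"]):
    print(f"  target {target:5.2f} -> computed {value:8.5f}")

active = odba.minute["odba"] > 0.28
print(f"\nactive minutes at the 0.28 g cut: {int(active.sum())} of {len(active)}")

scan = threshold_sensitivity(odba.minute, np.linspace(0.02, 0.7, 35))
print(f"threshold scan recommends {scan.recommended:.3f} g "
      "(between-class-variance optimum; the two clusters sit near 0.03 and 0.5)")
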