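"""mRNA-diffusivity battery: D_m in {0, 3e-9, 1e-7, 1e-5} cm^2/s for each
injection timing.

Immobile mRNA (D_m = 0) piles VEGF at the border and delays healing for
every timing; very fast diffusion loses the dose through the border
vasculature and weakens the response toward the vehicle baseline.
"""
from pathlib import Path

import pandas as pd

from woundangio.scenarios import diffusivity_sweep, run_battery, shifts_frame

out = Path("results"); out.mkdir(exist_ok=True)
frames = []
for days, tag in (((0.0,), "day0"), ((3.0,), "day3"), ((6.0,), "day6"),
                  ((0.0, 3.0), "day0+3")):
    battery = run_battery(diffusivity_sweep(days=days))
    df = shifts_frame(battery)
    df.insert(0, "injection_days", tag)
    frames.append(df)
all_df = pd.concat(frames, ignore_index=True)
all_df.to_csv(out / "sweep_diffusivity.csv", index=False)
print(all_df.to_string(index=False))
print(f"wrote {out/'sweep_diffusivity.csv'}")
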