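"""One-at-a-time +/-10% sensitivity of day-18 open wound area.

Run at the pre-calibration parameter column: the three most influential
constants are the ones subsequently fitted to the murine data
(anastomosis lambda0, tip production lambda1, chemotaxis chi).
"""
from pathlib import Path

from woundangio import WoundModelParameters
from woundangio.sensitivity import rank_by_magnitude, sensitivity_scan, to_frame

out = Path("results"); out.mkdir(exist_ok=True)
records = sensitivity_scan(WoundModelParameters.unfitted(), eval_day=18.0)
to_frame(records).to_csv(out / "sensitivity.csv", index=False)
ranking = rank_by_magnitude(records)
print("parameters ranked by |S| (day-18 open area):")
for name in ranking:
    s = max((abs(r.S) for r in records
             if r.parameter == name and r.feasible), default=float("nan"))
    print(f"  {name:10s} |S| = {s:.3f}")
print(f"top 3: {ranking[:3]} -> selected as the free fitting parameters")
print(f"wrote {out/'sensitivity.csv'}")
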