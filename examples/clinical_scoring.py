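"""Score bedside observations and extract a clinical detection time.

Four signs (colour, temperature, recapillarization, turgor) carry fixed
point values; re-exploration is indicated at total >= 9, two 3-point
signs, or persistently abnormal colour with critical recapillarization.
"""

import pandas as pd

from flapmon import clinical_detection_time, score_and_decide

observations = [
    {"color": "pink", "temperature": "body", "recap": "gt_2s", "turgor": "elastic",
     "abnormal_color_duration": 0.0},           # healthy baseline
    {"color": "blue", "temperature": "body", "recap": "lt_1s", "turgor": "elastic",
     "abnormal_color_duration": 75.0},          # venous congestion pattern
    {"color": "pale_white", "temperature": "cold", "recap": "none", "turgor": "soft",
     "abnormal_color_duration": 120.0},         # arterial failure pattern
]
for obs in observations:
    s = score_and_decide(obs)
    print(f"{obs['color']:10s} {obs['recap']:9s} -> points "
          f"({s.color_points},{s.temperature_points},{s.recap_points},{s.turgor_points}) "
          f"total {s.total:2d}  re-explore={s.reexplore}  clauses={sorted(s.triggered_clauses)}")

# a flap deteriorating over the first postoperative day
series = pd.DataFrame([
    {"flap_id": "F1", "timestamp": 6.0, "color": "pink", "temperature": "body",
     "recap": "gt_2s", "turgor": "elastic", "abnormal_color_duration": 0.0},
    {"flap_id": "F1", "timestamp": 18.0, "color": "blue", "temperature": "cold",
     "recap": "lt_1s", "turgor": "plump", "abnormal_color_duration": 90.0},
    {"flap_id": "F1", "timestamp": 30.0, "color": "blue", "temperature": "cold",
     "recap": "none", "turgor": "plump", "abnormal_color_duration": 300.0},
])
t = clinical_detection_time(series)
print(f"\nClinical detection time: {t} h post-inset "
      "(earliest observation meeting a re-exploration criterion)")
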