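"""End-to-end analysis of one synthetic shoulder sequence.

Generates an 8-frame abduction cycle for a supraspinatus-tear (SST)
shoulder, runs the full pipeline (registration, glenoid coordinate system,
head-centre projection, subacromial width, abduction angle) and prints the
per-frame samples, the looseness metrics and the tear classification.
"""

import dataclasses

from glenokin import analyze_sequence, classify_tear, normalize_to_glenoid_percent
from glenokin.synthetic import default_profiles, generate_sequence

profile = dataclasses.replace(default_profiles()["SST"], seed=11)
frames, truth = generate_sequence(profile)

result = analyze_sequence(
    frames, superior_hint=truth.superior_hint, anterior_hint=truth.anterior_hint
)

print("frame  t(s)   x(mm)   y(mm)  WSS(mm)  abduction(deg)   [x%, y%]")
for s in result.samples:
    x_pct, y_pct = normalize_to_glenoid_percent(s.x_mm, s.y_mm, result.glenoid_cs)
    print(
        f"{s.frame_index:>5} {s.time_s:>5.0f} {s.x_mm:>7.2f} {s.y_mm:>7.2f}"
        f" {s.wss_mm:>8.2f} {s.abduction_deg:>15.1f}   [{x_pct:>6.1f}, {y_pct:>6.1f}]"
    )

m = result.metrics
print(f"\nWSS  avg {m.wss_avg:.2f} mm, range {m.wss_range:.2f} mm")
print(f"Y    avg {m.y_avg:.2f} mm, range {m.y_range:.2f} mm")
print(f"X    avg {m.x_avg:.2f} mm, range {m.x_range:.2f} mm")
print(f"classification: {classify_tear(m)}  (WSS range > 4 mm -> tear)")
# The ranges are the 'looseness' of the joint: how much the humeral head
# wobbles on the glenoid over the abduction cycle.  An SST shoulder shows a
# WSS range above 4 mm and a large anterior-posterior (X) range.
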