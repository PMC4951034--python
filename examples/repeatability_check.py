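"""Intra-observer repeatability of the measurement chain.

Re-"reconstructs" one intermediate frame of a normal shoulder six times
with fresh 0.3 mm segmentation noise, registers and measures each repeat,
and reports the spread (max - min) of every kinematic quantity.
"""

from glenokin.pipeline import repeatability_trial

samples, spreads = repeatability_trial(n_repeats=6, noise_sd_mm=0.3, seed=0)

print("repeat   x(mm)   y(mm)  WSS(mm)  abduction(deg)")
for i, s in enumerate(samples):
    print(f"{i:>6} {s.x_mm:>7.2f} {s.y_mm:>7.2f} {s.wss_mm:>8.2f} {s.abduction_deg:>15.2f}")

print("\nextreme-value spreads:")
for key, val in spreads.items():
    unit = "deg" if key.endswith("deg") else "mm"
    print(f"  {key.rsplit('_', 1)[0]:<10} {val:.3f} {unit}")
# Spreads well under 2 mm (and ~a tenth of a degree of abduction) mean the
# looseness ranges of interest (several mm) are safely above measurement
# noise.
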