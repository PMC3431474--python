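"""Organism recovery times for every calibrated model variant.

For each model the time from the start of a 1-d pulse until the dose metric
(scaled damage or scaled internal concentration) falls to 5% of its maximum
is computed on the closed-form decay.  Slow damage recovery (small k_d, the
IT fits) means days of lingering susceptibility; fast recovery (the SD
fits) means the organism is effectively clean within ~1-3 days.
"""

from gutspulse import (
    ITParameters,
    ModelVariant,
    SDParameters,
    TKParameters,
    recovery_time,
)

TK = TKParameters(130.9, 6.9)

# k_d estimates (1/d) by mechanism, dose metric and calibration data
GRID = [
    ("sd", "full", "pulsed", 14.5), ("sd", "full", "acute", 2.7), ("sd", "full", "both", 2.3),
    ("sd", "reduced", "pulsed", 5.1), ("sd", "reduced", "acute", 2.1), ("sd", "reduced", "both", 1.7),
    ("it", "full", "pulsed", 0.6), ("it", "full", "acute", 1.0), ("it", "full", "both", 1.0),
    ("it", "reduced", "pulsed", 0.4), ("it", "reduced", "acute", 0.9), ("it", "reduced", "both", 0.8),
]

print("mechanism  metric   calibration  k_d [1/d]  95% recovery [d]")
for mech, tk_inc, calset, k_d in GRID:
    variant = ModelVariant(mech, tk_inc, TK if tk_inc == "full" else None)
    params = SDParameters(k_d, 1.0, 1.0) if mech == "sd" else ITParameters(k_d, 1.0, 1.0)
    t = recovery_time(variant, params)
    print(f"{mech:>9} {tk_inc:>8} {calset:>12} {k_d:10.1f} {t:17.1f}")

print("\n-> IT-calibrated models imply 4-9 d to recover from one pulse, "
      "SD-calibrated models 1.5-3 d; the gap reflects the mechanisms' "
      "opposite reading of mortality in repeated pulses")
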