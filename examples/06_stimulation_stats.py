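"""Electrical-stimulation outcome statistics.

Counts of fusiform sites whose stimulation distorted face perception,
split by region (posterior fusiform, y < -45, vs mid fusiform) and by
selectivity class, are compared with one-tailed two-proportion z-tests;
the charge delivered per trial is the pulse-width x current x frequency
x duration product.
"""

from ecogface.stim import StimulationParams, charge_per_trial, two_proportion_z_one_tailed

comparisons = [
    ("all stimulated sites  (pFG 9/31 vs mFG 0/21)", 9, 31, 0, 21),
    ("face-selective sites  (pFG 6/17 vs mFG 0/7) ", 6, 17, 0, 7),
    ("non-selective sites   (pFG 3/14 vs mFG 0/14)", 3, 14, 0, 14),
]
for label, k1, n1, k2, n2 in comparisons:
    r = two_proportion_z_one_tailed(k1, n1, k2, n2)
    print(f"{label}: z = {r.z:.3f}, one-tailed p = {r.p_one_tailed:.3f}")

lo = StimulationParams(current_ma=3, frequency_hz=50, pulse_width_ms=0.2, duration_s=1)
hi = StimulationParams(current_ma=8, frequency_hz=50, pulse_width_ms=0.2, duration_s=3)
print(f"\ncharge per trial: {charge_per_trial(lo):.0f}-{charge_per_trial(hi):.0f} uC "
      "over the clinical parameter range")
print("Face-perception distortions arise preferentially from posterior "
      "fusiform stimulation in every comparison.")
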