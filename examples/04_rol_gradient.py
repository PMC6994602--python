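"""Response onset latency (ROL) and its posterior-to-anterior gradient.

Onsets are detected per trial on the unsmoothed, peak-normalized band
power (30 ms bins, 2 ms steps, 25 consecutive supra-threshold bins);
a site's ROL is the median over detected trials.  Sites planted with a
2 ms/mm latency slope along y should show a strong positive Spearman
correlation between ROL and y.
"""

import numpy as np
import pandas as pd

import ecogface as ef
from ecogface import timing

layout = ef.make_layout(30, seed=3)
effects = ef.make_gradient_effects(
    layout, layout.names, categories=("human_face",),
    base_amplitude_db=5.0, base_latency_ms=100.0, latency_slope_ms_per_mm=2.0,
)
bp = ef.simulate_band_power(layout, effects, trials_per_category=8,
                            noise_sd_db=0.5, seed=3)

face_trials = bp.categories == "human_face"
rows = []
for ch, name in enumerate(bp.channel_names):
    est = timing.rol_site(bp.data[face_trials, ch, :], bp.times)
    rows.append({"name": name, "rol_ms": est.median_ms if est.valid else np.nan,
                 "selectivity": 1.0, "y": layout.y_of(name),
                 "detected": est.detection_fraction})
table = pd.DataFrame(rows)
print(table.head(6).round(1).to_string(index=False))

grad = timing.gradient_analysis(table)
print(f"\nSpearman rho(ROL, y) = {grad.rho_rol_y:.2f} (p = {grad.p_rol_y:.2g}, "
      f"n = {grad.n})")
print("region mean ROL:",
      {k: None if np.isnan(v) else round(v) for k, v in grad.region_means.items()})
print("Onsets grow more anterior (less negative y), reproducing the planted "
      "posterior-to-anterior latency gradient.")
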