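"""Classify sites as active / face-selective / human-face-selective.

Permutation tests compare each site's [150, 500) ms response against
its baseline (activity) and pooled faces against pooled non-faces
(selectivity), with Benjamini-Hochberg FDR across sites.
"""

import ecogface as ef

layout = ef.make_layout(12, seed=5)
effects = ef.make_gradient_effects(
    layout, layout.names[:4], categories=ef.FACE_CATEGORIES,
    base_amplitude_db=3.0,
)
# one site responding to every category: active but not selective
effects += [ef.PlantedEffect(site=layout.names[6], categories=ef.CATEGORIES,
                             amplitude_db=3.0)]
bp = ef.simulate_band_power(layout, effects, trials_per_category=10, seed=7)

cls = ef.classify_sites(bp, n_perm_active=5000, n_perm_selective=2000, seed=1)
cols = ["name", "y", "active", "face_selective", "human_face_selective",
        "task_active", "selectivity"]
print(cls.table[cols].round(2).to_string(index=False))
print("\nSites 0-3 carry the planted face response (face-selective); "
      "site 6 responds to everything, so it is task-active only.  An "
      "occasional extra task-active flag on a noise site is the expected "
      "FDR-level false-positive rate across the 11 per-category activity "
      "tests.  The selectivity column is the human-face minus non-face "
      "contrast in dB.")
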