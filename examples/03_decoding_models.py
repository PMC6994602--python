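"""Decoding-relevance models: what happens to face/non-face decoding
when face-selective sites are removed, and where a sparse model puts
its weight.

Model I uses all sites; model II drops the face-selective set; the
random-set ensemble relates accuracy to the proportion of face sites
included; sparse multiple kernel learning (model IV) learns one weight
per site.
"""

import numpy as np

import ecogface as ef
from ecogface import decoding as dec

layout = ef.make_layout(12, seed=5)
face_sites = layout.names[:4]
effects = ef.make_gradient_effects(
    layout, face_sites, categories=ef.FACE_CATEGORIES, base_amplitude_db=1.0,
)
bp = ef.simulate_band_power(layout, effects, trials_per_category=10,
                            noise_sd_db=1.0, seed=7)
task_sites = [s for s in bp.channel_names if s not in face_sites]
cv = dec.CVConfig(inner_folds=0)

m1 = dec.run_site_set_model(bp, bp.channel_names, seed=1, cv=cv, model="I")
m2 = dec.run_site_set_model(bp, task_sites, seed=1, cv=cv, model="II")
print(f"model I  (all sites):        {m1.balanced_accuracy:5.1f}% balanced accuracy")
print(f"model II (face sites ablated): {m2.balanced_accuracy:4.1f}%")

rset = dec.random_set_models(bp, face_sites, task_sites, n_models=99, size=5,
                             seed=2, cv=dec.CVConfig(outer_folds=3, inner_folds=0))
print(f"random sets: rho(accuracy, face proportion) = {rset.rho:.2f} "
      f"(p = {rset.p:.4f}, n = {len(rset.accuracies)})")

rng = np.random.default_rng(3)
idx, labels = dec._face_nonface_epochs(bp, rng)
kernels = {s: dec.linear_kernel(dec.build_features(bp, [s], idx))
           for s in bp.channel_names}
res, cmap = dec.sparse_mkl(kernels, labels, cv=cv, seed=4)
top = np.argsort(cmap.contributions)[::-1][:4]
print(f"model IV: {res.balanced_accuracy:.1f}%, sparsity {cmap.sparsity:.2f}; "
      "top contributions: "
      + ", ".join(f"{cmap.names[i]}={cmap.contributions[i]:.2f}" for i in top))
print("\nAblating face sites drops accuracy toward chance, accuracy grows "
      "with the share of face sites, and the sparse model concentrates its "
      "weight on the planted face sites.")
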