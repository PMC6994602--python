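"""Simulate a raw multichannel ECoG recording and preprocess it to
high-frequency broadband (HFB) power epochs.

Builds a rapid visual-presentation design (300 ms stimuli, 400 ms ISI),
plants 3 dB face-selective high-gamma bursts on three posterior sites,
and runs the full chain: downsample, notch, channel QC, common average
reference, epoching, artifact rejection, Morlet band power.
"""

import numpy as np

import ecogface as ef

design = ef.make_task_design(images_per_category=5, presentations=2, seed=1)
layout = ef.make_layout(10, seed=1)
face_sites = layout.names[:3]
effects = ef.make_gradient_effects(
    layout, face_sites, categories=ef.FACE_CATEGORIES,
    base_amplitude_db=3.0, base_latency_ms=150.0,
)
raw = ef.simulate_raw(design, layout, effects, seed=2)
print(f"simulated {design.n_stimuli} stimuli on {raw.n_channels} channels "
      f"({raw.n_samples / raw.fs:.0f} s at {raw.fs:.0f} Hz)")

bp, qc, epochs = ef.preprocess_raw(raw, design)
print(f"QC rejected {len(qc.bad_channels)} channels; "
      f"{int((~epochs.artifact).sum())}/{epochs.n_trials} epochs clean")

resp = bp.windowed_mean((150.0, 500.0))
face_trials = np.isin(bp.categories, ef.FACE_CATEGORIES)
for name in (face_sites[0], layout.names[-1]):
    ch = bp.channel_names.index(name)
    print(f"  {name}: faces {resp[face_trials, ch].mean():+.2f} dB, "
          f"non-faces {resp[~face_trials, ch].mean():+.2f} dB")
print("The planted site shows an HFB power increase to faces only; the "
      "noise site hovers near 0 dB for both.")
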