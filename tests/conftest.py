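import numpy as np
import pytest

import ecogface as ef


@pytest.fixture(scope="session")
def planted_bp():
    """Band-power scenario: 12 sites, the first 4 face-selective
    (responding to all four face categories), 10 trials per category."""
    layout = ef.make_layout(12, seed=5)
    face_sites = layout.names[:4]
    effects = ef.make_gradient_effects(
        layout, face_sites, categories=ef.FACE_CATEGORIES, base_amplitude_db=3.0,
        base_latency_ms=150.0,
    )
    bp = ef.simulate_band_power(layout, effects, trials_per_category=10, seed=7)
    return bp, face_sites


@pytest.fixture(scope="session")
def weak_planted_bp():
    """Same layout but a weak (0.8 dB) planted effect: single-subset
    accuracy is off-ceiling, so accuracy varies with how many face
    sites a model includes."""
    layout = ef.make_layout(12, seed=5)
    face_sites = layout.names[:4]
    effects = ef.make_gradient_effects(
        layout, face_sites, categories=ef.FACE_CATEGORIES, base_amplitude_db=0.8,
        base_latency_ms=150.0,
    )
    bp = ef.simulate_band_power(
        layout, effects, trials_per_category=10, noise_sd_db=1.0, seed=7
    )
    return bp, face_sites


@pytest.fixture(scope="session")
def raw_scenario():
    """Small raw-voltage scenario pushed through the full preprocessing
    chain: 10 channels, 3 of them face-selective, 110 stimuli."""
    design = ef.make_task_design(5, 2, seed=1)
    layout = ef.make_layout(10, seed=1)
    effects = ef.make_gradient_effects(
        layout, layout.names[:3], categories=ef.FACE_CATEGORIES,
        base_amplitude_db=3.0, base_latency_ms=150.0,
    )
    raw = ef.simulate_raw(design, layout, effects, seed=2)
    bp, qc, epochs = ef.preprocess_raw(raw, design)
    return {"design": design, "layout": layout, "raw": raw, "bp": bp, "qc": qc,
            "epochs": epochs, "face_sites": layout.names[:3]}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
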