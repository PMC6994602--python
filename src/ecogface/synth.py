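"""Synthetic ECoG generation.

Real intracranial recordings of this kind cannot be shared, so every
downstream stage is exercised on synthetic data that reproduces the
statistical structure the analyses rely on: 1/f-like background noise
with optional 60 Hz line contamination, category-selective high-gamma
bursts planted on a subset of sites, graded onset latency and
selectivity along the posterior-anterior (y) axis, and the ramp/SNR
semi-simulation used to validate response-onset detection.

Two levels of realism are provided:

* :func:`simulate_raw` builds a continuous voltage recording that must
  pass through the full preprocessing chain (notch, QC, re-reference,
  epoching, wavelets);
* :func:`simulate_band_power` plants the same effects directly in
  dB-scaled band-power epochs, for fast tests of the statistical stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import ndimage

from .containers import (
    CATEGORIES,
    RESPONSE_BLOCK,
    BandPowerEpochs,
    ElectrodeLayout,
    RawRecording,
    TaskDesign,
)

__all__ = [
    "PlantedEffect",
    "NoiseConfig",
    "SimulationParams",
    "make_task_design",
    "make_layout",
    "make_gradient_effects",
    "simulate_raw",
    "simulate_band_power",
    "inject_ramp",
    "normalize_peak",
    "image_luminance",
    "radial_power_spectrum",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A category-selective high-gamma response planted on one site.

    amplitude_db : plateau band-power increase above baseline, in dB
    latency_ms : response onset latency after stimulus onset
    latency_slope_ms_per_mm / selectivity_slope_db_per_mm : metadata
        recording the gradient a helper used to derive per-site values;
        the simulator itself uses amplitude_db and latency_ms directly.
    """

    site: str
    categories: tuple[str, ...]
    amplitude_db: float = 3.0
    latency_ms: float = 150.0
    latency_slope_ms_per_mm: float = 0.0
    selectivity_slope_db_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_db < 0:
            raise ValueError("amplitude_db must be >= 0")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be >= 0")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")


@dataclass(frozen=True)
class NoiseConfig:
    """Background noise model: AR(1) pink-like noise (spectral slope
    steepening toward -2 as ``ar_coef`` approaches 1) plus an optional
    60 Hz line component."""

    sigma_uv: float = 15.0
    ar_coef: float = 0.97
    line_amp_uv: float = 4.0
    line_freq_hz: float = 60.0


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the ramp-injection semi-simulation.

    The injected ramp rises linearly across ``window_ms`` and plateaus
    afterwards; its terminal amplitude is SNR_in x std over time of the
    trial-averaged reference (condition-B) trace, so the effective
    amplitude of condition-A trials is X_A + SNR_in * std(mean_B).
    """

    snr_grid: tuple[float, ...] = tuple(np.arange(2.0, 10.01, 0.5))
    slope: float = 3.0
    window_ms: tuple[float, float] = (0.0, 500.0)


def make_task_design(
    images_per_category: int,
    presentations: int,
    seed: int,
    *,
    stim_duration_s: float = 0.300,
    isi_s: float = 0.400,
    response_block_every: int = 20,
) -> TaskDesign:
    """Randomized rapid serial presentation design.

    Yields ``11 * images_per_category * presentations`` stimulus events
    (the standard 25 images x 2 presentations gives 550), with a
    response block ("###" catch trial) interleaved after every
    ``response_block_every`` stimuli; response blocks do not count
    toward the stimulus total and are excluded from analysis.
    """
    if images_per_category < 1 or presentations < 1:
        raise ValueError("images_per_category and presentations must be >= 1")
    rng = np.random.default_rng(seed)
    trials = [c for c in CATEGORIES for _ in range(images_per_category * presentations)]
    order = rng.permutation(len(trials))
    sequence = [trials[i] for i in order]
    if response_block_every > 0:
        with_blocks: list[str] = []
        for i, t in enumerate(sequence):
            if i > 0 and i % response_block_every == 0:
                with_blocks.append(RESPONSE_BLOCK)
            with_blocks.append(t)
        sequence = with_blocks
    onset = 1.0  # lead-in so the pre-stimulus window fits in the recording
    rows = []
    for t in sequence:
        rows.append({"onset": onset, "duration": stim_duration_s, "trial_type": t})
        onset += stim_duration_s + isi_s
    return TaskDesign(
        events=pd.DataFrame(rows),
        images_per_category=images_per_category,
        presentations_per_image=presentations,
        stim_duration_s=stim_duration_s,
        isi_s=isi_s,
    )


def make_layout(
    n_sites: int,
    seed: int = 0,
    *,
    y_range: tuple[float, float] = (-70.0, -20.0),
    hemisphere: str = "r",
) -> ElectrodeLayout:
    """Electrode grid spread along the posterior-anterior axis, with
    sites ordered posterior to anterior."""
    rng = np.random.default_rng(seed)
    y = np.linspace(y_range[0], y_range[1], n_sites) + rng.uniform(-1, 1, n_sites)
    y = np.clip(np.sort(y), -90, 40)
    table = pd.DataFrame(
        {
            "name": [f"ch{i:02d}" for i in range(n_sites)],
            "x": rng.uniform(25, 45, n_sites).round(1),
            "y": y.round(2),
            "z": rng.uniform(-25, -10, n_sites).round(1),
            "hemisphere": hemisphere,
        }
    )
    return ElectrodeLayout(table=table)


def make_gradient_effects(
    layout: ElectrodeLayout,
    sites: list[str],
    *,
    categories: tuple[str, ...] = ("human_face",),
    base_amplitude_db: float = 3.0,
    base_latency_ms: float = 150.0,
    latency_slope_ms_per_mm: float = 0.0,
    selectivity_slope_db_per_mm: float = 0.0,
    y_ref: float | None = None,
) -> list[PlantedEffect]:
    """Planted effects whose latency and amplitude vary linearly with
    the site's y coordinate, emulating the posterior-to-anterior
    gradients of onset latency and selectivity."""
    ys = np.array([layout.y_of(s) for s in sites])
    if y_ref is None:
        y_ref = float(ys.min())
    effects = []
    for s, y in zip(sites, ys):
        lat = base_latency_ms + latency_slope_ms_per_mm * (y - y_ref)
        amp = base_amplitude_db + selectivity_slope_db_per_mm * (y - y_ref)
        effects.append(
            PlantedEffect(
                site=s,
                categories=categories,
                amplitude_db=max(amp, 0.0),
                latency_ms=max(lat, 0.0),
                latency_slope_ms_per_mm=latency_slope_ms_per_mm,
                selectivity_slope_db_per_mm=selectivity_slope_db_per_mm,
            )
        )
    return effects


def _ar1_noise(rng: np.random.Generator, n_channels: int, n_samples: int, cfg: NoiseConfig) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    noise = sps.lfilter([1.0], [1.0, -cfg.ar_coef], white, axis=1)
    noise /= noise.std(axis=1, keepdims=True)
    return cfg.sigma_uv * noise


def _hfb_band_rms(noise_row: np.ndarray, fs: float, band=(72.0, 170.0)) -> float:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return float(np.std(sps.sosfiltfilt(sos, noise_row)))


def simulate_raw(
    design: TaskDesign,
    layout: ElectrodeLayout,
    effects: list[PlantedEffect],
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    *,
    fs: float = 1000.0,
    burst_band: tuple[float, float] = (72.0, 170.0),
    burst_duration_ms: float = 350.0,
) -> RawRecording:
    """Continuous voltage recording with planted category-selective
    high-gamma bursts.

    Each planted site carries, for every event of its preferred
    categories, a burst of band-limited noise (carrier inside the
    70-177 Hz high-frequency-broadband range, clear of the notch
    stopbands) starting at the planted latency.  Burst amplitude is
    calibrated against the background's own power in the band so that
    the band-power increase equals ``amplitude_db``.
    """
    known = set(layout.names)
    for e in effects:
        if e.site not in known:
            raise KeyError(f"planted effect on unknown site {e.site!r}")
    rng = np.random.default_rng(seed)
    last = design.events["onset"].iloc[-1] + design.events["duration"].iloc[-1]
    n_samples = int(np.ceil((last + 1.5) * fs))
    sig = _ar1_noise(rng, len(layout.names), n_samples, noise)
    if noise.line_amp_uv > 0:
        t = np.arange(n_samples) / fs
        phases = rng.uniform(0, 2 * np.pi, len(layout.names))
        sig += noise.line_amp_uv * np.sin(
            2 * np.pi * noise.line_freq_hz * t[None, :] + phases[:, None]
        )
    n_burst = int(round(burst_duration_ms / 1000.0 * fs))
    ramp_n = max(int(round(0.05 * fs)), 2)
    envelope = np.ones(n_burst)
    envelope[:ramp_n] = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
    envelope[-ramp_n:] = envelope[:ramp_n][::-1]
    sos = sps.butter(4, burst_band, btype="bandpass", fs=fs, output="sos")
    name_to_idx = {n: i for i, n in enumerate(layout.names)}
    for e in effects:
        ch = name_to_idx[e.site]
        sigma_b = _hfb_band_rms(sig[ch], fs)
        amp = sigma_b * np.sqrt(10 ** (e.amplitude_db / 10.0) - 1.0)
        onsets = design.events.loc[
            design.events["trial_type"].isin(e.categories), "onset"
        ].to_numpy()
        for onset_s in onsets:
            start = int(round((onset_s + e.latency_ms / 1000.0) * fs))
            stop = start + n_burst
            if stop > n_samples:
                continue
            carrier = sps.sosfiltfilt(sos, rng.standard_normal(n_burst + 2 * ramp_n))
            carrier = carrier[ramp_n:-ramp_n]
            carrier /= max(carrier.std(), 1e-12)
            sig[ch, start:stop] += amp * envelope * carrier
    return RawRecording(signal=sig, fs=fs, layout=layout, reference="none")


def simulate_band_power(
    layout: ElectrodeLayout,
    effects: list[PlantedEffect],
    *,
    trials_per_category: int = 10,
    window_ms: tuple[float, float] = (-200.0, 700.0),
    fs: float = 1000.0,
    noise_sd_db: float = 1.0,
    noise_smooth_ms: float = 20.0,
    response_end_ms: float = 500.0,
    rise_ms: float = 50.0,
    seed: int = 0,
) -> BandPowerEpochs:
    """Band-power epochs (dB) with planted responses, skipping the
    voltage-level simulation.

    Background is temporally smoothed Gaussian noise of standard
    deviation ``noise_sd_db`` centred on 0 dB.  Planted sites gain, on
    trials of their preferred categories, a plateau of ``amplitude_db``
    rising over ``rise_ms`` from the planted latency and decaying after
    ``response_end_ms``.
    """
    known = set(layout.names)
    for e in effects:
        if e.site not in known:
            raise KeyError(f"planted effect on unknown site {e.site!r}")
    rng = np.random.default_rng(seed)
    step = 1000.0 / fs
    times = np.arange(window_ms[0], window_ms[1], step)
    n_t = len(times)
    cats = np.repeat(CATEGORIES, trials_per_category)
    cats = cats[rng.permutation(len(cats))]
    n_trials, n_ch = len(cats), len(layout.names)
    noise = rng.standard_normal((n_trials, n_ch, n_t))
    sigma_samp = noise_smooth_ms / step / 2.355
    noise = ndimage.gaussian_filter1d(noise, sigma_samp, axis=2, mode="reflect")
    noise *= noise_sd_db / noise.std()
    data = noise
    name_to_idx = {n: i for i, n in enumerate(layout.names)}
    for e in effects:
        ch = name_to_idx[e.site]
        shape = np.zeros(n_t)
        rise = (times - e.latency_ms) / max(rise_ms, step)
        shape = np.clip(rise, 0.0, 1.0)
        fall = 1.0 - np.clip((times - response_end_ms) / max(rise_ms, step), 0.0, 1.0)
        shape = shape * fall
        mask = np.isin(cats, e.categories)
        data[mask, ch, :] += e.amplitude_db * shape[None, :]
    return BandPowerEpochs(
        data=data,
        times=times,
        categories=cats,
        channel_names=layout.names,
        fs=fs,
        band="HFB",
        layout=layout,
    )


def inject_ramp(
    a_trials: np.ndarray,
    b_trials: np.ndarray,
    times: np.ndarray,
    snr_in: float,
    *,
    slope: float = 3.0,
    window_ms: tuple[float, float] = (0.0, 500.0),
    plateau: bool = True,
) -> np.ndarray:
    """Inject a calibrated linear ramp into condition-A trials.

    The ramp rises from 0 at the window start to its terminal amplitude
    at the window end (then holds if ``plateau``).  The terminal
    amplitude is ``snr_in * std(mean_B)`` with the standard deviation
    taken over time of the trial-averaged condition-B trace, so the
    effective amplitude of A trials satisfies
    ``X_A_eff = X_A + SNR_in * std(mean_B)``.  ``slope`` sets the
    pre-calibration rise (amplitude units per window) and cancels for a
    purely linear ramp; it is kept so alternative ramp shapes can be
    calibrated consistently.  B trials are never modified.
    """
    a = np.asarray(a_trials, dtype=float)
    b = np.asarray(b_trials, dtype=float)
    if b.ndim != 2 or b.shape[0] == 0:
        raise ValueError("reference (condition B) trial set is empty")
    if a.shape[-1] != b.shape[-1] or a.shape[-1] != len(times):
        raise ValueError("condition A and B trials must share the time axis")
    w0, w1 = window_ms
    if w0 < times[0] or w1 > times[-1] + (times[1] - times[0]):
        raise ValueError("ramp window must lie inside the epoch")
    std_b = float(np.std(b.mean(axis=0)))
    terminal = snr_in * std_b
    frac = np.clip((times - w0) / (w1 - w0), 0.0, 1.0 if plateau else np.inf)
    frac[times < w0] = 0.0
    if not plateau:
        frac[times >= w1] = 0.0
    shape = slope * frac
    scale = terminal / slope if slope != 0 else 0.0
    return a + scale * shape[None, :]


def normalize_peak(
    trials: np.ndarray,
    times: np.ndarray | None = None,
    *,
    peak_window_ms: tuple[float, float] = (0.0, 600.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each trial to unit maximum (peak searched post-onset).

    Returns (normalized trials, valid mask); trials whose peak is not
    strictly positive cannot be normalized and are flagged invalid
    (returned unchanged).
    """
    x = np.asarray(trials, dtype=float)
    if times is not None:
        mask = (np.asarray(times) >= peak_window_ms[0]) & (
            np.asarray(times) < peak_window_ms[1]
        )
        if not mask.any():
            raise ValueError("peak window does not overlap the time axis")
        peaks = x[:, mask].max(axis=1)
    else:
        peaks = x.max(axis=1)
    valid = peaks > 0
    out = x.copy()
    out[valid] = x[valid] / peaks[valid, None]
    return out, valid


def image_luminance(image: np.ndarray) -> float:
    """Mean pixel luminance of a stimulus image."""
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    return float(img.mean())


def radial_power_spectrum(image: np.ndarray) -> np.ndarray:
    """Rotationally averaged spatial-frequency power spectrum.

    Computes the 2-D FFT power spectrum and averages it over annuli of
    one frequency-bin width around the DC bin; index k of the returned
    profile is the mean power at radial frequency k.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    power = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
    ny, nx = power.shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.ogrid[:ny, :nx]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    r_idx = np.round(r).astype(int)
    n_bins = min(cy, cx) + 1
    profile = np.array(
        [power[r_idx == k].mean() for k in range(n_bins)]
    )
    return profile
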