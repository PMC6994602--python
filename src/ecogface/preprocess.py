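"""Raw-to-band-power preprocessing chain.

The chain converts a continuous voltage recording into artifact-screened,
log-rescaled band-power epochs, in this order: downsample to 1 kHz,
notch-filter line noise and harmonics (57-63, 117-123, 177-183 Hz),
automatic bad-channel detection (variance and "jump" rules), common
average re-reference over the retained channels, epoching to
[-200, 700) ms with baseline correction, amplitude-based epoch
rejection (>100 μV), Morlet wavelet decomposition, per-frequency
log-power rescaling to the [-100, 0) ms baseline, averaging across the
band's frequency bins, and 50 ms Gaussian temporal smoothing.

Stage order matters (QC before re-referencing, rescaling before band
averaging); :func:`preprocess_raw` applies the full chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import signal as sps

from .containers import BandPowerEpochs, Epochs, RawRecording, TaskDesign

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "STANDARD_BANDS",
    "QCReport",
    "notch_filter",
    "resample",
    "detect_bad_channels",
    "rereference_common_average",
    "epoch_and_baseline",
    "reject_artifact_epochs",
    "band_power",
    "reject_high_z_epochs",
    "preprocess_raw",
    "DEFAULT_STOPBANDS",
]

DEFAULT_STOPBANDS: tuple[tuple[float, float], ...] = (
    (57.0, 63.0),
    (117.0, 123.0),
    (177.0, 183.0),
)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band analysed with a fixed-cycle Morlet wavelet.

    Seven cycles are used at and above 70 Hz, five below; frequency step
    1 Hz; frequencies inside the notch stopbands are skipped.
    """

    name: str
    fmin: float
    fmax: float
    freq_step: float = 1.0
    excluded: tuple[tuple[float, float], ...] = DEFAULT_STOPBANDS

    @property
    def n_cycles(self) -> int:
        return 7 if self.fmin >= 70 else 5

    @property
    def freqs(self) -> np.ndarray:
        f = np.arange(self.fmin, self.fmax + 0.5 * self.freq_step, self.freq_step)
        keep = np.ones(len(f), dtype=bool)
        for lo, hi in self.excluded:
            keep &= ~((f >= lo) & (f <= hi))
        return f[keep]


STANDARD_BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 4, 7),
    "alpha": BandSpec("alpha", 8, 12),
    "beta1": BandSpec("beta1", 13, 29),
    "beta2": BandSpec("beta2", 30, 39),
    "gamma": BandSpec("gamma", 40, 69),
    "HFB": BandSpec("HFB", 70, 177),
}


@dataclass
class QCReport:
    """Per-channel quality metrics and rejection decisions."""

    table: pd.DataFrame  # columns: name, variance, jumps, rejected, reason

    @property
    def good_channels(self) -> list[str]:
        return list(self.table.loc[~self.table["rejected"], "name"])

    @property
    def bad_channels(self) -> list[str]:
        return list(self.table.loc[self.table["rejected"], "name"])

    def to_json(self) -> str:
        return self.table.to_json(orient="records")


def notch_filter(
    raw: RawRecording,
    stopbands: tuple[tuple[float, float], ...] = DEFAULT_STOPBANDS,
    *,
    order: int = 4,
) -> RawRecording:
    """Zero-phase Butterworth band-stop at the line frequency and
    harmonics; stopbands above Nyquist are rejected."""
    nyq = raw.fs / 2.0
    sig = raw.signal
    for lo, hi in stopbands:
        if hi >= nyq:
            raise ValueError(f"stopband {lo}-{hi} Hz at or above Nyquist ({nyq} Hz)")
        sos = sps.butter(order, (lo, hi), btype="bandstop", fs=raw.fs, output="sos")
        sig = sps.sosfiltfilt(sos, sig, axis=1)
    return RawRecording(signal=sig, fs=raw.fs, layout=raw.layout, reference=raw.reference)


def resample(raw: RawRecording, fs_target: float = 1000.0) -> RawRecording:
    """Anti-aliased downsampling (polyphase when the rate ratio is a
    small rational, Fourier method otherwise); duration preserved to
    within one sample.  Upsampling is refused."""
    if fs_target > raw.fs:
        raise ValueError("resample only downsamples (fs_target > fs requested)")
    if fs_target == raw.fs:
        return raw
    from fractions import Fraction

    frac = Fraction(fs_target / raw.fs).limit_denominator(1000)
    n_out = int(round(raw.n_samples * fs_target / raw.fs))
    if abs(float(frac) - fs_target / raw.fs) < 1e-12:
        sig = sps.resample_poly(raw.signal, frac.numerator, frac.denominator, axis=1)
        sig = sig[:, :n_out]
    else:
        sig = sps.resample(raw.signal, n_out, axis=1)
    return RawRecording(signal=sig, fs=fs_target, layout=raw.layout, reference=raw.reference)


def detect_bad_channels(
    raw: RawRecording,
    *,
    variance_factor: float = 5.0,
    jump_factor: float = 3.0,
    jump_threshold_uv: float = 100.0,
) -> QCReport:
    """Flag pathological channels.

    A channel is rejected if its variance exceeds ``variance_factor``
    times (or falls below 1/``variance_factor`` of) the across-channel
    mean variance, or if its count of "jumps" (samples where the first
    difference exceeds ``jump_threshold_uv``) exceeds ``jump_factor``
    times the across-channel mean count.
    """
    if raw.n_channels < 2:
        raise ValueError("need at least 2 channels to assess quality")
    var = raw.signal.var(axis=1)
    jumps = (np.abs(np.diff(raw.signal, axis=1)) > jump_threshold_uv).sum(axis=1)
    mean_var = var.mean()
    mean_jumps = jumps.mean()
    rows = []
    for name, v, j in zip(raw.channel_names, var, jumps):
        reason = ""
        if v > variance_factor * mean_var:
            reason = "variance_high"
        elif mean_var > 0 and v < mean_var / variance_factor:
            reason = "variance_low"
        elif j > jump_factor * mean_jumps:
            reason = "spiky"
        rows.append(
            {
                "name": name,
                "variance": float(v),
                "jumps": int(j),
                "rejected": bool(reason),
                "reason": reason,
            }
        )
    return QCReport(table=pd.DataFrame(rows))


def rereference_common_average(raw: RawRecording, good_channels: list[str]) -> RawRecording:
    """Common average reference: subtract, at every sample, the mean
    over the retained (good) channels.  Bad channels do not enter the
    average but are re-referenced too."""
    if not good_channels:
        raise ValueError("no good channels to build the common average")
    idx = [raw.channel_names.index(n) for n in good_channels]
    if len(idx) < 2:
        raise ValueError("need at least 2 good channels for a common average")
    avg = raw.signal[idx].mean(axis=0, keepdims=True)
    return RawRecording(
        signal=raw.signal - avg, fs=raw.fs, layout=raw.layout, reference="common_average"
    )


def epoch_and_baseline(
    raw: RawRecording,
    design: TaskDesign,
    *,
    window_ms: tuple[float, float] = (-200.0, 700.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    include_response_blocks: bool = False,
) -> Epochs:
    """Extract per-event epochs and subtract the per-trial baseline mean.

    Windows are half-open [start, end) at sample resolution; time 0 is
    the stimulus onset sample.  Events whose window falls outside the
    recording are dropped with a log entry.
    """
    events = design.events if include_response_blocks else design.stimulus_events
    n_w = int(round((window_ms[1] - window_ms[0]) / 1000.0 * raw.fs))
    off0 = int(round(window_ms[0] / 1000.0 * raw.fs))
    times = window_ms[0] + np.arange(n_w) * 1000.0 / raw.fs
    data, cats = [], []
    n_dropped = 0
    for _, ev in events.iterrows():
        start = int(round(ev["onset"] * raw.fs)) + off0
        stop = start + n_w
        if start < 0 or stop > raw.n_samples:
            n_dropped += 1
            logger.warning(
                "dropping event at %.3f s (%s): window outside recording",
                ev["onset"],
                ev["trial_type"],
            )
            continue
        data.append(raw.signal[:, start:stop])
        cats.append(ev["trial_type"])
    if not data:
        raise ValueError("no events fall inside the recording")
    arr = np.stack(data, axis=0)
    bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    arr = arr - arr[:, :, bmask].mean(axis=2, keepdims=True)
    if n_dropped:
        logger.info("dropped %d events at the recording edge", n_dropped)
    return Epochs(
        data=arr,
        times=times,
        categories=np.array(cats),
        channel_names=raw.channel_names,
        fs=raw.fs,
        layout=raw.layout,
    )


def reject_artifact_epochs(epochs: Epochs, amplitude_threshold_uv: float = 100.0) -> Epochs:
    """Flag trials containing voltage spikes above the threshold on any
    channel; flagged trials are excluded from downstream analysis."""
    if amplitude_threshold_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    flags = (np.abs(epochs.data) > amplitude_threshold_uv).any(axis=(1, 2))
    if flags.any():
        logger.info("flagged %d / %d epochs as artifacts", int(flags.sum()), epochs.n_trials)
    return Epochs(
        data=epochs.data,
        times=epochs.times,
        categories=epochs.categories,
        channel_names=epochs.channel_names,
        fs=epochs.fs,
        layout=epochs.layout,
        artifact=flags,
    )


def _morlet_wavelet(freq: float, n_cycles: int, fs: float, max_len: int) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated to ±5σ or the
    signal length, whichever is shorter."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(min(round(5 * sigma_t * fs), (max_len - 1) // 2))
    t = np.arange(-half, half + 1) / fs
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    wav /= np.sqrt(0.5) * np.linalg.norm(wav)
    return wav


def _band_rescaled_db(
    data: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    n_cycles: int,
    baseline_mask: np.ndarray,
) -> np.ndarray:
    """Band-averaged log-rescaled Morlet power, (trials, channels,
    times).

    Per frequency, power (squared wavelet-coefficient magnitude, FFT
    convolution with 'same' alignment) is converted to dB and rescaled
    by its per-trial/channel baseline mean, then averaged across the
    band's frequencies.  The signal FFT is computed once and reused;
    per-frequency planes are accumulated rather than stored.
    """
    from scipy.fft import fft, ifft, next_fast_len

    n_tr, n_ch, n_t = data.shape
    flat = data.reshape(n_tr * n_ch, n_t)
    wavelets = [_morlet_wavelet(float(f), n_cycles, fs, n_t) for f in freqs]
    max_half = max((len(w) - 1) // 2 for w in wavelets)
    n_fft = next_fast_len(n_t + 2 * max_half)
    data_f = fft(flat, n_fft, axis=1)
    acc = np.zeros((n_tr * n_ch, n_t))
    for wav in wavelets:
        half = (len(wav) - 1) // 2
        coef = ifft(data_f * fft(wav, n_fft), axis=1)[:, half : half + n_t]
        db = 10.0 * np.log10(np.maximum(np.abs(coef) ** 2, 1e-300))
        db -= db[:, baseline_mask].mean(axis=1, keepdims=True)
        acc += db
    acc /= len(wavelets)
    return acc.reshape(n_tr, n_ch, n_t)


def band_power(
    epochs: Epochs,
    band: BandSpec,
    *,
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    smooth_ms: float = 50.0,
) -> BandPowerEpochs:
    """Morlet-wavelet band power, log-rescaled and smoothed.

    Per frequency bin, power is the squared wavelet-coefficient
    magnitude converted to dB and rescaled by subtracting the mean dB
    over the baseline window (per trial, channel and frequency) — so the
    baseline-window mean is exactly 0 dB before smoothing.  Power is
    then averaged across the band's bins and smoothed in time with a
    Gaussian window of ``smooth_ms`` full width at half maximum
    (reflection at the edges).  Artifact-flagged trials are excluded.
    """
    freqs = band.freqs
    if len(freqs) == 0:
        raise ValueError(f"band {band.name} has no analysable frequencies")
    if freqs[-1] >= epochs.fs / 2:
        raise ValueError("band extends beyond Nyquist")
    clean = epochs.clean()
    bmask = (clean.times >= baseline_ms[0]) & (clean.times < baseline_ms[1])
    if not bmask.any():
        raise ValueError("baseline window does not overlap the epoch")
    band_db = _band_rescaled_db(clean.data, clean.fs, freqs, band.n_cycles, bmask)
    if smooth_ms > 0:
        sigma = smooth_ms / 2.355 / 1000.0 * clean.fs
        band_db = ndimage.gaussian_filter1d(band_db, sigma, axis=2, mode="reflect")
    return BandPowerEpochs(
        data=band_db,
        times=clean.times,
        categories=clean.categories,
        channel_names=clean.channel_names,
        fs=clean.fs,
        band=band.name,
        baseline_window=baseline_ms,
        smoothing_ms=smooth_ms,
        layout=clean.layout,
    )


def reject_high_z_epochs(bp: BandPowerEpochs, z_threshold: float = 8.0) -> np.ndarray:
    """Optional post-rescale rejection: boolean mask of trials whose
    band power z-score (relative to the across-trial distribution at
    each channel/time) exceeds the threshold anywhere.  Off by default
    in the main chain; used by the ramp semi-simulation path."""
    mu = bp.data.mean(axis=0, keepdims=True)
    sd = bp.data.std(axis=0, keepdims=True)
    z = np.abs(bp.data - mu) / np.maximum(sd, 1e-12)
    return (z > z_threshold).any(axis=(1, 2))


def preprocess_raw(
    raw: RawRecording,
    design: TaskDesign,
    *,
    fs_target: float = 1000.0,
    stopbands: tuple[tuple[float, float], ...] = DEFAULT_STOPBANDS,
    window_ms: tuple[float, float] = (-200.0, 700.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    power_baseline_ms: tuple[float, float] = (-100.0, 0.0),
    band: BandSpec = STANDARD_BANDS["HFB"],
    amplitude_threshold_uv: float = 100.0,
    smooth_ms: float = 50.0,
) -> tuple[BandPowerEpochs, QCReport, Epochs]:
    """Full chain in the canonical order: downsample, notch, channel QC,
    common-average re-reference, epoch + baseline, artifact rejection,
    wavelet band power.  Returns (band power, QC report, voltage
    epochs); bad channels are dropped from the epochs.
    """
    raw = resample(raw, fs_target)
    raw = notch_filter(raw, stopbands)
    qc = detect_bad_channels(raw)
    raw = rereference_common_average(raw, qc.good_channels)
    epochs = epoch_and_baseline(
        raw, design, window_ms=window_ms, baseline_ms=baseline_ms
    )
    good_idx = [epochs.channel_names.index(n) for n in qc.good_channels]
    layout = None
    if epochs.layout is not None:
        from .containers import ElectrodeLayout

        layout = ElectrodeLayout(
            table=epochs.layout.table[
                epochs.layout.table["name"].isin(qc.good_channels)
            ].reset_index(drop=True)
        )
    epochs = Epochs(
        data=epochs.data[:, good_idx, :],
        times=epochs.times,
        categories=epochs.categories,
        channel_names=list(qc.good_channels),
        fs=epochs.fs,
        layout=layout,
    )
    epochs = reject_artifact_epochs(epochs, amplitude_threshold_uv)
    bp = band_power(epochs, band, baseline_ms=power_baseline_ms, smooth_ms=smooth_ms)
    return bp, qc, epochs
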