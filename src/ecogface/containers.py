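"""Core data containers shared across the pipeline.

The analysis operates on multichannel intracranial voltage recordings
(electrocorticography, ECoG) acquired while a subject viewed images from
11 visual categories.  Containers here carry the raw signal, the task
design, the electrode geometry (MNI coordinates; more negative y = more
posterior), voltage epochs, and log-rescaled band-power epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 11 stimulus categories (25 images each, presented twice in the
#: standard design).  Response blocks ("###" catch trials) are a 12th
#: event type excluded from all analyses.
CATEGORIES: tuple[str, ...] = (
    "human_face",
    "mammal_face",
    "bird_face",
    "marine_face",
    "human_body",
    "mammal_body",
    "bird_body",
    "marine_body",
    "limbs",
    "objects",
    "places",
)
RESPONSE_BLOCK = "response_block"
FACE_CATEGORIES: tuple[str, ...] = CATEGORIES[:4]
NONFACE_CATEGORIES: tuple[str, ...] = CATEGORIES[4:]


@dataclass
class TaskDesign:
    """Event table of one experimental run.

    ``events`` has columns onset (s), duration (s), trial_type; onsets
    strictly increasing.  Serializes to a BIDS-style events TSV.
    """

    events: pd.DataFrame
    images_per_category: int
    presentations_per_image: int
    stim_duration_s: float = 0.300
    isi_s: float = 0.400

    def __post_init__(self) -> None:
        required = {"onset", "duration", "trial_type"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"events table must have columns {sorted(required)}")
        onsets = self.events["onset"].to_numpy()
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def stimulus_events(self) -> pd.DataFrame:
        """Events excluding response blocks."""
        return self.events[self.events["trial_type"] != RESPONSE_BLOCK]

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_events)

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "TaskDesign":
        events = pd.read_csv(path, sep="\t")
        counts = events[events["trial_type"] != RESPONSE_BLOCK]["trial_type"].value_counts()
        n_per = int(counts.iloc[0]) if len(counts) else 0
        kwargs.setdefault("images_per_category", n_per)
        kwargs.setdefault("presentations_per_image", 1)
        return cls(events=events, **kwargs)


@dataclass
class ElectrodeLayout:
    """Electrode positions in MNI space (mm); y axis runs posterior (−)
    to anterior (+)."""

    table: pd.DataFrame  # columns: name, x, y, z, hemisphere

    def __post_init__(self) -> None:
        required = {"name", "x", "y", "z", "hemisphere"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"layout table must have columns {sorted(required)}")
        if self.table["name"].duplicated().any():
            raise ValueError("electrode labels must be unique")
        y = self.table["y"].to_numpy(float)
        if np.any((y < -90) | (y > 40)):
            raise ValueError("y coordinates outside the plausible [-90, 40] mm range")
        self.table = self.table.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(float)

    def y_of(self, name: str) -> float:
        row = self.table[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"unknown electrode {name!r}")
        return float(row["y"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeLayout":
        return cls(table=pd.read_csv(path, sep="\t"))


@dataclass
class RawRecording:
    """Continuous multichannel voltage recording.

    signal : (n_channels, n_samples) array, μV
    fs : sampling rate, Hz
    """

    signal: np.ndarray
    fs: float
    layout: ElectrodeLayout
    reference: str = "none"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.signal.shape[0] != len(self.layout.names):
            raise ValueError("channel count does not match layout")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return self.layout.names


@dataclass
class Epochs:
    """Voltage epochs around stimulus onsets.

    data : (n_trials, n_channels, n_times) array, μV
    times : ms relative to stimulus onset (half-open window [start, end))
    """

    data: np.ndarray
    times: np.ndarray
    categories: np.ndarray
    channel_names: list[str]
    fs: float
    layout: ElectrodeLayout | None = None
    artifact: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.categories = np.asarray(self.categories)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x times)")
        if self.artifact is None:
            self.artifact = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def clean(self) -> "Epochs":
        """Epochs with artifact trials removed."""
        keep = ~self.artifact
        return Epochs(
            data=self.data[keep],
            times=self.times,
            categories=self.categories[keep],
            channel_names=self.channel_names,
            fs=self.fs,
            layout=self.layout,
            artifact=np.zeros(int(keep.sum()), dtype=bool),
        )

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask for the half-open time window [start, end) in ms."""
        return (self.times >= window[0]) & (self.times < window[1])


@dataclass
class BandPowerEpochs:
    """Log-rescaled band power epochs (dB relative to per-trial baseline).

    data : (n_trials, n_channels, n_times) array, dB
    """

    data: np.ndarray
    times: np.ndarray
    categories: np.ndarray
    channel_names: list[str]
    fs: float
    band: str = "HFB"
    baseline_window: tuple[float, float] = (-100.0, 0.0)
    smoothing_ms: float = 50.0
    layout: ElectrodeLayout | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.categories = np.asarray(self.categories)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x times)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.times >= window[0]) & (self.times < window[1])

    def windowed_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Mean dB in the half-open window, per trial and channel:
        (n_trials, n_channels)."""
        return self.data[:, :, self.time_mask(window)].mean(axis=2)

    def select_channels(self, names) -> "BandPowerEpochs":
        idx = [self.channel_names.index(n) for n in names]
        return BandPowerEpochs(
            data=self.data[:, idx, :],
            times=self.times,
            categories=self.categories,
            channel_names=list(names),
            fs=self.fs,
            band=self.band,
            baseline_window=self.baseline_window,
            smoothing_ms=self.smoothing_ms,
            layout=self.layout,
        )
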