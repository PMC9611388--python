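"""Carrier objects for the pipeline: continuous recordings and epoch sets.

All potentials are in microvolts (µV), channel-major ``(n_channels, n_times)``
for continuous data and ``(n_epochs, n_channels, n_times)`` for epoched data.
Event onsets are sample indices into the continuous recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Event", "ContinuousRecording", "EpochSet", "BandSpec", "DEFAULT_BANDS"]


@dataclass(frozen=True)
class Event:
    sample: int
    condition: str
    session: str = "S1"


@dataclass
class ContinuousRecording:
    """Multichannel EEG with stimulus-onset events."""

    samples: np.ndarray          # (n_channels, n_times), µV
    sampling_rate: float         # Hz
    channel_names: list[str]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_channels, n_times)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        n = self.samples.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event at sample {ev.sample} outside recording of {n} samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "ContinuousRecording":
        return replace(self, samples=samples)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValueError(f"channel {name!r} not in recording") from None

    def get_channels(self, names: list[str]) -> np.ndarray:
        return self.samples[[self.channel_index(n) for n in names]]


@dataclass
class EpochSet:
    """Stimulus-locked epochs with a pre-stimulus baseline.

    ``times`` is seconds relative to stimulus onset; with the default epoch
    window the first sample sits at −0.200 s and t = 0 is always on the grid.
    ``rejection_log`` records every epoch ever cut from the set (kept +
    dropped = the original count).
    """

    data: np.ndarray             # (n_epochs, n_channels, n_times), µV
    times: np.ndarray            # seconds relative to onset
    sampling_rate: float
    channel_names: list[str]
    conditions: list[str]        # per epoch
    sessions: list[str] = field(default_factory=list)
    baseline_window: tuple[float, float] = (-0.2, 0.0)
    rejection_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["epoch", "condition", "kept", "reason"]
        )
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match times")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("epoch axis does not match condition labels")
        if not self.sessions:
            self.sessions = ["S1"] * self.data.shape[0]
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValueError(f"channel {name!r} not in epochs") from None

    def get_channel(self, name: str) -> np.ndarray:
        """(n_epochs, n_times) view of one channel."""
        return self.data[:, self.channel_index(name), :]

    def baseline_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window
        return (self.times >= lo) & (self.times < hi)

    def select_conditions(self, conditions: list[str]) -> "EpochSet":
        keep = [i for i, c in enumerate(self.conditions) if c in conditions]
        return replace(
            self,
            data=self.data[keep],
            conditions=[self.conditions[i] for i in keep],
            sessions=[self.sessions[i] for i in keep],
            rejection_log=self.rejection_log,
        )

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=data)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0 < self.low < self.high <= nyq):
            raise ValueError(
                f"band {self.name}: need 0 < low < high <= Nyquist "
                f"({self.low}, {self.high}, Nyquist {nyq})"
            )


#: The four analysis bands.
DEFAULT_BANDS = (
    BandSpec("delta", 1.0, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 14.0, 30.0),
)
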