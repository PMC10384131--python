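"""Core in-memory containers: multichannel recordings and event schedules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """A multichannel EEG recording.

    Attributes
    ----------
    data:
        ``(n_channels, n_samples)`` array of amplitudes in microvolts.
    fs:
        Sampling rate in Hz.
    channel_labels:
        One label per row of ``data``.
    components:
        Optional per-source breakdown kept by the synthesizer (keys are
        band names plus ``"background"``), each shaped like ``data``.
        Real recordings do not carry components.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    components: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            components=(
                {k: v.copy() for k, v in self.components.items()}
                if self.components is not None
                else None
            ),
        )


@dataclass
class EventSchedule:
    """Ordered cue onsets with optional per-event reaction times.

    ``reaction_times`` holds NaN where the response is unset; ``valid``
    flags events usable for analysis (set during segmentation/screening).
    """

    cue_times: np.ndarray
    reaction_times: np.ndarray | None = None
    event_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cue_times = np.asarray(self.cue_times, dtype=float)
        if self.cue_times.ndim != 1:
            raise ValueError("cue_times must be 1-D")
        if np.any(np.diff(self.cue_times) <= 0):
            raise ValueError("cue times must be strictly increasing")
        if self.reaction_times is None:
            self.reaction_times = np.full_like(self.cue_times, np.nan)
        else:
            self.reaction_times = np.asarray(self.reaction_times, dtype=float)
            if self.reaction_times.shape != self.cue_times.shape:
                raise ValueError("reaction_times shape mismatch")
        if self.event_ids is None:
            self.event_ids = np.arange(len(self.cue_times))
        else:
            self.event_ids = np.asarray(self.event_ids)

    def __len__(self) -> int:
        return len(self.cue_times)

    @property
    def response_times(self) -> np.ndarray:
        """Absolute response timestamps (cue + reaction time)."""
        return self.cue_times + self.reaction_times

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": self.event_ids,
                "cue_time_s": self.cue_times,
                "response_time_s": self.response_times,
            }
        )
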