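"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: columns every event table must carry
EVENT_COLUMNS = (
    "sample", "onset", "role", "condition", "half", "trial_index",
    "scale_index", "position", "f0_hz", "level_db",
)


@dataclass
class Recording:
    """Continuous multichannel EEG (µV) plus sensor geometry and markers."""

    data: np.ndarray                 # (n_channels, n_samples)
    sample_rate_hz: float
    channel_names: list[str]
    channel_positions: np.ndarray    # (n_channels, 2) projected coordinates
    events: pd.DataFrame             # EVENT_COLUMNS (sample = index at this fs)
    trial_spans: Optional[pd.DataFrame] = None  # trial_index, start/stop sample
    subject: Optional[int] = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("data rows must match channel_names")
        if not self.events["sample"].is_monotonic_increasing:
            self.events = self.events.sort_values("sample").reset_index(drop=True)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, sample_rate_hz: float | None = None,
                  events: pd.DataFrame | None = None,
                  trial_spans: pd.DataFrame | None = None) -> "Recording":
        return Recording(
            data=data,
            sample_rate_hz=sample_rate_hz or self.sample_rate_hz,
            channel_names=list(self.channel_names),
            channel_positions=self.channel_positions,
            events=self.events.copy() if events is None else events,
            trial_spans=self.trial_spans if trial_spans is None else trial_spans,
            subject=self.subject,
        )


@dataclass
class EpochsSet:
    """Trials x channels x time array with per-epoch labels.

    ``labels`` carries at least: content ('standard' | 'deviant_ID' |
    'deviant_BD'), position_type ('ID' | 'BD'), condition, half, trial_index.
    """

    data: np.ndarray                 # (n_epochs, n_channels, n_times) µV
    times: np.ndarray                # seconds relative to tone onset
    labels: pd.DataFrame
    sample_rate_hz: float
    channel_names: list[str]
    channel_positions: np.ndarray
    subject: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per epoch")

    def select(self, **criteria) -> "EpochsSet":
        mask = np.ones(len(self.labels), dtype=bool)
        for col, val in criteria.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= self.labels[col].isin(list(vals)).to_numpy()
        return EpochsSet(
            data=self.data[mask],
            times=self.times,
            labels=self.labels.loc[mask].reset_index(drop=True),
            sample_rate_hz=self.sample_rate_hz,
            channel_names=list(self.channel_names),
            channel_positions=self.channel_positions,
            subject=self.subject,
        )
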