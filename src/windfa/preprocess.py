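"""Band-limiting, notch filtering and event-aligned epoch extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "MultichannelRecording",
    "read_event_table",
    "validate_event_table",
    "TaskEpoch",
    "bandpass",
    "notch",
    "extract_epochs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultichannelRecording:
    """Sample matrix (time x channels, microvolts) with rate and labels."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (time x channels), got {data.shape}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        labels = list(self.channel_labels)
        if len(labels) != data.shape[1]:
            raise ValueError(f"{len(labels)} labels for {data.shape[1]} channels")
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.channel_labels.index(label)]


@dataclass(frozen=True)
class TaskEpoch:
    """Fixed-length excerpt aligned to a cue onset.

    ``t0_offset_s`` is the position of the cue within the epoch (e.g. 2.0
    when the epoch starts 2 s before the cue).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    t0_offset_s: float
    hand: str
    subject: str = ""
    trial: int = 0
    cue_duration_s: float = float("nan")

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.channel_labels.index(label)]


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and ordering; add a default ``keep`` column."""
    required = {"onset_s", "hand"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    onsets = events["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    bad = set(events["hand"]) - {"LH", "RH"}
    if bad:
        raise ValueError(f"unknown hand labels: {sorted(bad)}")
    events = events.copy()
    if "keep" not in events.columns:
        events["keep"] = True
    events["keep"] = events["keep"].astype(bool)
    return events


def read_event_table(path) -> pd.DataFrame:
    """Read a TSV event table (onset_s, hand, cue_duration_s, keep)."""
    return validate_event_table(pd.read_csv(path, sep="\t"))


def _check_band(low: float, high: float, nyquist: float) -> None:
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"cutoffs must satisfy 0 < {low} < {high} < Nyquist ({nyquist})")


def bandpass(recording: MultichannelRecording, low_hz: float = 1.0,
             high_hz: float = 100.0, order: int = 4) -> MultichannelRecording:
    """Zero-phase Butterworth bandpass applied per channel.

    Forward-backward (``sosfiltfilt``) so the passband delay is zero and
    no latency bias is introduced into later trajectory estimates.
    """
    nyq = recording.sampling_rate / 2.0
    _check_band(low_hz, high_hz, nyq)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.data, axis=0)
    return replace(recording, data=filtered)


def notch(recording: MultichannelRecording, freq_hz: float = 50.0,
          q: float = 30.0) -> MultichannelRecording:
    """Zero-phase narrow-band rejection (second-order IIR notch)."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < freq_hz < nyq:
        raise ValueError(f"notch frequency must be in (0, {nyq})")
    b, a = sps.iirnotch(freq_hz, q, fs=recording.sampling_rate)
    filtered = sps.filtfilt(b, a, recording.data, axis=0)
    return replace(recording, data=filtered)


def extract_epochs(recording: MultichannelRecording, events: pd.DataFrame,
                   pre_s: float = 2.0, post_s: float = 12.0, *,
                   subject: str = "", keep_only: bool = True) -> list[TaskEpoch]:
    """Cut one fixed-length epoch per event, centred on the cue onset.

    Sample intervals are half-open ``[onset - pre, onset + post)`` with
    0-based indices; every epoch holds ``round((pre + post) * rate)``
    samples.  Events whose window falls outside the recording are
    skipped with a logged warning.  Rows with ``keep == False`` are
    dropped when ``keep_only`` is set.
    """
    events = validate_event_table(events)
    rate = recording.sampling_rate
    n_len = int(round((pre_s + post_s) * rate))
    epochs: list[TaskEpoch] = []
    for trial, row in enumerate(events.itertuples(index=False)):
        if keep_only and not row.keep:
            continue
        start = int(round((row.onset_s - pre_s) * rate))
        stop = start + n_len
        if start < 0 or stop > recording.n_samples:
            logger.warning("event at %.3f s outside recording bounds; skipped",
                           row.onset_s)
            continue
        cue_dur = getattr(row, "cue_duration_s", float("nan"))
        epochs.append(TaskEpoch(
            data=recording.data[start:stop],
            sampling_rate=rate,
            channel_labels=recording.channel_labels,
            t0_offset_s=pre_s,
            hand=row.hand,
            subject=subject,
            trial=trial,
            cue_duration_s=float(cue_dur),
        ))
    return epochs
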