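"""Reading and writing recordings, event tables and result tables.

Recordings travel as delimited text (CSV/TSV): an optional comment line
``# sampling_rate_hz=<rate>`` followed by a header row of channel labels
and one row per sample.  EDF input is supported when ``pyedflib`` is
installed.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MultichannelRecording

__all__ = [
    "read_recording",
    "write_recording",
    "write_events",
    "read_events",
    "write_table",
]

_RATE_PREFIX = "# sampling_rate_hz="


def write_recording(recording: MultichannelRecording, path, *, sep: str | None = None) -> None:
    """Write a recording as delimited text with an embedded rate line."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.DataFrame(recording.data, columns=recording.channel_labels)
    with open(path, "w") as fh:
        fh.write(f"{_RATE_PREFIX}{recording.sampling_rate:g}\n")
        frame.to_csv(fh, sep=sep, index=False, float_format="%.6g")


def _read_delimited(path: Path, sampling_rate: float | None) -> MultichannelRecording:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_RATE_PREFIX):
            sampling_rate = float(first[len(_RATE_PREFIX):].strip())
            rest = fh.read()
        else:
            rest = first + fh.read()
    if sampling_rate is None:
        raise ValueError(
            f"{path}: sampling rate not embedded in the file and not supplied")
    frame = pd.read_csv(_io.StringIO(rest), sep=sep)
    if frame.isna().any().any():
        raise ValueError(f"{path}: ragged or non-numeric rows")
    data = frame.to_numpy(dtype=float)
    return MultichannelRecording(data=data, sampling_rate=sampling_rate,
                                 channel_labels=[str(c) for c in frame.columns])


def _read_edf(path: Path) -> MultichannelRecording:
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional 'pyedflib' package "
            "(pip install windfa[edf]); CSV/TSV input needs no extras") from exc
    with pyedflib.EdfReader(str(path)) as reader:  # pragma: no cover
        labels = reader.getSignalLabels()
        rates = {reader.getSampleFrequency(i) for i in range(reader.signals_in_file)}
        if len(rates) != 1:
            raise ValueError(f"{path}: channels have differing sampling rates")
        data = np.column_stack([reader.readSignal(i)
                                for i in range(reader.signals_in_file)])
    return MultichannelRecording(data=data, sampling_rate=float(rates.pop()),
                                 channel_labels=list(labels))


def read_recording(path, fmt: str | None = None,
                   sampling_rate: float | None = None) -> MultichannelRecording:
    """Read a multichannel recording from CSV, TSV or EDF.

    The format is inferred from the file suffix unless given explicitly.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".tab": "tsv",
               ".edf": "edf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt in {"csv", "tsv"}:
        return _read_delimited(path, sampling_rate)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    from .preprocess import read_event_table
    return read_event_table(path)


def write_table(frame: pd.DataFrame, path, *, config_hash: str | None = None) -> None:
    """Write a result table as TSV, stamped with the producing config."""
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=False)
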