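"""Reading and writing signals, annotations and result tables.

The package works on two time axes: the *original* axis of the recording,
on which respiratory events and artifacts are scored, and the *cleaned*
axis that remains after artifact segments have been cut out.  The
:class:`IndexMap` keeps the correspondence between the two.

File formats
------------
Signals are read either from EDF (any channel, at its native sampling
rate) or from a plain-text CSV holding one sample value per line with the
sampling rate declared in ``# key=value`` comment lines at the top (or in
a ``<name>.json`` sidecar).  Annotations travel as a CSV with columns
``onset_s,duration_s,kind`` where ``kind`` is one of ``apnea``,
``hypopnea`` or ``artifact``; onsets are seconds from recording start and
intervals are half-open ``[onset, onset+duration)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignalRecord",
    "Event",
    "AnnotationSet",
    "IndexMap",
    "ChannelNotFoundError",
    "FormatError",
    "ValidationError",
    "read_signal",
    "write_signal_csv",
    "read_annotations",
    "write_annotations",
    "read_results",
    "write_results",
    "write_summary",
]

EVENT_KINDS = ("apnea", "hypopnea")
ARTIFACT_KIND = "artifact"

#: column order of the epoch result table, fixed for serialization
RESULT_COLUMNS = (
    "epoch_index",
    "start_s",
    "AV",
    "MD",
    "SD",
    "CoV",
    "has_event",
    "event_overlap_s",
)


class FormatError(ValueError):
    """An input file could not be parsed in the expected format."""


class ChannelNotFoundError(KeyError):
    """The requested channel is absent from the recording."""


class ValidationError(ValueError):
    """An input violates a documented contract."""


@dataclass(frozen=True)
class SignalRecord:
    """A single-channel time series with its sampling rate.

    Parameters
    ----------
    samples
        Pressure samples in arbitrary units (the sliding z-score removes
        units downstream).  NaN is allowed only inside declared artifact
        segments.
    fs
        Sampling rate in Hz, strictly positive.
    t0
        Recording start offset in seconds (annotations are relative to it).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("signal must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class Event:
    """A scored interval on the original time axis."""

    onset_s: float
    duration_s: float
    kind: str = "apnea"

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValidationError(f"onset must be >= 0, got {self.onset_s}")
        if not self.duration_s > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class AnnotationSet:
    """Scored respiratory events and artifact segments.

    Both lists live on the original time axis.  Events need not be
    disjoint from artifacts; apnea/hypopnea types are retained but the
    epoch-labelling stage does not differentiate them.
    """

    events: list[Event] = field(default_factory=list)
    artifacts: list[Event] = field(default_factory=list)

    def event_intervals(self) -> list[tuple[float, float]]:
        return [(e.onset_s, e.end_s) for e in self.events]

    def artifact_intervals(self) -> list[tuple[float, float]]:
        return [(a.onset_s, a.end_s) for a in self.artifacts]


@dataclass(frozen=True)
class IndexMap:
    """Mapping from cleaned-signal samples to original sample indices.

    ``kept[i]`` is the original index of cleaned sample ``i``; the array
    is strictly increasing.  ``n_original`` is the length of the original
    signal, needed to rebuild per-sample masks on the original axis.
    """

    kept: np.ndarray
    n_original: int

    def __post_init__(self) -> None:
        kept = np.asarray(self.kept, dtype=np.int64)
        object.__setattr__(self, "kept", kept)
        if kept.size and (np.any(np.diff(kept) <= 0) or kept[0] < 0 or kept[-1] >= self.n_original):
            raise ValidationError("index map must be strictly increasing and in range")

    @property
    def n(self) -> int:
        return int(self.kept.size)

    @classmethod
    def identity(cls, n: int) -> "IndexMap":
        return cls(np.arange(n, dtype=np.int64), n)


# ---------------------------------------------------------------------------
# signals


def _read_csv_signal(path: Path) -> SignalRecord:
    meta: dict[str, float] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        pass
                continue
            if line.lower() in ("value", "sample"):  # optional header
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise FormatError(f"{path}: cannot parse sample value {line!r}") from exc
    sidecar = path.with_suffix(".json")
    if "fs" not in meta and sidecar.exists():
        with open(sidecar) as fh:
            meta.update({k: float(v) for k, v in json.load(fh).items()})
    if "fs" not in meta:
        raise FormatError(f"{path}: sampling rate not declared (`# fs=...` or JSON sidecar)")
    if not values:
        raise FormatError(f"{path}: no samples found")
    return SignalRecord(np.asarray(values), fs=meta["fs"], t0=meta.get("t0", 0.0))


def _read_edf_signal(path: Path, channel: str | int | None) -> SignalRecord:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=False, verbose="ERROR")
    except Exception as exc:  # mne raises various concrete types
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc
    names = raw.ch_names
    if channel is None:
        idx = 0
    elif isinstance(channel, int):
        if not 0 <= channel < len(names):
            raise ChannelNotFoundError(f"channel index {channel} out of range (n={len(names)})")
        idx = channel
    else:
        if channel not in names:
            raise ChannelNotFoundError(f"channel {channel!r} not in {names}")
        idx = names.index(channel)
    raw = raw.pick([names[idx]])
    data = raw.get_data()[0]
    return SignalRecord(np.asarray(data, dtype=np.float64), fs=float(raw.info["sfreq"]))


def read_signal(path: str | Path, channel: str | int | None = None) -> SignalRecord:
    """Read a single-channel signal from EDF or CSV at its native rate.

    Parameters
    ----------
    path
        ``.edf`` file or plain-text CSV (see module docstring).
    channel
        EDF channel label or index; ignored for CSV.  Defaults to the
        first channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix.lower() == ".edf":
        return _read_edf_signal(path, channel)
    return _read_csv_signal(path)


def write_signal_csv(record: SignalRecord, path: str | Path) -> None:
    """Write a signal as one sample per line with ``# fs=`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:.12g}\n")
        fh.write(f"# t0={record.t0:.12g}\n")
        np.savetxt(fh, record.samples, fmt="%.12g")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a CSV of scored events and artifact segments.

    Expects columns ``onset_s,duration_s,kind``; ``kind`` must be
    ``apnea``, ``hypopnea`` or ``artifact``.  Row order is preserved
    within each of the two output lists.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: unreadable annotation CSV ({exc})") from exc
    required = {"onset_s", "duration_s", "kind"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation CSV needs columns {sorted(required)}")
    out = AnnotationSet()
    for row in df.itertuples(index=False):
        kind = str(row.kind).strip().lower()
        if kind not in EVENT_KINDS + (ARTIFACT_KIND,):
            raise ValidationError(f"unknown annotation kind {row.kind!r}")
        interval = Event(float(row.onset_s), float(row.duration_s), kind)
        if kind == ARTIFACT_KIND:
            out.artifacts.append(interval)
        else:
            out.events.append(interval)
    return out


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    rows = [(e.onset_s, e.duration_s, e.kind) for e in annotations.events]
    rows += [(a.onset_s, a.duration_s, ARTIFACT_KIND) for a in annotations.artifacts]
    pd.DataFrame(rows, columns=["onset_s", "duration_s", "kind"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write an epoch table as CSV with the fixed column order.

    Values round-trip through :func:`read_results` to 12 significant
    digits.  Columns beyond :data:`RESULT_COLUMNS` are dropped.
    """
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "has_event" in df.columns:
        df["has_event"] = df["has_event"].astype(bool)
    return df


def write_summary(summary: dict, path: str | Path) -> None:
    """Write a JSON summary (full-night parameters, bookkeeping counters)."""

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
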