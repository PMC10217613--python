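"""Difference-envelope summary parameters at full-night and epoch scale.

Four statistics summarize the difference envelope over a span: the
average (AV), median (MD), population standard deviation (SD) and the
coefficient of variation CoV = SD / AV.  They are computed once over the
whole recording and once per non-overlapping 30-s epoch of the cleaned
signal; a trailing partial epoch is discarded.  An epoch is labelled
positive when at least one of its samples maps, through the artifact
index map, into any scored apnea or hypopnea interval — the two event
types are not differentiated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .envelope import EnvelopeResult, compute_envelopes
from .io import AnnotationSet, IndexMap, SignalRecord, ValidationError
from .preprocess import CleanSignal, preprocess
from .preprocess import _interval_to_samples

logger = logging.getLogger(__name__)

__all__ = [
    "EnvelopeParameters",
    "RecordingAnalysis",
    "summarize",
    "epoch_split",
    "label_epochs",
    "event_overlap_seconds",
    "build_epoch_table",
    "analyze_recording",
]

PARAMETER_NAMES = ("AV", "MD", "SD", "CoV")


@dataclass(frozen=True)
class EnvelopeParameters:
    """The (AV, MD, SD, CoV) quadruple for one signal span.

    ``cov`` is NaN and ``cov_defined`` False in the pathological case
    AV = 0 with SD > 0; downstream analyses exclude such spans.
    """

    av: float
    md: float
    sd: float
    cov: float
    cov_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"AV": self.av, "MD": self.md, "SD": self.sd, "CoV": self.cov}


def summarize(diff: np.ndarray) -> EnvelopeParameters:
    """AV/MD/SD/CoV of a difference-envelope span.

    SD uses the population convention (divide by n).  CoV is SD/AV, with
    CoV = 0 when both AV and SD are zero and undefined (NaN, flagged)
    when AV = 0 but SD > 0.
    """
    x = np.asarray(diff, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("cannot summarize an empty span")
    av = float(np.mean(x))
    md = float(np.median(x))
    sd = float(np.std(x))
    if av != 0.0:
        return EnvelopeParameters(av, md, sd, sd / av)
    if sd == 0.0:
        return EnvelopeParameters(av, md, sd, 0.0)
    return EnvelopeParameters(av, md, sd, float("nan"), cov_defined=False)


def epoch_split(n_samples: int, fs: float, epoch_s: float = 30.0) -> list[tuple[int, int]]:
    """Consecutive half-open spans of exactly ``epoch_s`` seconds.

    Spans start at cleaned sample 0; the remainder shorter than one epoch
    is dropped.  ``fs * epoch_s`` must be a whole number of samples.
    """
    w_float = fs * epoch_s
    w = int(round(w_float))
    if abs(w_float - w) > 1e-9 or w < 1:
        raise ValidationError(f"epoch of {epoch_s} s is not a whole number of samples at {fs} Hz")
    return [(k * w, (k + 1) * w) for k in range(n_samples // w)]


def _event_mask(events: AnnotationSet, fs: float, n_original: int) -> np.ndarray:
    """Boolean per-sample membership in any scored event, original axis."""
    mask = np.zeros(n_original, dtype=bool)
    for lo_s, hi_s in events.event_intervals():
        lo, hi = _interval_to_samples(lo_s, hi_s, fs, n_original)
        mask[lo:hi] = True
    return mask


def label_epochs(
    spans: list[tuple[int, int]],
    index_map: IndexMap,
    events: AnnotationSet,
    fs: float,
) -> np.ndarray:
    """True for epochs containing at least one sample of a scored event.

    Spans live on the cleaned axis; events on the original axis.  An
    event wholly inside a removed artifact segment labels nothing.
    """
    mask = _event_mask(events, fs, index_map.n_original)[index_map.kept]
    return np.array([bool(mask[a:b].any()) for a, b in spans])


def event_overlap_seconds(
    spans: list[tuple[int, int]],
    index_map: IndexMap,
    events: AnnotationSet,
    fs: float,
) -> np.ndarray:
    """Total scored-event time (s) mapped into each epoch."""
    mask = _event_mask(events, fs, index_map.n_original)[index_map.kept]
    return np.array([float(mask[a:b].sum()) / fs for a, b in spans])


def build_epoch_table(
    diff: np.ndarray,
    index_map: IndexMap,
    events: AnnotationSet,
    fs: float,
    epoch_s: float = 30.0,
) -> pd.DataFrame:
    """Per-epoch parameter table with event labels and overlap seconds."""
    spans = epoch_split(diff.size, fs, epoch_s)
    labels = label_epochs(spans, index_map, events, fs)
    overlap = event_overlap_seconds(spans, index_map, events, fs)
    rows = []
    for k, (a, b) in enumerate(spans):
        p = summarize(diff[a:b])
        rows.append((k, a / fs, p.av, p.md, p.sd, p.cov, bool(labels[k]), overlap[k]))
    return pd.DataFrame(
        rows,
        columns=[
            "epoch_index",
            "start_s",
            "AV",
            "MD",
            "SD",
            "CoV",
            "has_event",
            "event_overlap_s",
        ],
    )


@dataclass(frozen=True)
class RecordingAnalysis:
    """Everything the pipeline derives from one recording."""

    full_night: EnvelopeParameters
    epochs: pd.DataFrame
    clipped_fraction: float
    removed_s: float
    clean: CleanSignal
    envelopes: EnvelopeResult


def analyze_recording(
    signal: SignalRecord,
    annotations: AnnotationSet | None = None,
    config: AnalysisConfig | None = None,
) -> RecordingAnalysis:
    """Preprocess, build envelopes, and compute full-night + epoch parameters."""
    config = config or AnalysisConfig()
    annotations = annotations if annotations is not None else AnnotationSet()
    clean = preprocess(signal, annotations, config)
    env = compute_envelopes(clean, config)
    full_night = summarize(env.diff)
    epochs = build_epoch_table(env.diff, clean.index_map, annotations, clean.fs, config.epoch_s)
    n_undef = int(epochs["CoV"].isna().sum())
    if n_undef:
        logger.info("%d epochs with undefined CoV (AV=0, SD>0) flagged", n_undef)
    removed_s = (clean.index_map.n_original - clean.n) / clean.fs
    return RecordingAnalysis(full_night, epochs, env.clipped_fraction, removed_s, clean, env)
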