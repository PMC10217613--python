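"""Signal preprocessing: artifact removal, low-pass filtering, sliding z-score.

The pipeline runs in a fixed order — cut out cannula-detachment segments
longer than one second, low-pass filter the concatenated remainder with a
zero-phase 4th-order Butterworth (3 Hz cutoff), then z-score normalize
with a 5-min sliding window stepped one sample at a time.  The normalized
output is the *preprocessed signal* every later stage consumes.

Notes on conventions
--------------------
* Filtering is zero-phase (forward-backward), so the effective magnitude
  response is |H(f)|^2; phase distortion would shift extrema against the
  scored annotations.
* The z-score window is centered and truncated (shrinks) at the recording
  edges rather than padded, and uses the population standard deviation
  (divide by n).  A window with zero spread maps to output 0.
* Filtering is applied to the concatenated post-removal signal; splice
  discontinuities are accepted as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .config import AnalysisConfig
from .io import AnnotationSet, IndexMap, SignalRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CleanSignal",
    "remove_artifact_segments",
    "detect_detachment",
    "lowpass",
    "sliding_zscore",
    "preprocess",
]

#: minimum sampling rate accepted by the full pipeline (Hz)
MIN_FS = 32.0


@dataclass(frozen=True)
class CleanSignal:
    """Preprocessed signal on the cleaned (artifact-free) time axis."""

    samples: np.ndarray
    fs: float
    index_map: IndexMap

    def __post_init__(self) -> None:
        if self.samples.size != self.index_map.n:
            raise ValidationError("index map length must equal signal length")

    @property
    def n(self) -> int:
        return int(self.samples.size)


def _union_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching half-open intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for lo, hi in ordered[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _interval_to_samples(lo_s: float, hi_s: float, fs: float, n: int) -> tuple[int, int]:
    # sample i is inside [lo, hi) iff lo <= i/fs < hi; tiny slack absorbs
    # float noise in onset*fs products
    lo = int(np.ceil(lo_s * fs - 1e-9))
    hi = int(np.ceil(hi_s * fs - 1e-9))
    return max(lo, 0), min(hi, n)


def remove_artifact_segments(
    signal: SignalRecord,
    artifacts: list[tuple[float, float]],
    min_gap_s: float = 1.0,
) -> tuple[np.ndarray, IndexMap]:
    """Delete artifact segments longer than ``min_gap_s`` and concatenate.

    Overlapping intervals are unioned first; a merged segment is removed
    only when its total duration exceeds ``min_gap_s`` (detachments of a
    second or less are left in place).  Intervals reaching past the end
    of the recording are clipped with a warning.

    Returns the surviving samples together with the :class:`IndexMap`
    of their original indices.
    """
    n = signal.n
    duration = signal.duration_s
    keep = np.ones(n, dtype=bool)
    for lo_s, hi_s in _union_intervals([(lo, hi) for lo, hi in artifacts]):
        if hi_s > duration:
            logger.warning(
                "artifact interval (%.3f, %.3f) extends past recording end %.3f s; clipped",
                lo_s, hi_s, duration,
            )
            hi_s = duration
        if hi_s - lo_s <= min_gap_s:
            continue
        lo, hi = _interval_to_samples(lo_s, hi_s, signal.fs, n)
        keep[lo:hi] = False
    kept = np.nonzero(keep)[0]
    return signal.samples[kept], IndexMap(kept, n)


def detect_detachment(
    signal: SignalRecord, window_s: float = 2.0, amp_frac: float = 0.02
) -> list[tuple[float, float]]:
    """Flag segments whose local peak-to-peak amplitude collapses.

    A sample is flagged when the rolling peak-to-peak amplitude over
    ``window_s`` falls below ``amp_frac`` times the recording's median
    rolling peak-to-peak amplitude; maximal runs of flagged samples are
    returned as ``(onset_s, end_s)`` intervals.  An entirely flat signal
    yields one full-length interval.
    """
    x = signal.samples
    w = max(int(round(window_s * signal.fs)), 1)
    ptp = ndimage.maximum_filter1d(x, w, mode="nearest") - ndimage.minimum_filter1d(
        x, w, mode="nearest"
    )
    med = float(np.median(ptp))
    if med <= 0.0:
        return [(0.0, signal.duration_s)]
    flat = ptp < amp_frac * med
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flat, [False])).astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return [(s / signal.fs, e / signal.fs) for s, e in zip(starts, stops)]


def lowpass(
    samples: np.ndarray, fs: float, cutoff_hz: float = 3.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; output length equals input length.

    The forward-backward application squares the magnitude response, so
    the effective gain on a pure tone at frequency f is
    ``1 / (1 + (f / cutoff)**(2*order))``.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if not fs > 2.0 * cutoff_hz:
        raise ValidationError(f"fs={fs} must exceed twice the cutoff {cutoff_hz} Hz")
    if samples.size < 3 * order:
        raise ValidationError(
            f"signal of {samples.size} samples is shorter than the filter warm-up"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, samples)


def _window_bounds(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open centered windows of nominal width w, truncated at edges."""
    i = np.arange(n)
    lo = np.maximum(i - w // 2, 0)
    hi = np.minimum(i + (w - w // 2), n)
    return lo, hi


def sliding_zscore(
    samples: np.ndarray,
    fs: float,
    window_s: float = 300.0,
    step_samples: int = 1,
) -> np.ndarray:
    """Z-score each sample against its surrounding window.

    Output sample i is ``(x[i] - mean(W_i)) / std(W_i)`` where ``W_i`` is
    the window of ``window_s`` seconds centered on i, truncated at the
    recording edges; the standard deviation is the population one.  A
    window with (numerically) zero spread yields 0.  Only the one-sample
    step is implemented.
    """
    if step_samples != 1:
        raise ValidationError("only a one-sample window step is supported")
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    w = max(int(round(window_s * fs)), 1)
    lo, hi = _window_bounds(n, w)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    cnt = (hi - lo).astype(np.float64)
    mean = (c1[hi] - c1[lo]) / cnt
    msq = (c2[hi] - c2[lo]) / cnt
    var = msq - mean * mean
    # cumulative sums leave O(eps) residuals on flat windows; treat those as zero
    var = np.where(var <= 1e-12 * np.maximum(msq, 1e-300), 0.0, var)
    std = np.sqrt(np.maximum(var, 0.0))
    out = np.zeros(n)
    nz = std > 0
    out[nz] = (x[nz] - mean[nz]) / std[nz]
    return out


def preprocess(
    signal: SignalRecord,
    annotations: AnnotationSet | None = None,
    config: AnalysisConfig | None = None,
) -> CleanSignal:
    """Artifact removal, low-pass filtering and sliding z-score, in order."""
    config = config or AnalysisConfig()
    if signal.fs < MIN_FS:
        raise ValidationError(f"sampling rate {signal.fs} Hz below supported minimum {MIN_FS}")
    artifacts = annotations.artifact_intervals() if annotations is not None else []
    samples, index_map = remove_artifact_segments(
        signal, artifacts, min_gap_s=config.artifact_min_gap_s
    )
    if samples.size == 0:
        raise ValidationError("no signal left after artifact removal")
    if np.any(~np.isfinite(samples)):
        raise ValidationError("non-finite samples outside declared artifact segments")
    removed_s = (signal.n - samples.size) / signal.fs
    if removed_s > 0:
        logger.info("removed %.1f s of artifact segments", removed_s)
    filtered = lowpass(samples, signal.fs, config.cutoff_hz, config.filter_order)
    normalized = sliding_zscore(filtered, signal.fs, config.zscore_window_s)
    return CleanSignal(normalized, signal.fs, index_map)
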