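"""Upper/lower/difference envelope construction.

The breathing amplitude proxy is built in four steps: smooth the
preprocessed signal with a 0.5-s moving average to suppress spurious
ripples, locate local extrema on the smoothed trace, snap each extremum
back to the true extreme of the *unsmoothed* preprocessed signal within a
1-s window, and interpolate the refined maxima (minima) with a
shape-preserving piecewise cubic Hermite polynomial to obtain the upper
(lower) envelope.  The difference envelope is upper minus lower, clipped
at zero where the two cross.

Determinism conventions (the published description leaves these open):
plateau extrema take the plateau midpoint; ties inside the refinement
window go to the earliest sample; duplicate refined indices are merged;
beyond the first/last extremum the envelope holds the boundary value
constant; maxima and minima are handled independently — alternation is
not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .config import AnalysisConfig
from .io import ValidationError
from .preprocess import CleanSignal, _window_bounds

__all__ = [
    "ExtremaSet",
    "EnvelopeResult",
    "DegenerateEnvelopeError",
    "smooth",
    "detect_extrema",
    "refine_extrema",
    "build_envelope",
    "difference_envelope",
    "compute_envelopes",
]


class DegenerateEnvelopeError(ValueError):
    """Too few extrema to build an envelope."""


@dataclass(frozen=True)
class ExtremaSet:
    """Sample indices of local maxima and minima (each strictly increasing)."""

    maxima_idx: np.ndarray
    minima_idx: np.ndarray


@dataclass(frozen=True)
class EnvelopeResult:
    """Envelopes aligned sample-for-sample with the preprocessed signal.

    ``diff`` is non-negative everywhere; ``clipped_fraction`` is the share
    of samples where the raw upper-lower difference was negative and was
    set to zero.
    """

    upper: np.ndarray
    lower: np.ndarray
    diff: np.ndarray
    maxima_idx: np.ndarray
    minima_idx: np.ndarray
    clipped_fraction: float


def smooth(samples: np.ndarray, fs: float, window_s: float = 0.5) -> np.ndarray:
    """Centered moving average, window truncated at the edges."""
    x = np.asarray(samples, dtype=np.float64)
    w = int(round(window_s * fs))
    if w < 1:
        raise ValidationError("smoothing window must span at least one sample")
    lo, hi = _window_bounds(x.size, w)
    c = np.concatenate(([0.0], np.cumsum(x)))
    return (c[hi] - c[lo]) / (hi - lo)


def detect_extrema(smoothed: np.ndarray) -> ExtremaSet:
    """Locate local extrema by first-difference sign changes.

    A maximum is a + -> - sign change of the first difference, a minimum
    the reverse; a flat plateau contributes its midpoint sample once.
    Monotone signals produce empty index arrays.
    """
    x = np.asarray(smoothed, dtype=np.float64)
    if x.size < 3:
        raise ValidationError("need at least 3 samples to detect extrema")
    s = np.sign(np.diff(x))
    nz = np.flatnonzero(s)
    maxima: list[int] = []
    minima: list[int] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if s[a] == s[b]:
            continue
        mid = (a + 1 + b) // 2  # plateau spans samples a+1 .. b
        (maxima if s[a] > 0 else minima).append(mid)
    return ExtremaSet(
        np.asarray(maxima, dtype=np.int64), np.asarray(minima, dtype=np.int64)
    )


def refine_extrema(
    samples: np.ndarray,
    fs: float,
    candidates: np.ndarray,
    mode: str,
    window_s: float = 1.0,
) -> np.ndarray:
    """Snap smoothed-signal extrema to the true extremes of ``samples``.

    Each candidate is replaced by the argmax (``mode='max'``) or argmin
    (``mode='min'``) of ``samples`` within a centered ``window_s`` window,
    truncated at the edges; ties go to the earliest sample and duplicates
    are merged.
    """
    if mode not in ("max", "min"):
        raise ValidationError(f"mode must be 'max' or 'min', got {mode!r}")
    x = np.asarray(samples, dtype=np.float64)
    cands = np.asarray(candidates, dtype=np.int64)
    if cands.size and (cands.min() < 0 or cands.max() >= x.size):
        raise ValidationError("extremum candidates out of range")
    w = max(int(round(window_s * fs)), 1)
    pick = np.argmax if mode == "max" else np.argmin
    refined = np.empty(cands.size, dtype=np.int64)
    for k, c in enumerate(cands):
        lo = max(c - w // 2, 0)
        hi = min(c + (w - w // 2), x.size)
        refined[k] = lo + pick(x[lo:hi])
    return np.unique(refined)


def build_envelope(indices: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Shape-preserving cubic Hermite interpolant through (index, value).

    Evaluated at every sample ``0..n-1``; outside the first/last knot the
    envelope holds the boundary value constant.
    """
    idx = np.asarray(indices, dtype=np.float64)
    val = np.asarray(values, dtype=np.float64)
    if idx.size < 2:
        raise DegenerateEnvelopeError("need at least 2 points to build an envelope")
    if np.any(np.diff(idx) <= 0):
        raise ValidationError("envelope point indices must be strictly increasing")
    out = np.empty(n, dtype=np.float64)
    first, last = int(idx[0]), int(idx[-1])
    interp = PchipInterpolator(idx, val, extrapolate=False)
    inner = np.arange(max(first, 0), min(last, n - 1) + 1)
    out[inner] = interp(inner)
    out[: max(first, 0)] = val[0]
    out[min(last, n - 1) + 1 :] = val[-1]
    return out


def difference_envelope(upper: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """Upper minus lower, clipped at zero where the envelopes intersect."""
    upper = np.asarray(upper, dtype=np.float64)
    lower = np.asarray(lower, dtype=np.float64)
    if upper.shape != lower.shape:
        raise ValidationError("upper and lower envelopes must have equal length")
    return np.maximum(upper - lower, 0.0)


def compute_envelopes(
    preprocessed: CleanSignal, config: AnalysisConfig | None = None
) -> EnvelopeResult:
    """Run the full envelope pipeline on a preprocessed signal."""
    config = config or AnalysisConfig()
    x = preprocessed.samples
    fs = preprocessed.fs
    smoothed = smooth(x, fs, config.smooth_window_s)
    extrema = detect_extrema(smoothed)
    maxima = refine_extrema(x, fs, extrema.maxima_idx, "max", config.refine_window_s)
    minima = refine_extrema(x, fs, extrema.minima_idx, "min", config.refine_window_s)
    if maxima.size < 2:
        raise DegenerateEnvelopeError(
            f"only {maxima.size} maxima found; cannot build the upper envelope"
        )
    if minima.size < 2:
        raise DegenerateEnvelopeError(
            f"only {minima.size} minima found; cannot build the lower envelope"
        )
    upper = build_envelope(maxima, x[maxima], x.size)
    lower = build_envelope(minima, x[minima], x.size)
    diff = difference_envelope(upper, lower)
    clipped = float(np.mean(upper - lower < 0.0))
    return EnvelopeResult(upper, lower, diff, maxima, minima, clipped)
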