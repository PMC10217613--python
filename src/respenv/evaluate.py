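"""Evaluation layer: ROC/AUC against AHI groups and scored events.

Patients are classified at the conventional AHI severity thresholds
(5, 15, 30 events/h) using each full-night parameter as the score, plus
an extreme contrast between non-OSA (AHI < 5) and severe (AHI >= 30)
patients.  Pooled 30-s epochs are scored the same way against the
event/no-event label.  Score orientation is fixed a priori by the
physiological hypothesis — disturbed breathing shrinks the difference
envelope and raises its variability — so AV and MD classify with
lower-is-positive and SD and CoV with higher-is-positive; orientation is
never chosen from the data.

AUC is the trapezoidal area under the empirical ROC, identical to the
tie-corrected Mann-Whitney statistic P(score+ > score-) + P(=)/2.
Quartiles everywhere use linear interpolation between order statistics
(numpy's default, "type 7"), which pins down the 1.5 IQR outlier rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .io import ValidationError
from .parameters import PARAMETER_NAMES, EnvelopeParameters

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "ROCResult",
    "CorrelationResult",
    "BoxplotStats",
    "DegenerateAnalysisError",
    "PARAM_ORIENTATION",
    "severity_group",
    "auc",
    "classify_cohort",
    "extreme_contrast",
    "epoch_roc",
    "correlate_ahi",
    "pooled_epochs",
    "event_fraction_by_bin",
    "severity_distributions",
    "duration_stratified_stats",
    "analyze_cohort_records",
]

#: a priori score orientation per parameter (see module docstring)
PARAM_ORIENTATION = {"AV": "lower", "MD": "lower", "SD": "higher", "CoV": "higher"}

SEVERITY_GROUPS = ("non-OSA", "mild", "moderate", "severe")


class DegenerateAnalysisError(ValueError):
    """A contrast has no members on one side."""


def severity_group(ahi: float) -> str:
    """Conventional OSA severity group from the AHI (cut points 5/15/30)."""
    if ahi < 5:
        return "non-OSA"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


@dataclass
class PatientRecord:
    """One patient's AHI, full-night parameters, and epoch table."""

    id: str
    ahi: float
    full_night: EnvelopeParameters
    epochs: pd.DataFrame
    group: str = ""

    def __post_init__(self) -> None:
        if not self.group:
            self.group = severity_group(self.ahi)


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    orientation: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number summary with the 1.5 IQR whisker/outlier rule."""

    label: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n_outliers: int


def auc(scores: np.ndarray, labels: np.ndarray, orientation: str = "higher") -> ROCResult:
    """Empirical ROC curve and trapezoidal AUC.

    ``orientation='lower'`` treats smaller scores as more positive (the
    scores are negated before ranking).  Both classes must be present and
    all scores finite.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    if np.any(~np.isfinite(scores)):
        raise ValidationError("scores must be finite (drop undefined values first)")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateAnalysisError("ROC needs both classes present")
    if orientation not in ("higher", "lower"):
        raise ValidationError(f"orientation must be 'higher' or 'lower', got {orientation!r}")
    s = scores if orientation == "higher" else -scores
    fpr, tpr, thr = skm.roc_curve(labels, s, drop_intermediate=False)
    area = float(skm.auc(fpr, tpr))
    return ROCResult(thr, tpr, fpr, area, orientation, n_pos, n_neg)


def _full_night_scores(cohort: list[PatientRecord], parameter: str) -> np.ndarray:
    if parameter not in PARAMETER_NAMES:
        raise ValidationError(f"unknown parameter {parameter!r}")
    return np.array([p.full_night.as_dict()[parameter] for p in cohort])


def classify_cohort(
    cohort: list[PatientRecord], parameter: str, ahi_threshold: float
) -> ROCResult:
    """Binary patient classification at an AHI threshold (positive: AHI >= t)."""
    scores = _full_night_scores(cohort, parameter)
    labels = np.array([p.ahi >= ahi_threshold for p in cohort])
    if labels.all() or not labels.any():
        raise DegenerateAnalysisError(
            f"AHI threshold {ahi_threshold}: cohort has patients on one side only"
        )
    keep = np.isfinite(scores)
    if not keep.all():
        logger.info("dropping %d patients with undefined %s", int((~keep).sum()), parameter)
    return auc(scores[keep], labels[keep], PARAM_ORIENTATION[parameter])


def extreme_contrast(cohort: list[PatientRecord], parameter: str) -> ROCResult:
    """ROC between non-OSA (AHI < 5) and severe (AHI >= 30) patients only."""
    subset = [p for p in cohort if p.ahi < 5 or p.ahi >= 30]
    if not any(p.ahi < 5 for p in subset) or not any(p.ahi >= 30 for p in subset):
        raise DegenerateAnalysisError("extreme contrast needs both non-OSA and severe patients")
    return classify_cohort(subset, parameter, 30.0)


def pooled_epochs(cohort: list[PatientRecord]) -> pd.DataFrame:
    """All patients' epoch rows concatenated, with patient id and group."""
    frames = []
    for p in cohort:
        df = p.epochs.copy()
        df["patient_id"] = p.id
        df["group"] = p.group
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def epoch_roc(cohort: list[PatientRecord], parameter: str) -> ROCResult:
    """ROC over all epochs pooled across patients (no per-patient weighting)."""
    pooled = pooled_epochs(cohort)
    scores = pooled[parameter].to_numpy(dtype=np.float64)
    labels = pooled["has_event"].to_numpy(dtype=bool)
    keep = np.isfinite(scores)
    if not keep.all():
        logger.info("dropping %d epochs with undefined %s", int((~keep).sum()), parameter)
    return auc(scores[keep], labels[keep], PARAM_ORIENTATION[parameter])


def correlate_ahi(cohort: list[PatientRecord], parameter: str) -> CorrelationResult:
    """Spearman (primary) and Pearson correlation of a parameter with AHI.

    Spearman is the headline estimator: the AHI distribution is heavily
    right-skewed, which Pearson handles poorly.  Constant inputs yield an
    undefined (flagged) result.
    """
    scores = _full_night_scores(cohort, parameter)
    ahi = np.array([p.ahi for p in cohort])
    keep = np.isfinite(scores)
    scores, ahi = scores[keep], ahi[keep]
    if scores.size < 3:
        raise ValidationError("correlation needs at least 3 patients")
    if np.ptp(scores) == 0 or np.ptp(ahi) == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"), scores.size, False)
    rho, p = stats.spearmanr(scores, ahi)
    r, _ = stats.pearsonr(scores, ahi)
    return CorrelationResult(float(rho), float(p), float(r), scores.size)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed bins [e0,e1), ..., with the final bin open-ended."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, edges.size - 2 + 1).astype(int)  # last bin catches extremes


def event_fraction_by_bin(
    values: np.ndarray, labels: np.ndarray, bin_edges: np.ndarray
) -> pd.DataFrame:
    """Percentage of epochs containing a scored event, per parameter-value bin.

    ``bin_edges`` define left-closed bins; values at or above the last
    edge fall in a final open-ended "extreme" bin.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    edges = np.asarray(bin_edges, dtype=np.float64)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    idx = _bin_index(values, edges)
    n_bins = edges.size  # edges.size-1 regular bins + 1 open-ended
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        n_event = int(labels[sel].sum())
        left = edges[b] if b < edges.size else edges[-1]
        right = edges[b + 1] if b + 1 < edges.size else np.inf
        pct = 100.0 * n_event / n if n else float("nan")
        rows.append((left, right, n, n_event, pct))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "n_epochs", "n_event", "pct_event"])


def severity_distributions(
    cohort: list[PatientRecord], parameter: str, bin_edges: np.ndarray
) -> pd.DataFrame:
    """Per-severity-group epoch-value histograms normalized by patient count.

    Counts are divided by the number of patients in the group (epochs per
    patient, not a probability density); the final bin is open-ended.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    n_bins = edges.size
    out = {}
    pooled = pooled_epochs(cohort)
    group_sizes = {g: sum(p.group == g for p in cohort) for g in SEVERITY_GROUPS}
    for g in SEVERITY_GROUPS:
        n_patients = group_sizes[g]
        if n_patients == 0:
            logger.info("severity group %s is empty", g)
            out[g] = np.full(n_bins, np.nan)
            continue
        vals = pooled.loc[pooled["group"] == g, parameter].to_numpy(dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        counts = np.bincount(_bin_index(vals, edges), minlength=n_bins).astype(float)
        out[g] = counts / n_patients
    left = np.concatenate([edges[:-1], [edges[-1]]])
    right = np.concatenate([edges[1:], [np.inf]])
    df = pd.DataFrame(out)
    df.insert(0, "bin_left", left)
    df.insert(1, "bin_right", right)
    return df


def _boxplot_stats(label: str, x: np.ndarray) -> BoxplotStats:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotStats(
        label,
        int(x.size),
        float(med),
        float(q1),
        float(q3),
        float(inside.min()),
        float(inside.max()),
        int(x.size - inside.size),
    )


DURATION_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


def duration_stratified_stats(
    overlap_s: np.ndarray,
    values: np.ndarray,
    bin_edges: tuple[float, ...] = DURATION_EDGES,
) -> list[BoxplotStats]:
    """Boxplot statistics of epoch values stratified by event-overlap duration.

    The first stratum is exactly 0 s (no event time in the epoch); the
    rest are half-open-left bins ``(e_k, e_{k+1}]``.  Empty strata are
    flagged with n = 0.
    """
    overlap_s = np.asarray(overlap_s, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    keep = np.isfinite(values)
    overlap_s, values = overlap_s[keep], values[keep]
    out = []
    strata: list[tuple[str, np.ndarray]] = [("0", values[overlap_s == 0])]
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = (overlap_s > lo) & (overlap_s <= hi)
        strata.append((f"({lo:g},{hi:g}]", values[sel]))
    for label, x in strata:
        if x.size == 0:
            out.append(BoxplotStats(label, 0, *([float("nan")] * 5), 0))
        else:
            out.append(_boxplot_stats(label, x))
    return out


def analyze_cohort_records(
    cohort: list[PatientRecord], ahi_thresholds: tuple[float, ...] = (5.0, 15.0, 30.0)
) -> dict:
    """The full evaluation bundle for a cohort of analyzed patients.

    Returns a dict with full-night AUCs per parameter and AHI threshold,
    extreme-contrast AUCs, pooled-epoch AUCs, AHI correlations, and group
    sizes; figure-style tables are produced by the dedicated functions.
    """
    if len(cohort) < 2:
        raise DegenerateAnalysisError("cohort analysis needs at least 2 patients")
    bundle: dict = {
        "n_patients": len(cohort),
        "group_sizes": {g: sum(p.group == g for p in cohort) for g in SEVERITY_GROUPS},
        "cohort_auc": {},
        "extreme_auc": {},
        "epoch_auc": {},
        "correlation": {},
    }
    for param in PARAMETER_NAMES:
        bundle["cohort_auc"][param] = {
            f"{t:g}": classify_cohort(cohort, param, t).auc for t in ahi_thresholds
        }
        bundle["extreme_auc"][param] = extreme_contrast(cohort, param).auc
        bundle["epoch_auc"][param] = epoch_roc(cohort, param).auc
        if len(cohort) >= 3:
            corr = correlate_ahi(cohort, param)
            bundle["correlation"][param] = {
                "spearman_rho": corr.spearman_rho,
                "pearson_r": corr.pearson_r,
                "n": corr.n,
            }
        else:
            bundle["correlation"][param] = None
    pooled = pooled_epochs(cohort)
    bundle["n_epochs"] = int(len(pooled))
    bundle["n_event_epochs"] = int(pooled["has_event"].sum())
    return bundle
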