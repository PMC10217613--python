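"""Synthetic nasal-pressure-like recordings with known ground truth.

The generator emulates the phenomenology the envelope method exploits:
quasi-periodic breathing near 0.25 Hz whose amplitude collapses almost
completely during apneas and partially during hypopneas.  The signal is
a multiplicative model

    x(t) = A(t) * E(t) * D(t) * sin(phi(t)) + b(t) + noise

where ``phi`` integrates a per-breath-jittered breathing rate, ``A`` is a
slow log-amplitude random walk (body position / sleep stage drift), ``E``
ramps down to a per-event residual factor over scheduled respiratory
events, ``D`` zeroes the carrier during cannula-detachment segments, and
``b`` is a slow additive baseline wander.  Event schedules realize a
target AHI exactly (events per hour of recording); events last at least
10 s, never overlap, and their edges are ramped over 2 s with a
half-cosine so the envelope is not handed trivial step edges.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .io import AnnotationSet, Event, SignalRecord, ValidationError

__all__ = ["SimConfig", "SyntheticPatient", "generate_patient", "generate_cohort", "AHI_STRATA"]

#: target-AHI ranges of the four severity strata (events/h)
AHI_STRATA = {
    "non-OSA": (0.0, 5.0),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, 90.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic recording.

    Residual factors are relative to the local breathing amplitude:
    apneas retain 5% of it, hypopneas a uniform draw from 30-70%.
    """

    duration_s: float = 1800.0
    fs: float = 128.0
    breath_rate_hz: float = 0.25
    breath_jitter: float = 0.10          # uniform +/- fraction per breath
    base_amplitude: float = 1.0
    amplitude_drift: float = 0.10        # log random-walk step sd per control point
    drift_step_s: float = 30.0
    baseline_drift: float = 0.10         # additive wander sd, relative to base amplitude
    baseline_step_s: float = 60.0
    noise_sd: float = 0.05               # white noise sd, relative to base amplitude
    apnea_residual: float = 0.05
    hypopnea_residual: tuple[float, float] = (0.3, 0.7)
    apnea_fraction: float = 0.5
    event_duration_s: tuple[float, float] = (10.0, 60.0)
    min_event_gap_s: float = 2.0
    ramp_s: float = 2.0
    target_ahi: float = 0.0
    n_detachments: int = 0
    detachment_duration_s: tuple[float, float] = (5.0, 15.0)
    detachments_overlap_events: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.breath_rate_hz <= 0:
            raise ValidationError("duration, fs and breathing rate must be positive")
        if not self.apnea_residual < self.hypopnea_residual[0]:
            raise ValidationError("apnea residual must lie below the hypopnea residual range")
        if self.event_duration_s[0] < 10.0:
            raise ValidationError("respiratory events must last at least 10 s")
        if self.target_ahi < 0:
            raise ValidationError("target AHI must be non-negative")


@dataclass
class SyntheticPatient:
    id: str
    config: SimConfig
    signal: SignalRecord
    annotations: AnnotationSet
    realized_ahi: float


def _schedule_events(config: SimConfig, rng: np.random.Generator) -> list[Event]:
    """Place non-overlapping events realizing the target AHI exactly."""
    hours = config.duration_s / 3600.0
    k = int(round(config.target_ahi * hours))
    if k == 0:
        return []
    dmin, dmax = config.event_duration_s
    gap = config.min_event_gap_s
    avail = config.duration_s - (k + 1) * gap
    if k * dmin > avail:
        raise ValidationError(
            f"target AHI {config.target_ahi} infeasible: {k} events of >= {dmin} s "
            f"do not fit in {config.duration_s} s"
        )
    durs = rng.uniform(dmin, dmax, size=k)
    total = durs.sum()
    if total > avail:
        # squeeze affinely toward the 10-s floor so the schedule fits
        durs = dmin + (durs - dmin) * (avail - k * dmin) / (total - k * dmin)
        total = durs.sum()
    free = config.duration_s - total - (k + 1) * gap
    gaps = gap + rng.dirichlet(np.ones(k + 1)) * free
    kinds = np.where(rng.random(k) < config.apnea_fraction, "apnea", "hypopnea")
    events, t = [], 0.0
    for g, d, kind in zip(gaps[:-1], durs, kinds):
        t += g
        events.append(Event(round(t, 6), round(float(d), 6), str(kind)))
        t += d
    return events


def _place_detachments(
    config: SimConfig, events: list[Event], rng: np.random.Generator
) -> list[Event]:
    """Drop detachment segments, by default into event-free stretches."""
    out: list[Event] = []
    lo_d, hi_d = config.detachment_duration_s
    for _ in range(config.n_detachments):
        dur = float(rng.uniform(lo_d, hi_d))
        if config.detachments_overlap_events or not events:
            onset = float(rng.uniform(0.0, max(config.duration_s - dur, 0.0)))
            out.append(Event(onset, dur, "artifact"))
            continue
        # candidate gaps between events (and recording edges) with room to spare
        bounds = [0.0] + [e.onset_s for e in events] + [config.duration_s]
        ends = [0.0] + [e.end_s for e in events]
        gaps = [
            (ends[i], bounds[i + 1])
            for i in range(len(ends))
            if bounds[i + 1] - ends[i] > dur + 2.0
        ]
        if not gaps:
            continue  # recording too dense; emit fewer segments
        lo, hi = gaps[rng.integers(len(gaps))]
        onset = float(rng.uniform(lo + 1.0, hi - dur - 1.0))
        out.append(Event(onset, dur, "artifact"))
    return sorted(out, key=lambda a: a.onset_s)


def _control_curve(
    n: int, fs: float, step_s: float, values: np.ndarray
) -> np.ndarray:
    """Smooth curve through control points spaced step_s apart."""
    t_ctrl = np.arange(values.size) * step_s
    t = np.arange(n) / fs
    if values.size == 1:
        return np.full(n, values[0])
    interp = PchipInterpolator(t_ctrl, values, extrapolate=True)
    return interp(np.clip(t, t_ctrl[0], t_ctrl[-1]))


def _event_factor(
    n: int, fs: float, events: list[Event], config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative amplitude factor with 2-s half-cosine ramps."""
    factor = np.ones(n)
    t = np.arange(n) / fs
    ramp = config.ramp_s
    for ev in events:
        residual = (
            config.apnea_residual
            if ev.kind == "apnea"
            else float(rng.uniform(*config.hypopnea_residual))
        )
        # depth profile: 0 outside, 1 in the event core, half-cosine edges
        inside = np.minimum(t - ev.onset_s, ev.end_s - t)
        if ramp > 0:
            depth = np.clip(inside / ramp, 0.0, 1.0)
            shape = 0.5 * (1.0 - np.cos(np.pi * depth))
        else:
            shape = (inside > 0).astype(np.float64)
        factor *= 1.0 - (1.0 - residual) * shape
    return factor


def generate_patient(config: SimConfig, patient_id: str = "P000") -> SyntheticPatient:
    """Synthesize one recording with its annotation ground truth.

    The realized AHI is the emitted event count divided by the recording
    duration in hours; with the exact scheduler it matches the target up
    to event-count rounding.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    events = _schedule_events(config, rng)
    detachments = _place_detachments(config, events, rng)

    # per-breath jittered phase
    n_breaths = int(np.ceil(config.duration_s * config.breath_rate_hz * (1 + config.breath_jitter))) + 2
    rates = config.breath_rate_hz * (
        1.0 + rng.uniform(-config.breath_jitter, config.breath_jitter, size=n_breaths)
    )
    periods = 1.0 / rates
    breath_starts = np.concatenate(([0.0], np.cumsum(periods)))
    t = np.arange(n) / config.fs
    which = np.clip(np.searchsorted(breath_starts, t, side="right") - 1, 0, n_breaths - 1)
    inst_freq = rates[which]
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / config.fs
    carrier = np.sin(phase)

    n_ctrl = int(np.ceil(config.duration_s / config.drift_step_s)) + 1
    log_amp = np.cumsum(rng.normal(0.0, config.amplitude_drift, size=n_ctrl))
    amplitude = config.base_amplitude * np.exp(_control_curve(n, config.fs, config.drift_step_s, log_amp))

    n_base = int(np.ceil(config.duration_s / config.baseline_step_s)) + 1
    base_pts = rng.normal(0.0, config.baseline_drift * config.base_amplitude, size=n_base)
    baseline = _control_curve(n, config.fs, config.baseline_step_s, base_pts)

    event_factor = _event_factor(n, config.fs, events, config, rng)
    detach_factor = np.ones(n)
    for a in detachments:
        lo = int(round(a.onset_s * config.fs))
        hi = min(int(round(a.end_s * config.fs)), n)
        detach_factor[lo:hi] = 0.0

    noise = rng.normal(0.0, config.noise_sd * config.base_amplitude, size=n)
    x = amplitude * event_factor * detach_factor * carrier + baseline * detach_factor + noise

    annotations = AnnotationSet(events=list(events), artifacts=detachments)
    realized_ahi = len(events) / (config.duration_s / 3600.0)
    return SyntheticPatient(patient_id, config, SignalRecord(x, config.fs), annotations, realized_ahi)


def generate_cohort(
    n_per_group: Sequence[int],
    template: SimConfig | None = None,
    seed: int = 0,
) -> list[SyntheticPatient]:
    """Generate a cohort stratified by OSA severity.

    ``n_per_group`` gives patient counts for (non-OSA, mild, moderate,
    severe); each patient's target AHI is drawn uniformly from its
    stratum's range and its seed derived from the master seed, so the
    cohort is a deterministic function of ``seed``.
    """
    if len(n_per_group) != 4 or any(c < 0 for c in n_per_group):
        raise ValidationError("n_per_group must be 4 non-negative counts")
    template = template or SimConfig()
    master = np.random.default_rng(seed)
    patients = []
    i = 0
    for (group, (lo, hi)), count in zip(AHI_STRATA.items(), n_per_group):
        for _ in range(count):
            target = float(master.uniform(lo, hi))
            child_seed = int(master.integers(0, 2**31 - 1))
            config = replace(template, target_ahi=target, seed=child_seed)
            patients.append(generate_patient(config, patient_id=f"S{i:03d}"))
            i += 1
    return patients
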