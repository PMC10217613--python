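"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force; never share code with src/)


def pairwise_auc_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + P(score+ = score-)/2."""
    pos = np.asarray(scores)[np.asarray(labels, dtype=bool)]
    neg = np.asarray(scores)[~np.asarray(labels, dtype=bool)]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (pos.size * neg.size))


def sliding_zscore_oracle(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Literal per-sample window recomputation of the sliding z-score."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    w = max(int(round(window_s * fs)), 1)
    out = np.zeros(n)
    for i in range(n):
        lo = max(i - w // 2, 0)
        hi = min(i + (w - w // 2), n)
        win = x[lo:hi]
        std = win.std()
        if std > 0:
            out[i] = (x[i] - win.mean()) / std
    return out


def summarize_oracle(diff: np.ndarray) -> tuple[float, float, float, float]:
    """Hand computation of AV/MD/SD/CoV with population SD."""
    x = np.sort(np.asarray(diff, dtype=np.float64))
    n = x.size
    av = x.sum() / n
    md = x[n // 2] if n % 2 else 0.5 * (x[n // 2 - 1] + x[n // 2])
    sd = float(np.sqrt(np.sum((x - av) ** 2) / n))
    cov = sd / av if av != 0 else (0.0 if sd == 0 else float("nan"))
    return av, md, sd, cov


def interval_union_oracle(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Brute-force union of half-open intervals via a fine boolean grid."""
    if not intervals:
        return []
    hi = max(b for _, b in intervals)
    grid = np.linspace(0, hi, 10001)
    member = np.zeros(grid.size, dtype=bool)
    for a, b in intervals:
        member |= (grid >= a) & (grid < b)
    out, start = [], None
    for g, m in zip(grid, member):
        if m and start is None:
            start = g
        elif not m and start is not None:
            out.append((start, g))
            start = None
    if start is not None:
        out.append((start, grid[-1]))
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230517)


def sinusoid(freq_hz: float, duration_s: float, fs: float, amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(duration_s * fs))) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t)


def write_minimal_edf(path, channels: dict[str, np.ndarray], fs: float) -> None:
    """Byte-level writer of a minimal EDF file (synthetic test fixture).

    Physical and digital ranges are both [-32768, 32767], so stored int16
    values round-trip exactly.
    """
    names = list(channels)
    data = [np.asarray(channels[k], dtype=np.int16) for k in names]
    n_sig = len(names)
    spr = int(fs)
    n_rec = len(data[0]) // spr

    def field(value, width: int) -> bytes:
        return str(value)[:width].ljust(width).encode("ascii")

    hdr = b"".join(
        [
            field("0", 8),
            field("X X X X", 80),
            field("Startdate 01-JAN-2020 X X X", 80),
            field("01.01.20", 8),
            field("00.00.00", 8),
            field(256 * (1 + n_sig), 8),
            field("", 44),
            field(n_rec, 8),
            field("1", 8),
            field(n_sig, 4),
        ]
    )
    for width, values in (
        (16, names),
        (80, [""] * n_sig),
        (8, [""] * n_sig),
        (8, [-32768] * n_sig),
        (8, [32767] * n_sig),
        (8, [-32768] * n_sig),
        (8, [32767] * n_sig),
        (80, [""] * n_sig),
        (8, [spr] * n_sig),
        (32, [""] * n_sig),
    ):
        hdr += b"".join(field(v, width) for v in values)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for d in data:
                fh.write(d[r * spr : (r + 1) * spr].astype("<i2").tobytes())
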