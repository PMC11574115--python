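"""Resting heart rate and time-domain HRV from the 2-min baseline beat series.

Beats are photoplethysmography-derived timestamps (ms); successive
differences give the RR interval series from which SDNN, RMSSD, pNN50 and
resting HR are computed. HRV is computed from the baseline only, never from
trial-period beats. No artifact correction is applied: RR intervals outside
the physiological band [300, 2000] ms trigger a warning but are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

PNN_THRESHOLD_MS = 50.0
RR_PLAUSIBLE_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class RRSeries:
    """Ordered beat-to-beat intervals (ms) from a baseline recording."""

    rr_ms: np.ndarray
    source: str = "baseline"

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "rr_ms", rr)
        if rr.ndim != 1:
            raise ValueError("rr_ms must be one-dimensional")
        if np.any(rr <= 0):
            raise ValueError("all RR intervals must be positive")
        lo, hi = RR_PLAUSIBLE_MS
        n_out = int(np.sum((rr < lo) | (rr > hi)))
        if n_out:
            msg = f"{n_out} RR interval(s) outside [{lo:.0f}, {hi:.0f}] ms; retained uncorrected"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)


@dataclass(frozen=True)
class HRVMetrics:
    sdnn_ms: float
    rmssd_ms: float
    pnn50_pct: float
    resting_hr_bpm: float


def timestamps_to_rr(beats_ms) -> RRSeries:
    """Successive differences of strictly increasing beat timestamps (ms)."""
    beats = np.asarray(beats_ms, dtype=float)
    if beats.size < 3:
        raise ValueError(f"need at least 3 beat timestamps, got {beats.size}")
    diffs = np.diff(beats)
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"beat timestamps not strictly increasing: beats[{i + 1}]={beats[i + 1]} "
            f"<= beats[{i}]={beats[i]}"
        )
    return RRSeries(rr_ms=diffs)


def _rr_array(rr, min_len: int, what: str) -> np.ndarray:
    arr = rr.rr_ms if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if arr.size < min_len:
        raise ValueError(f"{what} requires >= {min_len} RR intervals, got {arr.size}")
    return arr


def sdnn(rr) -> float:
    """Sample standard deviation (n-1 denominator) of the RR series, ms."""
    arr = _rr_array(rr, 2, "sdnn")
    return float(np.std(arr, ddof=1))


def rmssd(rr) -> float:
    """Root mean square of successive RR differences, ms."""
    arr = _rr_array(rr, 3, "rmssd")
    return float(np.sqrt(np.mean(np.diff(arr) ** 2)))


def pnn50(rr) -> float:
    """Percent of successive RR differences strictly exceeding 50 ms."""
    arr = _rr_array(rr, 3, "pnn50")
    d = np.abs(np.diff(arr))
    return float(100.0 * np.mean(d > PNN_THRESHOLD_MS))


def resting_hr(rr) -> float:
    """Mean heart rate in bpm: 60000 / mean RR (ms)."""
    arr = _rr_array(rr, 2, "resting_hr")
    return float(60000.0 / np.mean(arr))


def baseline_hrv(beats_ms) -> HRVMetrics:
    """All time-domain metrics from one baseline beat-timestamp series."""
    rr = timestamps_to_rr(beats_ms)
    return HRVMetrics(
        sdnn_ms=sdnn(rr),
        rmssd_ms=rmssd(rr),
        pnn50_pct=pnn50(rr),
        resting_hr_bpm=resting_hr(rr),
    )
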