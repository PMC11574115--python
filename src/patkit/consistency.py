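"""Circular consistency scoring for Phase Adjustment Task sessions.

Each PAT trial ends with a selected tone delay (ms). Relative to the
concurrent cardiac cycle of length ``rr_reference_ms`` the delay maps to a
phase angle on [0, 2pi). Cross-trial agreement of those angles is summarised
by the mean resultant length: 1 when every trial lands on the same phase,
near 0 when phases are scattered uniformly around the circle. That scalar is
the participant's consistency score and the basis for the
interoceptive / non-interoceptive classification downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .ingest_qc import RawSession

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ConsistencyScore:
    """Cross-trial phase-agreement summary for one scored session."""

    value: float
    n_trials: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"consistency score {self.value} outside [0, 1]")


def delay_to_phase(selected_delay_ms: float, rr_reference_ms: float) -> float:
    """Map a tone delay to its phase angle within the cardiac cycle.

    theta = 2pi * ((delay mod RR) / RR), in radians on [0, 2pi). Delays
    longer than one cycle wrap: a 1000 ms delay at RR = 800 ms is a quarter
    cycle (pi/2).
    """
    if rr_reference_ms <= 0:
        raise ValueError(f"rr_reference_ms must be positive, got {rr_reference_ms}")
    if selected_delay_ms < 0:
        raise ValueError(f"selected_delay_ms must be non-negative, got {selected_delay_ms}")
    return TWO_PI * ((selected_delay_ms % rr_reference_ms) / rr_reference_ms)


def mean_resultant_length(angles: Iterable[float]) -> float:
    """Mean resultant length of a set of angles (radians).

    The magnitude of the average unit vector: ``|mean(exp(i*theta))|``.
    Equals 1 for identical angles and tends to 0 as angles disperse
    uniformly; for n uniform angles the expectation is ~ sqrt(pi / (4 n)).
    """
    theta = np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles, dtype=float)
    if theta.size == 0:
        raise ValueError("mean_resultant_length requires at least one angle")
    return float(np.hypot(np.mean(np.cos(theta)), np.mean(np.sin(theta))))


def session_consistency(session: "RawSession") -> ConsistencyScore:
    """Score a QC-passed session: MRL of the per-trial phase angles.

    Every retained trial must carry a selected delay and a positive
    ``rr_reference_ms`` (the mean RR over the trial's own beats); trials
    missing the reference are reported by index.
    """
    missing = [t.index for t in session.trials if t.rr_reference_ms is None or t.rr_reference_ms <= 0]
    if missing:
        raise ValueError(
            f"session {session.participant_id!r}: trials missing rr_reference_ms: {missing}"
        )
    angles = [delay_to_phase(t.selected_delay_ms, t.rr_reference_ms) for t in session.trials]
    return ConsistencyScore(value=mean_resultant_length(angles), n_trials=len(angles))
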