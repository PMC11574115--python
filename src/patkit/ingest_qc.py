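"""Session ingestion and trial-level quality control.

The smartphone app stores one JSON record per participant x task (screener
or PAT): a 2-min baseline beat series plus an ordered trial list. The
canonical schema is defined here by the pydantic models (documented in
``docs/session_schema.md``) and the parser is strict: missing or malformed
keys raise :class:`SessionParseError` naming the offending key.

The QC cascade mirrors the study's pre-registered exclusion rules:

1. drop practice trials (explicit ``is_practice`` flags preferred; if a
   session carries no flags the first 2 trials are dropped positionally,
   with a log message);
2. drop trials with <= 4 heart-rate samples (lack of engagement);
3. drop trials whose dial never left its default position ("0 delays");
4. exclude participants with < 17 valid trials, otherwise keep exactly the
   first 17 valid trials in task order;
5. gate screener sessions at a consistency cutoff of 0.42 (strict ``<``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pydantic
from pydantic import BaseModel, Field

logger = logging.getLogger(__name__)

MIN_VALID_TRIALS = 17
MIN_HR_SAMPLES = 5  # trials with <= 4 heart-rate values are removed
SCREENER_CUTOFF = 0.42
N_PRACTICE_FALLBACK = 2
EXPECTED_TASK_TRIALS = 20


class SessionParseError(ValueError):
    """Raised when session JSON is malformed or violates the schema."""


class Trial(BaseModel):
    """One adjustment trial as recorded by the app."""

    model_config = pydantic.ConfigDict(extra="forbid")

    index: int = Field(ge=0)
    is_practice: Optional[bool] = None
    hr_samples: list[float]
    delay_trajectory: list[float]
    selected_delay_ms: float = Field(ge=0)
    rr_reference_ms: Optional[float] = None
    default_delay_ms: float = 0.0
    duration_s: float = Field(ge=0)
    confidence: int = Field(ge=0, le=9)
    meta: dict = Field(default_factory=dict)

    @pydantic.field_validator("rr_reference_ms")
    @classmethod
    def _rr_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("rr_reference_ms must be positive when present")
        return v


class RawSession(BaseModel):
    """One participant x task record: baseline beats plus ordered trials."""

    model_config = pydantic.ConfigDict(extra="forbid")

    participant_id: str
    task: Literal["screener", "pat"]
    baseline_beats_ms: list[float]
    trials: list[Trial]
    meta: dict = Field(default_factory=dict)

    @pydantic.field_validator("baseline_beats_ms")
    @classmethod
    def _increasing(cls, v):
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("baseline_beats_ms must be strictly increasing")
        return v

    @pydantic.field_validator("trials")
    @classmethod
    def _ordered(cls, v):
        idx = [t.index for t in v]
        if idx != sorted(idx):
            raise ValueError("trials must be ordered by index")
        return v


@dataclass(frozen=True)
class QCReport:
    """Per-session accounting of the QC cascade; counts always reconcile."""

    participant_id: str
    task: str
    n_trials_in: int
    n_practice_removed: int
    n_removed_few_samples: int
    n_removed_zero_delays: int
    n_valid: int
    passed: bool
    reason: str = ""

    def __post_init__(self) -> None:
        removed = self.n_practice_removed + self.n_removed_few_samples + self.n_removed_zero_delays
        if self.n_valid != self.n_trials_in - removed:
            raise ValueError("QCReport counts do not reconcile")


@dataclass(frozen=True)
class EngagementMetrics:
    """Aggregate engagement over the retained trials.

    ``n_valid_trials`` is the pre-truncation valid-trial count (out of the
    20 task trials), matching how the study tabulates engagement.
    """

    mean_time_per_trial_s: float
    mean_dial_turns: float
    n_valid_trials: int


def parse_session(text: str) -> RawSession:
    """Parse canonical session JSON; errors name the offending key."""
    try:
        return RawSession.model_validate_json(text)
    except pydantic.ValidationError as e:
        locs = ", ".join(".".join(str(p) for p in err["loc"]) or "<root>" for err in e.errors())
        raise SessionParseError(f"invalid session record (keys: {locs}): {e}") from e
    except json.JSONDecodeError as e:  # pragma: no cover - pydantic wraps most
        raise SessionParseError(f"malformed JSON: {e}") from e


def write_session(session: RawSession) -> str:
    """Serialize to canonical JSON (inverse of :func:`parse_session`)."""
    return session.model_dump_json(indent=1)


def remove_practice(session: RawSession) -> RawSession:
    """Drop practice trials (explicit flags; positional first-2 fallback)."""
    if any(t.is_practice is not None for t in session.trials):
        kept = [t for t in session.trials if not t.is_practice]
    else:
        if session.trials:
            logger.info(
                "session %s/%s: no practice flags, removing first %d trials positionally",
                session.participant_id, session.task, N_PRACTICE_FALLBACK,
            )
        kept = session.trials[N_PRACTICE_FALLBACK:]
    return session.model_copy(update={"trials": kept})


def _dial_untouched(trial: Trial) -> bool:
    # "0 delays": the dial never left its default position — an empty
    # trajectory, or one whose every entry equals the default.
    return all(d == trial.default_delay_ms for d in trial.delay_trajectory)


def filter_valid_trials(session: RawSession) -> tuple[RawSession, QCReport]:
    """Apply the trial-level validity filters (practice already removed).

    Removal reasons are counted in the order the study applies them: the
    heart-rate check first, then the untouched-dial check.
    """
    kept: list[Trial] = []
    n_few = n_zero = 0
    for t in session.trials:
        if len(t.hr_samples) < MIN_HR_SAMPLES:
            n_few += 1
        elif _dial_untouched(t):
            n_zero += 1
        else:
            kept.append(t)
    report = QCReport(
        participant_id=session.participant_id,
        task=session.task,
        n_trials_in=len(session.trials),
        n_practice_removed=0,
        n_removed_few_samples=n_few,
        n_removed_zero_delays=n_zero,
        n_valid=len(kept),
        passed=len(kept) >= MIN_VALID_TRIALS,
        reason="" if len(kept) >= MIN_VALID_TRIALS else f"< {MIN_VALID_TRIALS} valid trials",
    )
    return session.model_copy(update={"trials": kept}), report


def enforce_min_and_truncate(
    session: RawSession, min_trials: int = MIN_VALID_TRIALS
) -> Optional[RawSession]:
    """Keep the first ``min_trials`` valid trials in task order, or exclude.

    Returns ``None`` when the participant has too few valid trials
    (exclusion is a value, not an error).
    """
    if len(session.trials) < min_trials:
        return None
    return session.model_copy(update={"trials": session.trials[:min_trials]})


def run_qc(
    session: RawSession, min_trials: int = MIN_VALID_TRIALS
) -> tuple[Optional[RawSession], QCReport]:
    """Full cascade: practice removal -> validity filters -> min/truncate."""
    n_in = len(session.trials)
    if n_in > N_PRACTICE_FALLBACK + EXPECTED_TASK_TRIALS:
        logger.warning(
            "session %s/%s: %d trials recorded (> %d expected)",
            session.participant_id, session.task, n_in,
            N_PRACTICE_FALLBACK + EXPECTED_TASK_TRIALS,
        )
    no_practice = remove_practice(session)
    filtered, rep = filter_valid_trials(no_practice)
    report = QCReport(
        participant_id=rep.participant_id,
        task=rep.task,
        n_trials_in=n_in,
        n_practice_removed=n_in - len(no_practice.trials),
        n_removed_few_samples=rep.n_removed_few_samples,
        n_removed_zero_delays=rep.n_removed_zero_delays,
        n_valid=rep.n_valid,
        passed=rep.n_valid >= min_trials,
        reason="" if rep.n_valid >= min_trials else f"< {min_trials} valid trials",
    )
    return enforce_min_and_truncate(filtered, min_trials), report


def engagement(session: RawSession, n_valid_trials: Optional[int] = None) -> EngagementMetrics:
    """Aggregate engagement metrics over the retained (truncated) trials.

    Dial turns per trial = number of unique values in the delay trajectory.
    """
    if not session.trials:
        raise ValueError("engagement requires a session with retained trials")
    durations = [t.duration_s for t in session.trials]
    turns = [len(set(t.delay_trajectory)) for t in session.trials]
    return EngagementMetrics(
        mean_time_per_trial_s=float(np.mean(durations)),
        mean_dial_turns=float(np.mean(turns)),
        n_valid_trials=len(session.trials) if n_valid_trials is None else n_valid_trials,
    )


def screener_gate(screener_score: float, cutoff: float = SCREENER_CUTOFF) -> bool:
    """True if retained; excluded iff score < cutoff (strict).

    Applies to screener sessions only — PAT sessions are never gated on
    their own score.
    """
    if not 0.0 <= screener_score <= 1.0:
        raise ValueError(f"screener score {screener_score} outside [0, 1]")
    return screener_score >= cutoff
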