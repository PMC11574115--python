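"""Synthetic Phase Adjustment Task cohorts with known ground truth.

The generator emulates the smartphone app's output: per participant a 2-min
baseline beat series plus 2 practice and 20 task trials, each with
heart-rate samples, a dial-delay trajectory, a selected delay, a duration
and a confidence rating. Interoceptive participants select delays whose
implied cardiac phase is von Mises-concentrated around a preferred phase;
non-interoceptive participants respond uniformly on the circle (kappa = 0).
A fraction of trials is injected as invalid — too few heart-rate samples,
or an untouched dial — and labelled in the trial metadata so the QC
cascade's precision and recall are testable by construction.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical configs give byte-identical cohorts.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
import pydantic
from pydantic import BaseModel, Field

from .consistency import TWO_PI
from .ingest_qc import RawSession, Trial

RR_FLOOR_MS = 300.0
DIAL_TURNS_LAMBDA = 27.0  # unique dial positions per trial, study-scale
TRIAL_DURATION_MEAN_S = 21.6
TRIAL_DURATION_SD_S = 11.0

InvalidMode = Literal["few_samples", "untouched_dial"]


class SimulationConfig(BaseModel):
    """Study conditions for one simulated cohort.

    Defaults reproduce the magnitudes of the remote-vs-laboratory study:
    ~75 bpm resting heart rate, ~4.5% invalid task trials (about 19 valid
    of 20), and a 40% interoceptive fraction whose concentration kappa in
    [0.8, 2] yields 17-trial consistency scores in the mid-0.5s while uniform
    responders centre near the 0.215 Rayleigh expectation.
    """

    model_config = pydantic.ConfigDict(extra="forbid")

    n_participants: int = Field(default=100, ge=0)
    prop_interoceptive: float = Field(default=0.4, ge=0.0, le=1.0)
    kappa_range: tuple[float, float] = (0.8, 2.0)
    mu_phase: Optional[float] = Field(default=None, ge=0.0, lt=TWO_PI)
    rr_mean_ms: float = Field(default=800.0, gt=0)
    rr_sd_ms: float = Field(default=50.0, ge=0)
    n_task_trials: int = Field(default=20, ge=0)
    n_practice: int = Field(default=2, ge=0)
    baseline_duration_s: float = Field(default=120.0, gt=0)
    p_invalid_trial: float = Field(default=0.045, ge=0.0, le=1.0)
    # The screener is an exteroceptive tone-matching task: performance
    # reflects task adherence, not interoception, so adherent participants
    # respond concentrated on it whatever their interoceptive status.
    screener_kappa_range: tuple[float, float] = (2.0, 6.0)
    p_non_adherent: float = Field(default=0.05, ge=0.0, le=1.0)
    group: Literal["laboratory", "remote"] = "laboratory"
    age_mean: float = 23.1
    age_sd: float = 7.7
    seed: int = 0

    @pydantic.field_validator("kappa_range")
    @classmethod
    def _kappa_ok(cls, v):
        lo, hi = v
        if lo <= 0 or hi < lo:
            raise ValueError("kappa_range must satisfy 0 < lo <= hi")
        return v


class ParticipantProfile(BaseModel):
    """Ground truth for one simulated participant."""

    model_config = pydantic.ConfigDict(extra="forbid")

    participant_id: str
    is_interoceptive: bool
    kappa: float = Field(ge=0)
    mu_phase: float = Field(ge=0, lt=TWO_PI)
    age: float
    sex: Literal["female", "male"]
    group: Literal["laboratory", "remote"]

    @pydantic.model_validator(mode="after")
    def _uniform_iff_kappa_zero(self):
        if not self.is_interoceptive and self.kappa != 0:
            raise ValueError("non-interoceptive participants must have kappa = 0")
        return self


def simulate_rr_series(
    rr_mean_ms: float, rr_sd_ms: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Beat timestamps (ms) with truncated-normal RR intervals.

    Intervals are normal(rr_mean_ms, rr_sd_ms) truncated below at 300 ms
    (rejection sampling); timestamps start at the first beat and cover
    ``duration_s`` seconds.
    """
    if rr_mean_ms <= 0:
        raise ValueError(f"rr_mean_ms must be positive, got {rr_mean_ms}")
    if rr_sd_ms < 0:
        raise ValueError(f"rr_sd_ms must be non-negative, got {rr_sd_ms}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    duration_ms = duration_s * 1000.0
    intervals: list[float] = []
    total = 0.0
    while total < duration_ms:
        r = float(rng.normal(rr_mean_ms, rr_sd_ms)) if rr_sd_ms > 0 else rr_mean_ms
        if r < RR_FLOOR_MS:
            continue
        intervals.append(r)
        total += r
    return np.cumsum(intervals)


def sample_response_phase(profile: ParticipantProfile, rng: np.random.Generator) -> float:
    """One trial's selected phase angle, radians in [0, 2pi).

    von Mises(mu_phase, kappa) for interoceptive participants, uniform for
    non-interoceptive (kappa = 0).
    """
    if profile.is_interoceptive and profile.kappa > 0:
        theta = float(rng.vonmises(profile.mu_phase, profile.kappa))
    else:
        theta = float(rng.uniform(-np.pi, np.pi))
    return theta % TWO_PI


def phase_to_delay(angle: float, rr_ms: float) -> float:
    """Invert the delay-to-phase map: delay = (angle / 2pi) * RR, in [0, RR)."""
    if rr_ms <= 0:
        raise ValueError(f"rr_ms must be positive, got {rr_ms}")
    if not 0.0 <= angle < TWO_PI:
        raise ValueError(f"angle {angle} outside [0, 2pi)")
    return angle / TWO_PI * rr_ms


def _dial_trajectory(
    selected_delay: float, rr_ms: float, rng: np.random.Generator
) -> list[float]:
    # Random walk over delay values ending at the selected delay; the number
    # of unique positions is Poisson(27) + 1 to match study magnitudes.
    n_moves = int(rng.poisson(DIAL_TURNS_LAMBDA)) + 1
    steps = rng.normal(0.0, rr_ms / 12.0, size=n_moves - 1)
    start = selected_delay - steps.sum()
    walk = start + np.concatenate([[0.0], np.cumsum(steps)])
    return [float(np.round(d % rr_ms, 3)) for d in walk]


def simulate_trial(
    profile: ParticipantProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    index: int = 0,
    is_practice: bool = False,
    invalid_mode: Optional[InvalidMode] = None,
) -> Trial:
    """One adjustment trial; ``invalid_mode`` forces a QC-failing trial."""
    # 2 s floor + gamma bulk, keeping the study-scale mean/SD of ~21.6/11 s.
    bulk = TRIAL_DURATION_MEAN_S - 2.0
    duration = 2.0 + float(
        rng.gamma((bulk / TRIAL_DURATION_SD_S) ** 2, TRIAL_DURATION_SD_S**2 / bulk)
    )
    rr_ref = float(rng.normal(config.rr_mean_ms, config.rr_sd_ms / 4.0))
    rr_ref = max(rr_ref, RR_FLOOR_MS)
    hr_nominal = 60000.0 / rr_ref
    n_hr = max(5, int(round(duration)))
    hr_samples = list(np.round(hr_nominal + rng.normal(0, 2.0, size=n_hr), 1))

    theta = sample_response_phase(profile, rng)
    selected = phase_to_delay(theta, rr_ref)
    trajectory = _dial_trajectory(selected, rr_ref, rng)

    meta: dict = {}
    if invalid_mode == "few_samples":
        hr_samples = hr_samples[: int(rng.integers(0, 5))]
        meta["injected_invalid"] = "few_samples"
    elif invalid_mode == "untouched_dial":
        trajectory = []
        selected = 0.0
        meta["injected_invalid"] = "untouched_dial"

    return Trial(
        index=index,
        is_practice=is_practice,
        hr_samples=[float(h) for h in hr_samples],
        delay_trajectory=trajectory,
        selected_delay_ms=float(selected),
        rr_reference_ms=rr_ref,
        duration_s=duration,
        confidence=int(rng.integers(0, 10)),
        meta=meta,
    )


def simulate_session(
    profile: ParticipantProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    task: Literal["screener", "pat"] = "pat",
) -> RawSession:
    """One participant x task record: baseline plus practice and task trials."""
    beats = simulate_rr_series(
        config.rr_mean_ms, config.rr_sd_ms, config.baseline_duration_s, rng
    )
    trials = []
    for i in range(config.n_practice):
        trials.append(simulate_trial(profile, config, rng, index=i, is_practice=True))
    for j in range(config.n_task_trials):
        mode: Optional[InvalidMode] = None
        if rng.uniform() < config.p_invalid_trial:
            mode = "few_samples" if rng.uniform() < 0.5 else "untouched_dial"
        trials.append(
            simulate_trial(
                profile, config, rng, index=config.n_practice + j, invalid_mode=mode
            )
        )
    return RawSession(
        participant_id=profile.participant_id,
        task=task,
        baseline_beats_ms=[float(b) for b in beats],
        trials=trials,
        meta={
            "group": profile.group,
            "age": profile.age,
            "sex": profile.sex,
            "simulated": True,
        },
    )


def simulate_cohort(config: SimulationConfig) -> tuple[list[RawSession], pd.DataFrame]:
    """Simulate a cohort: screener + PAT session per participant.

    Returns the session list (screener then PAT per participant) and a
    ground-truth table (participant_id, group, is_interoceptive, kappa,
    mu_phase, age, sex).
    """
    rng = np.random.default_rng(config.seed)
    sessions: list[RawSession] = []
    truth_rows = []
    for i in range(config.n_participants):
        pid = f"{config.group[:3]}_{i:04d}"
        is_intero = bool(rng.uniform() < config.prop_interoceptive)
        kappa = float(rng.uniform(*config.kappa_range)) if is_intero else 0.0
        mu = (
            float(config.mu_phase)
            if config.mu_phase is not None
            else float(rng.uniform(0.0, TWO_PI))
        )
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 65.0))
        adherent = bool(rng.uniform() >= config.p_non_adherent)
        screener_kappa = float(rng.uniform(*config.screener_kappa_range)) if adherent else 0.0
        profile = ParticipantProfile(
            participant_id=pid,
            is_interoceptive=is_intero,
            kappa=kappa,
            mu_phase=mu,
            age=age,
            sex="female" if rng.uniform() < 0.55 else "male",
            group=config.group,
        )
        screener_profile = profile.model_copy(
            update={"is_interoceptive": adherent, "kappa": screener_kappa}
        )
        sessions.append(simulate_session(screener_profile, config, rng, task="screener"))
        sessions.append(simulate_session(profile, config, rng, task="pat"))
        truth_rows.append(
            {
                "participant_id": pid,
                "group": profile.group,
                "is_interoceptive": is_intero,
                "kappa": kappa,
                "mu_phase": mu,
                "age": age,
                "sex": profile.sex,
                "adherent": adherent,
                "screener_kappa": screener_kappa,
            }
        )
    columns = [
        "participant_id", "group", "is_interoceptive", "kappa", "mu_phase",
        "age", "sex", "adherent", "screener_kappa",
    ]
    return sessions, pd.DataFrame(truth_rows, columns=columns)
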