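import numpy as np
import pytest
from hypothesis import settings

from patkit.ingest_qc import RawSession, Trial

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_trial():
    """Builder for schema-valid trials with sensible defaults."""

    def _make(
        index=0,
        is_practice=False,
        n_hr=10,
        delay_trajectory=None,
        selected_delay_ms=400.0,
        rr_reference_ms=800.0,
        duration_s=20.0,
        confidence=5,
        **overrides,
    ):
        if delay_trajectory is None:
            delay_trajectory = [100.0, 250.0, selected_delay_ms]
        return Trial(
            index=index,
            is_practice=is_practice,
            hr_samples=[75.0] * n_hr,
            delay_trajectory=delay_trajectory,
            selected_delay_ms=selected_delay_ms,
            rr_reference_ms=rr_reference_ms,
            duration_s=duration_s,
            confidence=confidence,
            **overrides,
        )

    return _make


@pytest.fixture
def make_session(make_trial):
    """Builder for sessions: 2 practice + n_task trials by default."""

    def _make(n_task=20, n_practice=2, task="pat", trials=None, **session_kw):
        if trials is None:
            trials = [
                make_trial(index=i, is_practice=i < n_practice)
                for i in range(n_practice + n_task)
            ]
        beats = [float(b) for b in np.arange(0.0, 120_000.0, 800.0)]
        return RawSession(
            participant_id=session_kw.pop("participant_id", "p001"),
            task=task,
            baseline_beats_ms=beats,
            trials=trials,
            **session_kw,
        )

    return _make
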