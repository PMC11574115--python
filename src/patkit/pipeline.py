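"""End-to-end orchestration: simulate/load -> QC -> score -> HRV -> classify -> compare.

A run is fully described by a :class:`RunConfig` (arm, thresholds, seed,
input or simulation settings). All stage outputs are written as CSV under
the output directory and a JSON manifest records the seed, thresholds and
participant counts at every exclusion step, mirroring the study's
participant-flow accounting. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import pydantic
from pydantic import BaseModel, Field

from . import classification, consistency, group_compare, ingest_qc, physiology
from .synthetic_data import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


class CohortSimSpec(BaseModel):
    """Two-group simulation settings for a pipeline run."""

    model_config = pydantic.ConfigDict(extra="forbid")

    n_laboratory: int = Field(default=100, ge=0)
    n_remote: int = Field(default=143, ge=0)
    prop_interoceptive: float = Field(default=0.4, ge=0, le=1)
    kappa_range: tuple[float, float] = (0.8, 2.0)
    p_invalid_trial: float = Field(default=0.045, ge=0, le=1)


class RunConfig(BaseModel):
    """One reproducible pipeline run."""

    model_config = pydantic.ConfigDict(extra="forbid")

    input_dir: Optional[Path] = None
    simulation: Optional[CohortSimSpec] = None
    arm: Literal["screened", "unscreened"] = "screened"
    thresholds: tuple[float, ...] = classification.BF_THRESHOLDS
    min_trials: int = ingest_qc.MIN_VALID_TRIALS
    screener_cutoff: float = ingest_qc.SCREENER_CUTOFF
    match_age: bool = True
    seed: int = 0
    out_dir: Path = Path("patkit_run")

    @pydantic.model_validator(mode="after")
    def _one_source(self):
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("specify exactly one of input_dir or simulation")
        return self


def load_sessions(input_dir: Path) -> list[ingest_qc.RawSession]:
    """Parse every ``*.json`` session file in a directory (sorted order)."""
    files = sorted(Path(input_dir).glob("*.json"))
    if not files:
        raise FileNotFoundError(f"no session JSON files found in {input_dir}")
    return [ingest_qc.parse_session(f.read_text()) for f in files]


def _simulate_two_groups(sim: CohortSimSpec, seed: int) -> list[ingest_qc.RawSession]:
    common = dict(
        prop_interoceptive=sim.prop_interoceptive,
        kappa_range=sim.kappa_range,
        p_invalid_trial=sim.p_invalid_trial,
    )
    lab_cfg = SimulationConfig(
        n_participants=sim.n_laboratory, group="laboratory",
        age_mean=23.1, age_sd=7.7, seed=seed, **common,
    )
    rem_cfg = SimulationConfig(
        n_participants=sim.n_remote, group="remote",
        age_mean=31.0, age_sd=9.4, seed=seed + 1, **common,
    )
    lab_sessions, _ = simulate_cohort(lab_cfg)
    rem_sessions, _ = simulate_cohort(rem_cfg)
    return lab_sessions + rem_sessions


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sessions = _simulate_two_groups(config.simulation, config.seed)
    else:
        sessions = load_sessions(config.input_dir)

    by_participant: dict[str, dict[str, ingest_qc.RawSession]] = {}
    for s in sessions:
        by_participant.setdefault(s.participant_id, {})[s.task] = s

    qc_rows, score_rows, hrv_rows, cohort_rows = [], [], [], []
    screener_scores: dict[str, float] = {}
    pat_sessions: dict[str, ingest_qc.RawSession] = {}
    n_pat_in = n_pat_valid = 0

    for pid in sorted(by_participant):
        tasks = by_participant[pid]
        for task, session in sorted(tasks.items()):
            kept, report = ingest_qc.run_qc(session, min_trials=config.min_trials)
            qc_rows.append(report.__dict__)
            if task == "pat":
                n_pat_in += 1
            if kept is None:
                continue
            score = consistency.session_consistency(kept)
            score_rows.append(
                {
                    "participant_id": pid,
                    "task": task,
                    "consistency": score.value,
                    "n_trials": score.n_trials,
                }
            )
            if task == "screener":
                screener_scores[pid] = score.value
            else:
                n_pat_valid += 1
                pat_sessions[pid] = kept
                eng = ingest_qc.engagement(kept, n_valid_trials=report.n_valid)
                hrv = physiology.baseline_hrv(session.baseline_beats_ms)
                hrv_rows.append({"participant_id": pid, **hrv.__dict__})
                cohort_rows.append(
                    {
                        "participant_id": pid,
                        "group": session.meta.get("group"),
                        "age": session.meta.get("age"),
                        "sex": session.meta.get("sex"),
                        "consistency": score.value,
                        "mean_time_per_trial_s": eng.mean_time_per_trial_s,
                        "mean_dial_turns": eng.mean_dial_turns,
                        "n_valid_trials": eng.n_valid_trials,
                        **hrv.__dict__,
                    }
                )

    cohort = pd.DataFrame(cohort_rows)
    if cohort.empty:
        raise ValueError("no participant passed PAT quality control")

    # Arm selection: screened requires a valid screener passing the cutoff.
    n_screener_fail = 0
    if config.arm == "screened":
        retained = []
        for pid in cohort["participant_id"]:
            sc = screener_scores.get(pid)
            ok = sc is not None and ingest_qc.screener_gate(sc, config.screener_cutoff)
            if not ok:
                n_screener_fail += 1
            retained.append(ok)
        cohort = cohort.loc[retained].reset_index(drop=True)
    if cohort.empty:
        raise ValueError("no participant remains in the selected arm")

    # Pooled mixture fit across laboratory + remote together.
    params = classification.fit_two_component_gmm(cohort["consistency"].to_numpy())
    memberships = {
        pid: classification.membership(score, params)
        for pid, score in zip(cohort["participant_id"], cohort["consistency"])
    }
    groups = dict(zip(cohort["participant_id"], cohort["group"]))
    counts = classification.classification_table(memberships, groups, config.thresholds)

    mem_rows = [
        {"participant_id": pid, **m.__dict__} for pid, m in memberships.items()
    ]
    cohort = cohort.merge(
        pd.DataFrame(mem_rows)[["participant_id", "bf", "label_bf3", "label_bf10", "label_bf30"]],
        on="participant_id",
    )

    comparisons = {f"unmatched/{k}": v for k, v in group_compare.compare_groups(cohort).items()}
    label_order = ["non-interoceptive", "unclassified", "interoceptive"]
    for thr in config.thresholds:
        sub = counts[counts["threshold"] == thr].set_index("group")
        table = sub.loc[["laboratory", "remote"], label_order].to_numpy()
        try:
            comparisons[f"unmatched/classification_bf{thr:g}"] = group_compare.chi_square(table)
        except ValueError as e:
            logger.warning("chi-square skipped at BF%g: %s", thr, e)

    matched = group_compare.age_match(cohort) if config.match_age else cohort
    if config.match_age:
        comparisons.update(
            {f"matched/{k}": v for k, v in group_compare.compare_groups(matched).items()}
        )
        matched_counts = classification.classification_table(
            {pid: memberships[pid] for pid in matched["participant_id"]},
            dict(zip(matched["participant_id"], matched["group"])),
            config.thresholds,
        )
    else:
        matched_counts = counts

    # Write stage outputs.
    pd.DataFrame(qc_rows).to_csv(out / "qc_reports.csv", index=False)
    pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)
    pd.DataFrame(hrv_rows).to_csv(out / "hrv.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(mem_rows).to_csv(out / "memberships.csv", index=False)
    counts.to_csv(out / "classification_counts.csv", index=False)
    matched_counts.to_csv(out / "classification_counts_matched.csv", index=False)
    comp_rows = [
        {
            "comparison": name,
            "test": r.test,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "n_laboratory": r.n_per_group[0] if r.n_per_group else None,
            "n_remote": r.n_per_group[1] if len(r.n_per_group) > 1 else None,
        }
        for name, r in comparisons.items()
    ]
    pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)

    manifest = {
        "seed": config.seed,
        "arm": config.arm,
        "thresholds": list(config.thresholds),
        "min_trials": config.min_trials,
        "screener_cutoff": config.screener_cutoff,
        "counts": {
            "sessions_in": len(sessions),
            "participants_in": len(by_participant),
            "pat_sessions_in": n_pat_in,
            "pat_valid": n_pat_valid,
            "screener_gate_excluded": n_screener_fail,
            "arm_n": int(len(set(cohort["participant_id"]))),
            "arm_n_laboratory": int((cohort["group"] == "laboratory").sum()),
            "arm_n_remote": int((cohort["group"] == "remote").sum()),
            "age_matched_n": int(len(matched)),
        },
        "mixture": {
            "w_N": params.w_N, "w_I": params.w_I,
            "mu_N": params.mu_N, "mu_I": params.mu_I,
            "sigma_N": params.sigma_N, "sigma_I": params.sigma_I,
            "loglik": params.loglik, "n_iter": params.n_iter,
            "degenerate": params.degenerate,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
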