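"""Laboratory-vs-remote group comparisons on the participant-level table.

Implements the study's analysis arms: age matching of the two cohorts,
pooled-variance t-tests on consistency scores, Mann-Whitney U (normal
approximation with tie correction, as SPSS reports) for engagement, HRV and
age, Pearson chi-square (no continuity correction) on sex and on
classification counts, and a control analysis that regresses resting heart
rate and RMSSD out of the consistency scores before re-testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

LAB_MIN_AGE = 19.0  # laboratory rows under 19 removed
REMOTE_MAX_AGE = 30.0  # remote rows aged 30 and over removed
LAB_OUTLIER_AGE = 63.0  # single laboratory age outlier bound (inclusive)


@dataclass(frozen=True)
class ComparisonReport:
    """One statistical comparison, with the descriptives the study tabulates."""

    test: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    n_per_group: tuple[int, ...] = ()
    group_means: tuple[float, ...] = ()
    group_sds: tuple[float, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def age_match(
    cohort: pd.DataFrame,
    lab_min_age: float = LAB_MIN_AGE,
    remote_max_age: float = REMOTE_MAX_AGE,
    lab_outlier_age: Optional[float] = LAB_OUTLIER_AGE,
) -> pd.DataFrame:
    """Match the cohorts on age at the group level.

    Removes remote rows aged ``remote_max_age`` and over, laboratory rows
    under ``lab_min_age``, and laboratory rows at or above the outlier
    bound. Idempotent.
    """
    if cohort["age"].isna().any():
        ids = cohort.loc[cohort["age"].isna(), "participant_id"].tolist()
        raise ValueError(f"missing ages for participants: {ids}")
    lab = cohort["group"] == "laboratory"
    remote = cohort["group"] == "remote"
    keep = ~(
        (remote & (cohort["age"] >= remote_max_age))
        | (lab & (cohort["age"] < lab_min_age))
    )
    if lab_outlier_age is not None:
        keep &= ~(lab & (cohort["age"] >= lab_outlier_age))
    return cohort.loc[keep].reset_index(drop=True)


def students_t(x, y, pooled: bool = True) -> ComparisonReport:
    """Two-sample t-test, pooled-variance by default (df = n1 + n2 - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    df = x.size + y.size - 2 if pooled else float(res.df)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return ComparisonReport(
        test="students_t" if pooled else "welch_t",
        statistic=t,
        p_value=p,
        df=float(df),
        n_per_group=(x.size, y.size),
        group_means=(float(x.mean()), float(y.mean())),
        group_sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
    )


def mann_whitney(x, y) -> ComparisonReport:
    """Mann-Whitney U with tie-corrected normal approximation.

    Z = (U - n1 n2 / 2) / sigma_U with the standard tie correction to
    sigma_U; the two-sided p comes from the normal approximation. |Z| is
    reported (the study tabulates unsigned Z).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u1 = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
    mu_u = n1 * n2 / 2.0
    combined = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:  # every observation tied
        z, p = 0.0, 1.0
    else:
        z = (u1 - mu_u) / np.sqrt(var_u)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonReport(
        test="mann_whitney",
        statistic=abs(float(z)),
        p_value=min(p, 1.0),
        df=None,
        n_per_group=(n1, n2),
        group_means=(float(x.mean()), float(y.mean())),
        group_sds=(
            float(x.std(ddof=1)) if n1 > 1 else 0.0,
            float(y.std(ddof=1)) if n2 > 1 else 0.0,
        ),
        extra={"U": u1},
    )


def chi_square(counts) -> ComparisonReport:
    """Pearson chi-square on a 2 x k count table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 2x3 table, got shape {table.shape}")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq < 5):
        logger.warning("chi-square expected counts below 5; asymptotic p may be inaccurate")
    return ComparisonReport(
        test="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.dof),
        n_per_group=tuple(int(s) for s in table.sum(axis=1)),
        extra={"expected": res.expected_freq.tolist()},
    )


def residualized_compare(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("resting_hr_bpm", "rmssd_ms"),
    outcome: str = "consistency",
) -> ComparisonReport:
    """Group comparison after regressing covariates out of the outcome.

    OLS of the outcome on the covariates, pooled across groups with an
    intercept; the residuals are then compared between groups with the
    pooled t-test. Raises on collinear covariates.
    """
    for col in (*covariates, outcome, "group"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing column {col!r}")
        if col != "group" and cohort[col].isna().any():
            ids = cohort.loc[cohort[col].isna(), "participant_id"].tolist()
            raise ValueError(f"missing {col} for participants: {ids}")
    design = sm.add_constant(cohort[list(covariates)].to_numpy(dtype=float))
    if np.linalg.cond(design) > 1e8:
        raise ValueError("collinear covariates: design condition number > 1e8")
    y = cohort[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, design).fit()
    resid = pd.Series(fit.resid, index=cohort.index)
    lab = resid[cohort["group"] == "laboratory"]
    remote = resid[cohort["group"] == "remote"]
    # An (effectively) exact fit leaves only float noise in the residuals;
    # the scale-invariant t would then be meaningless, so report a null test.
    if np.max(np.abs(resid)) <= 1e-10 * max(np.std(y), 1e-30):
        report = ComparisonReport(
            test="students_t", statistic=0.0, p_value=1.0,
            df=float(lab.size + remote.size - 2),
            n_per_group=(lab.size, remote.size),
            group_means=(0.0, 0.0), group_sds=(0.0, 0.0),
        )
    else:
        report = students_t(lab, remote)
    return ComparisonReport(
        test="residualized_t",
        statistic=report.statistic,
        p_value=report.p_value,
        df=report.df,
        n_per_group=report.n_per_group,
        group_means=report.group_means,
        group_sds=report.group_sds,
        extra={"covariates": list(covariates), "r_squared": float(fit.rsquared)},
    )


def compare_groups(cohort: pd.DataFrame) -> dict[str, ComparisonReport]:
    """The study's battery of comparisons on one analysis arm.

    t-test on consistency; Mann-Whitney on engagement, HRV and age;
    chi-square on sex counts. Classification-count chi-squares are produced
    separately from the per-threshold tables.
    """
    lab = cohort[cohort["group"] == "laboratory"]
    remote = cohort[cohort["group"] == "remote"]
    if lab.empty or remote.empty:
        raise ValueError("both groups must be non-empty")
    out: dict[str, ComparisonReport] = {
        "consistency_t": students_t(lab["consistency"], remote["consistency"])
    }
    nonparam = [
        "mean_time_per_trial_s",
        "mean_dial_turns",
        "n_valid_trials",
        "resting_hr_bpm",
        "sdnn_ms",
        "rmssd_ms",
        "pnn50_pct",
        "age",
    ]
    for col in nonparam:
        if col in cohort.columns:
            out[col] = mann_whitney(lab[col], remote[col])
    if "sex" in cohort.columns:
        sex_counts = [
            [int((g["sex"] == "male").sum()), int((g["sex"] == "female").sum())]
            for g in (lab, remote)
        ]
        out["sex_chi2"] = chi_square(sex_counts)
    if {"resting_hr_bpm", "rmssd_ms"}.issubset(cohort.columns):
        out["consistency_residualized_t"] = residualized_compare(cohort)
    return out
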