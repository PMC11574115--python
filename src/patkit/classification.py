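"""Mixture-model classification of participants from consistency scores.

A two-component Gaussian mixture is fit to the pooled consistency scores
(laboratory + remote together) by expectation-maximisation. The lower-mean
component models non-interoceptive participants (whose uniform-phase
responses yield small scores), the higher-mean component interoceptive
ones. For each participant a z-score under each component gives membership
probabilities (posterior responsibilities), and their ratio is a Bayes
factor. Strict thresholds of 3, 10 and 30 grade the evidence as moderate,
strong and very strong; scores between 1/T and T remain unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

MIN_SCORES = 10
SIGMA_FLOOR = 1e-4
DEGENERATE_WEIGHT = 0.01
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000
BF_THRESHOLDS = (3.0, 10.0, 30.0)

Label = Literal["interoceptive", "non-interoceptive", "unclassified"]


@dataclass(frozen=True)
class MixtureParameters:
    """Fitted two-component Gaussian mixture over consistency scores.

    Components are ordered so ``mu_N < mu_I`` (non-interoceptive = lower
    mean). ``degenerate`` flags a collapsed fit (a component's SD pinned at
    the floor with negligible weight, or zero-variance input); degenerate
    parameters must not be used for membership computation.
    """

    w_N: float
    w_I: float
    mu_N: float
    mu_I: float
    sigma_N: float
    sigma_I: float
    loglik: float
    n_iter: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if abs(self.w_N + self.w_I - 1.0) > 1e-10:
            raise ValueError("mixture weights must sum to 1")
        if min(self.sigma_N, self.sigma_I) < SIGMA_FLOOR - 1e-15:
            raise ValueError(f"component SDs must be >= {SIGMA_FLOOR}")
        if not self.degenerate and self.mu_N >= self.mu_I:
            raise ValueError("components must be ordered mu_N < mu_I")


@dataclass(frozen=True)
class Membership:
    """Per-participant membership under the fitted mixture."""

    z_N: float
    z_I: float
    p_N: float
    p_I: float
    bf: float
    label_bf3: Label
    label_bf10: Label
    label_bf30: Label


def _loglik(x: np.ndarray, w, mu, sigma) -> float:
    dens = w[0] * norm.pdf(x, mu[0], sigma[0]) + w[1] * norm.pdf(x, mu[1], sigma[1])
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_two_component_gmm(
    scores: Iterable[float],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> MixtureParameters:
    """Fit the two-component mixture by EM.

    Initialisation is deterministic: split the sample at its median and take
    each half's mean and SD, with weights 0.5/0.5. EM iterates until the
    log-likelihood changes by less than ``tol`` or ``max_iter`` is reached;
    the log-likelihood is asserted non-decreasing at every iteration.
    Component SDs are floored at ``SIGMA_FLOOR`` to prevent variance
    collapse on small samples.
    """
    x = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, dtype=float)
    if x.size < MIN_SCORES:
        raise ValueError(f"need >= {MIN_SCORES} scores to fit the mixture, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("consistency scores must lie in [0, 1]")

    if np.ptp(x) == 0.0:
        # Zero-variance input: the mixture is unidentifiable.
        return MixtureParameters(
            w_N=0.5, w_I=0.5, mu_N=float(x[0]), mu_I=float(x[0]),
            sigma_N=SIGMA_FLOOR, sigma_I=SIGMA_FLOOR,
            loglik=math.nan, n_iter=0, degenerate=True,
        )

    med = np.median(x)
    lower, upper = x[x <= med], x[x > med]
    if upper.size == 0:  # heavy ties at the median
        lower, upper = np.sort(x)[: x.size // 2], np.sort(x)[x.size // 2:]
    mu = np.array([lower.mean(), upper.mean()])
    sigma = np.maximum(
        np.array([lower.std(ddof=0) or x.std(ddof=0), upper.std(ddof=0) or x.std(ddof=0)]),
        SIGMA_FLOOR,
    )
    w = np.array([0.5, 0.5])

    ll = _loglik(x, w, mu, sigma)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: posterior responsibilities.
        dens = np.stack([w[k] * norm.pdf(x, mu[k], sigma[k]) for k in range(2)])
        total = np.maximum(dens.sum(axis=0), 1e-300)
        resp = dens / total
        # M-step.
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
        sigma = np.maximum(np.sqrt(var), SIGMA_FLOOR)

        new_ll = _loglik(x, w, mu, sigma)
        if new_ll < ll - 1e-9:
            raise RuntimeError(f"EM log-likelihood decreased at iteration {n_iter}")
        converged = abs(new_ll - ll) < tol
        ll = new_ll
        if converged:
            break

    order = np.argsort(mu)
    w, mu, sigma = w[order], mu[order], sigma[order]
    degenerate = any(
        sigma[k] <= SIGMA_FLOOR * (1 + 1e-9) and w[k] < DEGENERATE_WEIGHT for k in range(2)
    )
    return MixtureParameters(
        w_N=float(w[0]), w_I=float(w[1]),
        mu_N=float(mu[0]), mu_I=float(mu[1]),
        sigma_N=float(sigma[0]), sigma_I=float(sigma[1]),
        loglik=ll, n_iter=n_iter, degenerate=degenerate or bool(mu[0] >= mu[1]),
    )


def classify(bf: float, threshold: float) -> Label:
    """Grade the evidence at a strict Bayes-factor threshold.

    ``bf > threshold`` -> interoceptive; ``bf < 1/threshold`` ->
    non-interoceptive; anything else (including a BF exactly at the
    threshold) is unclassified.
    """
    if not bf > 0:
        raise ValueError(f"Bayes factor must be positive, got {bf}")
    if bf > threshold:
        return "interoceptive"
    if bf < 1.0 / threshold:
        return "non-interoceptive"
    return "unclassified"


def membership(
    score: float, params: MixtureParameters, weighted: bool = True
) -> Membership:
    """z-scores, membership probabilities and Bayes factor for one score.

    ``p_k`` is the posterior responsibility ``w_k * phi(z_k) / sigma_k``
    normalised over the two components; with ``weighted=False`` the mixture
    weights are dropped and the probabilities reduce to a pure density
    ratio. ``bf = p_I / p_N``.
    """
    if params.degenerate:
        raise ValueError("cannot compute membership under a degenerate mixture fit")
    z_N = (score - params.mu_N) / params.sigma_N
    z_I = (score - params.mu_I) / params.sigma_I
    # log-space throughout so far-tail scores neither underflow to BF = 0
    # nor divide by zero
    log_d_N = norm.logpdf(z_N) - math.log(params.sigma_N)
    log_d_I = norm.logpdf(z_I) - math.log(params.sigma_I)
    if weighted:
        log_d_N += math.log(params.w_N) if params.w_N > 0 else -math.inf
        log_d_I += math.log(params.w_I) if params.w_I > 0 else -math.inf
    log_bf = log_d_I - log_d_N
    m = max(log_d_N, log_d_I)
    if not math.isfinite(m):  # both densities underflow entirely
        p_N = p_I = 0.5
        log_bf = 0.0
    else:
        total = math.exp(log_d_N - m) + math.exp(log_d_I - m)
        p_N = math.exp(log_d_N - m) / total
        p_I = math.exp(log_d_I - m) / total
    # clip so exp() stays a positive finite float at extreme evidence
    bf = math.inf if log_bf > 700 else math.exp(max(log_bf, -700.0))
    return Membership(
        z_N=float(z_N), z_I=float(z_I), p_N=float(p_N), p_I=float(p_I), bf=float(bf),
        label_bf3=classify(bf, 3.0),
        label_bf10=classify(bf, 10.0),
        label_bf30=classify(bf, 30.0),
    )


def classification_table(
    memberships: Mapping[str, Membership],
    groups: Mapping[str, str],
    thresholds: Sequence[float] = BF_THRESHOLDS,
) -> pd.DataFrame:
    """Counts by group x label for each BF threshold.

    Returns a tidy frame with columns ``threshold, group,
    non-interoceptive, unclassified, interoceptive``; each row sums to the
    group's size.
    """
    label_order = ["non-interoceptive", "unclassified", "interoceptive"]
    rows = []
    for thr in thresholds:
        for grp in sorted(set(groups.values())):
            counts = dict.fromkeys(label_order, 0)
            for pid, m in memberships.items():
                if groups[pid] == grp:
                    counts[classify(m.bf, thr)] += 1
            rows.append({"threshold": thr, "group": grp, **counts})
    return pd.DataFrame(rows)
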