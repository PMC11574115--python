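# Methods

## The task and the measurement model

In the smartphone Phase Adjustment Task (PAT), tones are triggered by the
participant's heartbeats (detected by photoplethysmography through the
phone camera) but delayed by an adjustable amount. The participant turns a
virtual dial until the tones feel synchronous with their heartbeat and then
confirms. Because the starting delay is random on every trial, someone who
can actually feel their heartbeat will settle, trial after trial, near the
same *phase* of the cardiac cycle, while someone who cannot will settle at
phases scattered uniformly around the circle. Cross-trial phase agreement
is therefore the task's measure of cardiac interoceptive accuracy.

`patkit` implements the full analysis chain for this design: trial-level
quality control, circular consistency scoring, mixture-model
classification, time-domain heart rate variability from the 2-minute
baseline, and the laboratory-vs-remote group comparison — plus a simulator
that produces app-schema sessions with known ground truth so that every
stage is testable without human data.

## Consistency score

Each retained trial contributes a phase angle

    theta_t = 2*pi * ((d_t mod RR_t) / RR_t)

where `d_t` is the selected delay (ms) and `RR_t` the mean RR interval over
the trial's own beats (the phase of a delayed tone is defined relative to
the concurrent cardiac cycle, so a per-trial reference is used rather than
the baseline mean). The session's consistency score is the circular mean
resultant length of the 17 angles,

    R = | (1/n) * sum_t exp(i * theta_t) |  in [0, 1].

R = 1 when every trial lands on the same phase; for uniformly random phases
E[R] ~ sqrt(pi / (4n)) (~0.215 at n = 17), not 0 — the scores of
non-interoceptive participants therefore pile up near 0.21-0.25, which is
exactly where the lower mixture component sits. The verbal definition of
the score (1 for close angles, near 0 for random ones) is compatible with
several circular statistics; the mean resultant length is the standard one
with those properties and is the package's documented choice. If an
alternative angular-similarity formula differed, scores would differ by a
monotone transform and the classification would be qualitatively unchanged.

## Quality control

Applied per session, in order, with every threshold surfaced as a named
parameter:

1. practice trials removed (explicit `is_practice` flags; if a session has
   no flags the first 2 trials are removed positionally and this is logged);
2. trials with <= 4 heart-rate samples removed (task disengagement);
3. trials whose dial never left its default position removed — an empty
   trajectory, or one whose every entry equals the default, both count as
   untouched;
4. participants with < 17 valid trials excluded; otherwise exactly the
   *first 17 valid* trials in task order are kept (truncation happens after
   filtering, so a participant with 20 valid trials contributes trials
   1-17 of the valid ones);
5. the screener gate excludes participants whose screener-task consistency
   is < 0.42 (strict); PAT sessions are never gated on their own score.
   The cutoff corresponds to a score at which the probability of being
   non-interoceptive under the reference mixture is approximately zero, so
   lower screener scores indicate non-adherence rather than poor
   interoception.

Engagement metrics are means over the 17 retained trials (time per trial,
unique dial positions per trial), except the valid-trial count, which is
reported pre-truncation (out of 20) as in the study tables.

## Classification

A two-component Gaussian mixture is fit to the *pooled* consistency scores
(both groups together) by EM:

- initialisation: deterministic median split — component means/SDs from the
  two halves, weights 0.5/0.5; no random restarts by default;
- convergence: |delta log-likelihood| < 1e-8, max 1000 iterations; the
  log-likelihood is asserted non-decreasing at every iteration and the fit
  aborts if it ever decreases;
- component SDs floored at 1e-4 to prevent variance collapse; a component
  pinned at the floor with weight < 0.01 (or zero-variance input) marks the
  fit degenerate rather than failing silently;
- components are relabelled so the lower-mean one is "non-interoceptive".

For a score `s`, z-scores under each component are `z_k = (s - mu_k) /
sigma_k` and membership probabilities are posterior responsibilities,
`p_k ∝ w_k * phi(z_k) / sigma_k`, normalised. Responsibilities are the
EM-consistent choice; an unweighted density ratio (dropping `w_k`) is
available via `membership(..., weighted=False)` since the classical
description of the procedure does not pin the weighting down. The Bayes
factor is `BF = p_I / p_N`, and strict thresholds grade it: BF > 3 / 10 /
30 classifies as interoceptive (moderate/strong/very strong evidence),
BF < 1/3, 1/10, 1/30 as non-interoceptive, anything in between —
including a BF exactly at a threshold — as unclassified. Strictness makes
the unclassified band nested, so unclassified counts can only grow as the
threshold rises.

## Heart rate variability

From the strictly increasing baseline beat timestamps, RR intervals are
successive differences. SDNN is the sample SD (n−1 denominator); RMSSD the
root mean square of successive differences; pNN50 the percentage of
successive differences strictly exceeding 50 ms; resting HR is
60000 / mean(RR) bpm. HRV uses the baseline only, never trial-period
beats, and no artifact correction is applied — intervals outside
[300, 2000] ms trigger a warning but are retained, matching an analysis
that reported none.

## Group comparison

- **Age matching**: remote participants aged >= 30 removed, laboratory
  participants under 19 removed, plus laboratory participants at or above
  an outlier bound (default 63). Implemented as bounds (idempotent) rather
  than a hard-coded participant list so it generalises to simulated data.
- **Consistency**: pooled-variance Student's t (df = n1 + n2 − 2; Welch
  available via flag). The pooled variant is used because reported degrees
  of freedom in this literature equal n1 + n2 − 2.
- **Engagement / HRV / age**: Mann-Whitney U with the tie-corrected normal
  approximation; |Z| and two-sided p are reported (the SPSS convention).
  Exact enumeration is used as a test oracle only.
- **Sex and classification counts**: Pearson chi-square without continuity
  correction (2x3 classification tables have df = 2 under plain Pearson);
  expected counts below 5 log a warning.
- **Control analysis**: consistency is regressed on resting HR and RMSSD
  (OLS, pooled across groups, with intercept — pooling chosen so both
  groups share one covariate adjustment) and the residuals are compared
  with the pooled t-test. Collinear covariates (condition number > 1e8)
  raise an error; an exact fit (residuals at float-noise level) reports a
  null comparison explicitly, because the scale-invariant t statistic of
  pure rounding noise would otherwise be meaningless.
- Outlying consistency scores are retained; sensitivity reruns can simply
  drop rows from the cohort table.

## Synthetic cohorts

The generator's defaults are the study conditions; they are fixed once and
not tuned per analysis:

| parameter | default | rationale |
|---|---|---|
| RR mean / SD | 800 / 50 ms | resting HR ~75 bpm, as in the cohort tables |
| baseline duration | 120 s | the task's baseline recording window |
| trials | 2 practice + 20 task | task structure |
| trial duration | 2 s + gamma, mean 21.6 s, SD 11 s | engagement-table magnitudes |
| dial positions per trial | Poisson(27) + 1 | engagement-table magnitudes |
| p(invalid trial) | 0.045 | ~19.1 valid of 20 trials, as observed |
| interoceptive fraction | 0.40 | classification-table magnitudes at BF3 |
| kappa (interoceptive) | uniform(0.8, 2.0) | via the Bessel ratio I1/I0, mean 17-trial score ~0.55-0.6, the upper mixture component's neighbourhood |
| screener kappa (adherent) | uniform(2, 6) | the screener matches two audible tones — an exteroceptive skill nearly all adherent participants have, so screener concentration is independent of interoceptive status |
| p(non-adherent) | 0.05 | small screener-gate exclusion rates |
| ages | lab N(23.1, 7.7), remote N(31.0, 9.4), clipped to [18, 65] | cohort demographics |

RR intervals are truncated-normal (floor 300 ms, rejection sampling) rather
than autocorrelated: the pipeline only needs plausible RR variability for
time-domain HRV, and an AR structure would change none of the tested
quantities. Responses are von Mises draws around a per-participant
preferred phase (kappa = 0, i.e. uniform, for non-interoceptive
participants); the true response-generation process of a human is unknown,
and the von Mises model is this package's explicit assumption. Confidence
ratings are drawn independent of accuracy (they are collected but not
analysed). Invalid trials are injected explicitly and labelled in trial
metadata, so QC precision/recall is measurable by construction. All
randomness flows from a single integer seed through one numpy Generator;
identical configs give byte-identical session files.

What the simulator does **not** emulate: PPG waveforms and beat-detection
error, within-session learning or drift, phase-dependent response biases,
respiratory sinus arrhythmia and other RR autocorrelation, and any
dependence of confidence on accuracy. Passing tests on simulated cohorts
therefore demonstrate that the analysis chain is correct under the stated
generative model — not that the model captures every property of human
data.

## Numerical choices and degenerate inputs

- Angles are radians in [0, 2pi); delays in ms; the phase map wraps delays
  longer than one cycle.
- EM: tol 1e-8 on log-likelihood, max 1000 iterations, sigma floor 1e-4,
  deterministic initialisation (restarts configurable).
- An all-tied Mann-Whitney input returns Z = 0, p = 1 instead of dividing
  by a zero variance.
- A BF of +inf (score in the far tail where p_N underflows) classifies as
  interoceptive at every threshold; both-tail underflow falls back to
  p = 0.5/0.5.
- Zero-variance score sets and collapsed mixture components are flagged
  degenerate; membership computation refuses degenerate parameters.

## Problem sizes

The test suite and the acceptance script use 2,000 replicates for
Monte-Carlo calibration checks, 20 replicate fits of 500 scores for
mixture recovery, and simulated cohorts of 100 laboratory + 143 remote
participants for the end-to-end run — the sizes at which the quantities of
interest are stable to well within their tolerances.

## Known limitations

- The exact angular-similarity formula of the original task's reference
  implementation is not public in this form; mean resultant length is the
  documented reading, and a monotone transform of it would reorder nothing.
- The mixture is restricted to two Gaussian components; heavy-tailed or
  skewed score distributions would be mis-modelled.
- The Mann-Whitney p is asymptotic; at very small n it deviates from the
  exact permutation p (the tests quantify this at n = 4).
- Analyses of deposited human data require that data to be downloaded
  separately; this package validates the pipeline on simulated cohorts.
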