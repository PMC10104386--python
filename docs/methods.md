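# Methods

`vigilpred` implements an individual-differences analysis of psychomotor
vigilance under recurrent partial sleep restriction, together with a
generative simulator that stands in for (unavailable) participant data.
This note records the models, the parameter choices and their rationale, the
numerical decisions, and what the synthetic data can and cannot establish.

## The study design being modelled

Two groups of adolescents live through a 15-day protocol: two 9-h
time-in-bed (TIB) baseline nights (B1, B2), five restriction nights at 5.0 h
or 6.5 h TIB (M1_1–M1_5), two 9-h recovery nights (R1_1, R1_2), three more
restriction nights (M2_1–M2_3) and two final recovery nights.  A 10-minute
psychomotor vigilance task (PVT) is administered three times per day (twice
on the arrival day B0; none on the final day).  A day label names the
*preceding night*: "M1_5 performance" means the sessions after the fifth
restriction night.

PVT outcomes per session: number of lapses (RT ≥ 500 ms, timeouts
included), median RT, and the within-session SD of RT.  False starts
(RT < 100 ms) are excluded from all three; timeouts (10-s deadline) count as
lapses but are excluded from median/SD by default — a censored 10 000 ms
value would dominate the SD (`MetricRules.include_timeouts_in_rt_stats`
flips this).  Daily values are unweighted means over the day's sessions,
regardless of trial counts.  The median of an even count is the mean of the
two central values.

## One-choice drift-diffusion model

A single accumulator starts at 0 and drifts toward an absorbing boundary
`a` with unit diffusion coefficient (the scale convention; the σ = 0.1
convention in parts of the literature is the reparameterization v → v/0.1,
a → a/0.1, η → η/0.1).  For a trial with drift `u` the decision time is
Wald (inverse-Gaussian):

    f(t | u, a) = a (2π t³)^(-1/2) exp(−(a − u t)² / (2t))

Across trials the drift is Normal(v, η²); marginalizing gives the closed
form used throughout:

    f(t | v, η, a) = a (2π t³ (1 + η² t))^(-1/2)
                     exp(−(a − v t)² / (2 t (1 + η² t)))

with the matching closed-form CDF

    F(t) = Φ((vt − a)/s) + exp(2va + 2η²a²) Φ(−(vt + a + 2η²at)/s),
    s² = t (1 + η² t),

whose second term is evaluated on the log scale (`log_ndtr`) to avoid
overflow.  The density is defective when η > 0: drifts ≤ 0 may never absorb,
which is exactly the timeout mass before censoring.

The observed RT adds a non-decision time uniform on [ter − st/2, ter + st/2]
(motor/encoding latency; `st` is the non-decision time *range*, the
within-subject variability of interest), and a uniform contaminant on
(0, 10] s with weight `p_c` (capped at 0.1 so it cannot absorb the slow tail
that drift variability should explain) accounts for anticipations and other
off-model responses.  The RT density convolves the decision density with the
uniform window by K-node Gauss–Legendre quadrature (K = 11 default; the
integrand is smooth away from the onset kink, where the quadrature error is
confined).  Timeouts contribute log S(10) to the likelihood, with S computed
from the closed-form CDF.

### Estimation

`fit_day` pools all of a subject-day's sessions (≥ 100 trials by default)
and maximizes the censored log-likelihood by Nelder–Mead on an unconstrained
transform (log for positive scales, logit for p_c; the lower non-decision
edge is kept above 50 ms).  Multi-start: method-of-moments anchors for a
shifted Wald — one from mean/SD, one from robust (interquartile) moments,
each with a high- and a low-drift-variability variant — plus seeded ±0.4
log-scale jitters.  Ties across restarts (< 1e-9) resolve to the lowest
restart index.  The hot path (likelihood and simplex loop) is
numba-compiled; a test pins it to the numpy reference implementation.

**Boundary anchoring.**  By default the boundary is fixed at a = 1 and only
(v, η, ter, st, p_c) are estimated (`FitOptions.fix_a=None` frees it).  The
reason is identification, established numerically: at a realistic baseline
day (v = 4, η = 1, a = 1, ter = 0.28 s, st = 0.12 s, ~270 trials) the Fisher
information has a near-null direction mixing (v, η, a) — the CRLB for v̂ with
all six parameters free is σ ≈ 3.4, i.e. the drift is not usably estimable
from a single day's data.  Anchoring the boundary collapses the ridge
(CRLB σ(v̂) ≈ 0.41, ~8% median relative error at 270 trials).  Drift is
therefore measured in boundary units per second; real between-subject
boundary variation folds into the effective drift, which is the appropriate
scale for ranking individuals — the analysis's only use of v̂.

An alternative estimator (`method="quantile_chisq"`) minimizes a Pearson
chi-square of observed vs model counts in RT-decile bins plus a timeout
cell; it is provided because pipelines in this literature differ on the
estimation route, and the choice is then explicit.

## Vulnerability slopes and inference

Per subject and outcome, OLS slopes over daily values for
week 1 = (B2, M1_1…M1_5) and week 2 = (R1_2, M2_1…M2_3), with day offsets
0,1,2,… within each window (slope units: outcome per day; missing days keep
their offsets; fewer than 3 usable days flags the slope missing).
`slope_diff = slope_wk2 − slope_wk1` indexes vulnerability to *recurrent*
restriction.

The week × group analysis exploits the two-level structure: with two
balanced within-subject levels, the mixed-model tests reduce exactly to
t-contrasts on per-subject week means (group effect), week differences
(interaction = pooled two-sample t on slope_diff; the test suite asserts
this identity to 1e-10), and the unweighted marginal mean of the group week
differences (week effect).  Simple effects are the corresponding paired and
two-sample contrasts.  This equivalence is exact only for the balanced
2-level case, which this design is.

The prediction models regress a target (slope_wk1 or slope_diff) on the
subject's baseline (B2) summary metric for the same outcome, the two
baseline DDM predictors (drift average v̂ and non-decision time range ŝt),
and a group indicator (1 = 5-h TIB).  Classical OLS inference; raw two-sided
p-values (a Benjamini–Hochberg helper exists but is off by default, matching
the way such analyses are conventionally reported); complete-case analysis —
subjects with non-converged baseline fits are dropped and counted.

## Synthetic-data generator

Each subject is a one-choice diffusion whose day-level mean drift declines
with accumulated sleep pressure:

    P(d) = max(0, ρ·P(d−1) + (need − TIB_d)),    ρ = 0.5, need = 9 h
    v_d  = max(0.25·v_base, v_base − κ·(1 + κ₂·[week-2 and P ≥ 4.9]) · P)

κ is the subject's vulnerability trait (drift loss per hour-equivalent of
pressure); κ₂ = 0.5 makes a unit of pressure more costly in the second
restriction cycle, but only at severe pressure (the 4.9-h gate sits between
the 6.5-h group's maximum, 4.84, and the 5-h group's second-cycle levels,
4.97–7.24).  The gate is what lets the 5-h group diverge in week 2 while the
6.5-h group deteriorates at its week-1 rate — the observed signature of
recurrent-restriction vulnerability.

Decision times are sampled exactly (inverse-Gaussian for u > 0 via
Michael–Schucany–Haas; for u < 0 the reflection identity — absorbed with
probability exp(2ua), conditional time IG with mirrored drift; Lévy law at
u = 0), so the generator's RT law equals the fitted density by construction;
an independent Euler path oracle (Brownian-bridge corrected) verifies both
in the tests.  Sessions draw ISIs uniform on 2–10 s and keep producing
trials while the cumulative ISI + RT is inside the 10-minute window (~90–95
trials at baseline speed).  Anticipations occur with probability 1% per
trial, uniform on 100–250 ms; they are below any plausible true RT but above
the 100-ms false-start filter, and are absorbed by the fitted contaminant
component.  Every session has its own RNG stream keyed by
(seed, subject, day, session) through stable CRC-32 hashing, so studies are
reproducible and insensitive to generation order.

### Population defaults and calibration

| parameter | default | rationale |
| --- | --- | --- |
| v_base | N(8.0, 1.5²) | baseline median RT ≈ 300–330 ms, 2–7 lapses/session |
| η | N(2.5, 0.4²) | lapse tail at baseline without timeouts |
| a | N(1.0, 0.12²) | modest caution differences |
| ter | N(0.20, 0.02²) s | motor latency; floor 60 ms + st/2 |
| st | N(0.12, 0.04²) s, clipped to [0.02, 0.30] | non-decision variability |
| κ | N(0.25, 0.08²), κ ≥ 0 | see calibration below |
| corr(v_base, κ) | −0.6 | plants "poor baseline ⇒ steep decline" |
| p_false_start | 0.01 | low anticipatory rate |

The vulnerability scale κ̄ = 0.25 (CV kept at 1/3) was calibrated against
the reported group-mean lapse slopes for adolescents under this protocol
(≈ +1.8 lapses/day in week 1; ≈ +4.75 vs +1.9 lapses/day in week 2 for the
5-h vs 6.5-h dose): the expected-value trajectory of the generator then
yields wk1 ≈ 1.6/0.95 and wk2 ≈ 4.3/2.0 lapses/day.  The week-1 equality of
the two dose groups reported empirically is *not* reproducible under a
dose-proportional drift-loss model — pressure differs between groups from
the first night — and is a known qualitative mismatch of this generator.

What the generator deliberately omits: time-of-day (circadian) modulation of
the three daily sessions, state-instability (within-session drift random
walks), homeostatic two-process dynamics, and practice effects.  Passing
tests therefore show that the pipeline recovers the planted structure under
the fitted model's own assumptions — not that real PVT data satisfy those
assumptions.

## Problem sizes in the test suite

Replicate-study experiments run scaled-down: the null-calibration runs use
120-s sessions and a single optimizer start per fit (type-I error is
insensitive to these); the planted-effect runs keep full 10-minute sessions
(the drift-mediated effects need full trial counts) with two starts per fit.
Subject counts (28 + 29), the session schedule, and population parameters
are never scaled.  The parameter-recovery study uses 100 replicate baseline
days of 270 trials.

## Known limitations

- Estimation noise in v̂ at ~270 baseline trials per subject bounds the
  attainable rank agreement between true and fitted drift at roughly
  0.6–0.75 across a 57-subject study; between-subject boundary variation
  contributes because v̂ is drift in boundary units.
- Every baseline regressor (lapses, v̂, ŝt) is measured from the same B2 day
  whose sampling noise also enters the week-1 slope as its first point.
  Under a null generator this errors-in-variables coupling miscalibrates the
  regression terms — the baseline-lapses term rejects at ~17% with
  full-length sessions and ~46% at heavily scaled-down sessions instead of
  5%, with smaller distortions on the ŝt and v̂ terms — while the
  week/group/interaction tests calibrate cleanly.  This is a property of
  the analysis design itself, not of the OLS machinery (which calibrates
  exactly under independent noise).  Notably the artifact's sign (negative
  on slope_wk1, positive on slope_diff) is *opposite* to the reported
  empirical associations, so it cannot manufacture them.
- The SD-RT outcome is a sample SD of a heavy-tailed distribution and is by
  far the noisiest of the three; sign consistency of its drift coefficient
  across replicate studies is correspondingly fragile.
- The closed-form week × group analysis assumes compound symmetry, exact
  here only because there are two within-subject levels.
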