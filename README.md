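# vigilpred

Who is vulnerable to sleep loss?  Healthy people restricted to the same
short sleep schedule deteriorate at strikingly different rates on the
psychomotor vigilance task (PVT), and that trait is stable — so the
practical question is whether a single *well-rested* testing day can predict
how badly someone will fare over one week of short sleep, and over a second
week after recovery sleep.  `vigilpred` implements that analysis as a tested
pipeline for trial-level PVT data from two-cycle sleep-restriction
protocols, together with a generative simulator of such studies (for power
analysis, pipeline validation, and as a stand-in where participant data
cannot be shared).

It is aimed at sleep and vigilance researchers working with PVT data, and at
cognitive modellers who want a fast, validated one-choice drift-diffusion
fitting routine for simple-RT tasks.

## The model and the statistics

The PVT is a 10-minute simple-RT task (respond as fast as possible when a
counter starts; stimuli at random 2–10 s intervals; 10-s deadline).  Each
trial is modelled as a one-choice diffusion: evidence accumulates from 0
toward a boundary *a* at drift *u* with unit diffusion coefficient, giving a
Wald (inverse-Gaussian) decision time; across trials *u* ~ N(v, η²), which
produces the lapse tail.  Marginally,

    f(t) = a · (2π t³ (1 + η²t))^(-1/2) · exp(−(a − vt)² / (2t(1 + η²t)))

and the observed RT adds a non-decision time uniform on [Ter − st/2,
Ter + st/2].  Censored maximum likelihood (timeouts enter through the
closed-form survival term, plus a small uniform-contaminant mixture) yields
the two baseline predictors: the **drift average v** (speed of information
accumulation) and the **non-decision time range st** (within-subject
variability of non-cognitive responding).

Vigilance deterioration is summarized per subject as OLS slopes of the daily
PVT metrics — lapses (RT ≥ 500 ms), median RT, SD RT — across the first
restriction week (last baseline day B2 → fifth restriction day M1_5) and the
second (last recovery day R1_2 → third restriction day M2_3):
**slope_wk1**, **slope_wk2**, and their difference **slope_wk2−wk1**, the
index of vulnerability to *recurrent* restriction.  Inference is a 2 × 2
week-by-group repeated-measures analysis of the slopes (closed form; with
two within-subject levels every test is an exact t-contrast) and multiple
regressions of each vulnerability target on the baseline summary metric, v,
st and a group covariate.

## Worked example

Simulate a full 57-subject study (28 at 5-h TIB, 29 at 6.5-h TIB, 15 days,
three 10-minute PVT sessions per test day) and run the complete analysis:

```
vigilpred simulate --seed 1 --out study/
vigilpred analyze --trials study/trials.csv --out study/
```

or in Python:

```python
from vigilpred import simulate_study, run_analysis

study = simulate_study(seed=1)              # trials + latent ground truth
result = run_analysis(study.trials)
print(result.week_group["lapses"].p_interaction)
print(result.regressions[("slope_wk1", "lapses")].to_frame())
```

With seed 1 the pipeline prints the following (values from
`results/acceptance.json`, see below):

- Group-mean lapse slopes: **+1.89** lapses/day (5-h group) vs **+0.93**
  (6.5-h) in week 1, **+4.18** vs **+1.22** in week 2 — the 5-h group
  deteriorates almost three times faster when restriction recurs, while the
  6.5-h group barely steepens; week × group interaction p = 1.9e-08.
- Baseline lapses predict week-1 lapse accumulation: B = **+0.10** lapses/day
  per baseline lapse (p = 3.3e-06), controlling for baseline drift,
  non-decision time range and group.
- Baseline drift carries a negative coefficient on the week-2-minus-week-1
  lapse slope (B = −0.034) and on the SD-RT slope difference (B = −5.3):
  slower evidence accumulation at baseline goes with a larger second-week
  penalty (single-study p-values are noisy; the sign pattern is the stable
  quantity, see `tests/test_acceptance.py`).
- DDM recovery: median |v̂ − v|/v = **8.3%** over 40 simulated baseline days
  of 270 trials; Spearman correlation between true and fitted drift across
  the 57 subjects = **0.62**.

The simulator writes the latent truth (each subject's baseline drift,
vulnerability coefficient κ, per-day true drift) beside the trials, so every
analysis output can be checked against what was planted.

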