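# semcond

Analysis pipeline for **semantic classical conditioning** as a basis for
binary ("yes"/"no") EEG brain–computer communication — aimed at the
completely locked-in state, where operant BCI control fails and classical
conditioning may be the only viable learning channel.

In the paradigm, spoken true statements (CS1, prompting "yes" thinking) and
false statements (CS2, "no" thinking) are paired with two aversive noises
(US1/US2) over two sessions; the conditioned EEG reactions to *unpaired*
statements are then analyzed. No recordings of this paradigm are public, so
the package simulates the complete experiment — trial scheduling, continuous
500 Hz EEG with configurable conditioned responses, noise and artifacts —
and applies the full analysis chain to it:

- **paradigm** — two-session schedules for four experimental arms
  (original, long-US, individually-selected-US, no-US control): 640 trials,
  250 CS+ / 50 CS− / 20 CS−ext per CS type, every unpaired trial followed
  by a paired one.
- **synthgen** — synthetic multichannel EEG realizing a schedule: AR(1) (or
  1/f) background, half-cosine conditioned-response templates with latency
  jitter, US-evoked responses, optional blinks; template amplitudes are
  calibrated analytically to per-trial AUC effect sizes.
- **preprocess** — zero-phase 0.009–30 Hz Butterworth filtering, EOG
  regression, 2000 ms post-sentence and baseline epochs with 100 ms offset
  correction.
- **aucstats** — the AUC-with-respect-to-increase statistic
  `AUC_ri = ∫(x − x₁) dt`, last-20-segment cell means, and a
  repeated-measures ANOVA engine (any number of within factors, one
  between factor, Greenhouse–Geisser correction, partial η², planned
  contrasts, Shapiro–Wilk screening).
- **decode** — single-trial RBF-SVM classification: Scheme I ("yes" vs
  "no"), II ("yes" vs baseline), III ("no" vs baseline); 70 trials per
  class, 1000-dimensional moving-average/decimated features, stratified
  10-fold CV with inner-fold hyperparameter search, binomial chance bands
  (`50 ± z·100·√(0.25/n)` %), and group aggregation.

See `docs/methods.md` for the model, parameter choices, and limitations.

## Worked example

```python
from semcond.pipeline import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(schedule_seed=1, signal_seed=2))
for scheme, res in bundle["classification"].items():
    lo, hi = res.chance
    print(f"Scheme {scheme}: {res.round2():.2f}% (chance {lo:.2f}-{hi:.2f}%)")
```

prints, for the default differential-conditioning model (AUC effect sizes
d = 0.5 for CS1 and d = 0.8 for CS2 vs baseline):

```
Scheme I: 97.86% (chance 41.72-58.28%)
Scheme II: 98.57% (chance 41.72-58.28%)
Scheme III: 100.00% (chance 41.72-58.28%)
```

Scheme III ("no" vs baseline) is easiest, Scheme I (the two conditioned
reactions against each other) hardest — the qualitative ordering expected
when the two CRs share their shape and differ mainly in amplitude. Under
the null model (`RunConfig(erp=ERPSettings(kind="null"))`), Scheme I falls
inside the chance band.

The numbered drivers under `analysis/` run the same steps as a narrative:
schedules (`01`), simulation + preprocessing (`02`), AUC/ANOVA on a cohort
(`03`), classification cohorts (`04`), and aggregation of the published
per-participant accuracies (`05`), writing tables under `results/`. A
`semcond` CLI exposes each stage (`semcond simulate-schedule`,
`simulate-eeg` (EDF out), `preprocess`, `auc`, `anova`, `classify`,
`report`, `run`, `validate-config`).

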